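import numpy as np
import pytest

from sibassoc import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate cohort with a planted effect, shared across read-only
    tests (500 pairs, single SNP, icc 0.4)."""
    cfg = SimulationConfig(n_pairs=500, maf_per_snp=(0.2,),
                           beta_sd_per_snp=(0.15,), trait_per_snp=("tg",),
                           icc=0.4, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def panel_cohort():
    """Default 7-SNP study-design cohort at reduced size."""
    return simulate_cohort(SimulationConfig(n_pairs=600, seed=11))


def spawn_seeds(base: int, n: int) -> list[int]:
    """Deterministic independent child seeds below 2**31."""
    ss = np.random.SeedSequence(base)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]
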