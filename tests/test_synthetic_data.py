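"""Generator sanity: allele frequencies, sibling genetic correlation, trait
scaling, null calibration, and the Friedewald arithmetic."""

import numpy as np
import pytest
from scipy.stats import kstest

from sibassoc import (LDPanelConfig, SimulationConfig, fit_quantitative,
                      friedewald_ldl, r2_matrix, simulate_cohort,
                      simulate_ld_panels)

from conftest import spawn_seeds


@pytest.mark.parametrize("tc,hdl,tg,expected", [
    (200.0, 50.0, 100.0, 130.0),
    (183.2, 43.5, 134.1, 112.88),   # study-mean arithmetic
    (100.0, 100.0, 0.0, 0.0),
])
def test_friedewald_arithmetic(tc, hdl, tg, expected):
    assert friedewald_ldl(tc, hdl, tg) == pytest.approx(expected, abs=1e-9)


def test_friedewald_warns_outside_validity_domain():
    with pytest.warns(UserWarning, match="TG >= 400"):
        v = friedewald_ldl(300.0, 40.0, 450.0)
    assert v == pytest.approx(300.0 - 40.0 - 90.0)


def test_pooled_allele_frequency_matches_target():
    """fst=0, q=0.2: the pooled sample frequency sits within 3 binomial SEs."""
    cfg = SimulationConfig(n_pairs=5000, maf_per_snp=(0.2,),
                           beta_sd_per_snp=(0.0,), trait_per_snp=("tg",),
                           fst=0.0, seed=101)
    coh = simulate_cohort(cfg)
    freq = coh.genotypes[:, 0].mean() / 2.0
    # var(ghat) for sib pairs: var(g1+g2)=6pq per pair -> 3pq/(8 n_pairs)
    se = np.sqrt(3 * 0.2 * 0.8 / (8 * cfg.n_pairs))
    assert abs(freq - 0.2) < 3 * se


def test_sib_dosage_correlation_is_half():
    """Full sibs share half their genome: dosage correlation ~ 0.5; unrelated
    individuals from the same population correlate ~ 0."""
    cfg = SimulationConfig(n_pairs=20000, maf_per_snp=(0.3,),
                           beta_sd_per_snp=(0.0,), trait_per_snp=("tg",),
                           seed=5)
    coh = simulate_cohort(cfg)
    pr = coh.pair_rows()
    g1, g2 = coh.genotypes[pr[:, 0], 0], coh.genotypes[pr[:, 1], 0]
    assert np.corrcoef(g1, g2)[0, 1] == pytest.approx(0.5, abs=0.02)
    assert abs(np.corrcoef(g1[:-1], g1[1:])[0, 1]) < 0.02


def test_trait_variance_and_pair_share():
    """The standardized trait has unit variance; the pair-shared share of the
    non-systematic variance equals icc."""
    cfg = SimulationConfig(n_pairs=20000, maf_per_snp=(0.2,),
                           beta_sd_per_snp=(0.0,), trait_per_snp=("tg",),
                           icc=0.4, covariate_effects={"age": 0, "male": 0, "urban": 0},
                           seed=17)
    coh = simulate_cohort(cfg)
    z = coh.samples["z_tg"].to_numpy()
    pr = coh.pair_rows()
    assert np.var(z) == pytest.approx(1.0, abs=0.02)
    assert np.corrcoef(z[pr[:, 0]], z[pr[:, 1]])[0, 1] == pytest.approx(0.4, abs=0.03)


def test_cohort_structure_and_hypertension():
    coh = simulate_cohort(SimulationConfig(n_pairs=4000, seed=3))
    assert coh.n_individuals == 8000 and coh.n_pairs == 4000
    assert set(coh.samples["pair_id"].value_counts()) == {2}
    flagged = (coh.samples["sbp"] >= 140) | (coh.samples["dbp"] >= 90)
    assert (coh.samples["hypertension"] == flagged.astype(int)).all()
    assert coh.samples["hypertension"].mean() == pytest.approx(0.181, abs=0.03)
    assert (coh.samples["location"] == "rural").mean() == pytest.approx(0.366, abs=0.03)
    assert set(coh.samples["fat_intake"]) == {"low", "high"}


def test_null_within_pair_pvalues_uniform():
    """beta=0, no confounding: within-pair association p-values are uniform."""
    pvals = []
    for seed in spawn_seeds(2101, 150):
        cfg = SimulationConfig(n_pairs=300, maf_per_snp=(0.25,),
                               beta_sd_per_snp=(0.0,), trait_per_snp=("tg",),
                               icc=0.3, seed=seed)
        coh = simulate_cohort(cfg)
        pvals.append(fit_quantitative(coh, coh.snp_ids[0], "tg").p_within)
    assert kstest(pvals, "uniform").pvalue > 0.01


@pytest.mark.parametrize("bad", [
    dict(maf_per_snp=(0.6,), beta_sd_per_snp=(0.0,), trait_per_snp=("tg",)),
    dict(maf_per_snp=(0.0,), beta_sd_per_snp=(0.0,), trait_per_snp=("tg",)),
    dict(icc=1.0),
    dict(fst=1.0),
    dict(maf_per_snp=(0.2, 0.3), beta_sd_per_snp=(0.0,), trait_per_snp=("tg",)),
    dict(n_pairs=0),
])
def test_invalid_simulation_config_rejected(bad):
    with pytest.raises(ValueError):
        simulate_cohort(SimulationConfig(**bad))


def test_ld_panel_config_validation():
    good = np.eye(3)
    with pytest.raises(ValueError, match="shape"):
        LDPanelConfig((50, 50), (0.3, 0.3), good).validate()
    asym = np.array([[1.0, 0.5, 0.0], [0.2, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        LDPanelConfig((50, 50), (0.3,) * 3, asym).validate()
    npsd = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
    with pytest.raises(ValueError, match="positive semidefinite"):
        LDPanelConfig((50, 50), (0.3,) * 3, npsd).validate()


def test_independent_panel_r2_vanishes():
    cfg = LDPanelConfig(n_subjects=(10000, 10), allele_freqs=(0.3,) * 4,
                        target_corr_pop1=np.eye(4), seed=8)
    p1, _ = simulate_ld_panels(cfg)
    r2 = r2_matrix(p1).r2
    off = r2[np.triu_indices(4, k=1)]
    assert np.nanmean(off) < 0.01


def test_ld_panel_realized_frequency():
    cfg = LDPanelConfig(n_subjects=(20000, 10), allele_freqs=(0.1, 0.4),
                        target_corr_pop1=np.eye(2), seed=9)
    p1, _ = simulate_ld_panels(cfg)
    np.testing.assert_allclose(p1.mean(axis=0) / 2, [0.1, 0.4], atol=0.01)
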