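"""Synthetic sib-pair cohorts and two-population LD panels.

The real study cohort (3,178 Indian sib pairs, seven lipid SNPs) is not
public, so every downstream stage is exercised on simulated data with the
same statistical structure:

* genotypes — parental alleles drawn from subpopulation frequencies under
  the Balding–Nichols model (subpopulation frequency ~ Beta with mean q and
  variance Fst·q(1−q)), offspring by Mendelian transmission, which yields
  the sib-sib dosage correlation of 1/2 expected for full sibs;
* traits — standardized lipid levels built from per-allele additive effects,
  age/sex/location covariate effects, an optional per-subpopulation mean
  shift that *covaries with the subpopulation allele-frequency deviations*
  (the confounding that motivates within-pair inference), a pair-shared
  normal effect and an individual residual;
* natural units — mg/dl traits by affine transform using the study's
  all-participant means/SDs; blood pressures and the derived hypertension
  label (SBP ≥ 140 or DBP ≥ 90 mmHg).

The pair-shared and residual variances are scaled so the standardized trait
has total variance 1, with ``icc`` controlling the pair-shared share of the
non-systematic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from . import reference as ref
from .cohort_io import SibPairCohort, SnpMeta

_PANEL_MAFS = tuple(s["maf"] for s in ref.SNP_PANEL)
_PANEL_BETAS = tuple(s["beta_sd"] for s in ref.SNP_PANEL)
_PANEL_TRAITS = tuple(s["primary_trait"] for s in ref.SNP_PANEL)

DEFAULT_COVARIATE_EFFECTS = {"age": 0.15, "male": 0.10, "urban": 0.13}
"""Standardized-trait effects: per SD of age, male vs female, urban vs rural."""


@dataclass
class SimulationConfig:
    """Knobs for :func:`simulate_cohort`; defaults emulate the study design."""

    n_pairs: int = ref.N_PAIRS
    maf_per_snp: tuple[float, ...] = _PANEL_MAFS
    beta_sd_per_snp: tuple[float, ...] = _PANEL_BETAS
    trait_per_snp: tuple[str, ...] = _PANEL_TRAITS
    icc: float = 0.3
    n_subpops: int = 4
    fst: float = 0.0
    confounding_shift: float = 0.0
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    migrant_pair_fraction: float = 2 * ref.RURAL_FRACTION
    geno_missing_rate: float = 0.0
    binary_logor_per_snp: tuple[float, ...] | None = None
    binary_pair_sd: float = 0.0
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return len(self.maf_per_snp)

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not all(0.0 < q <= 0.5 for q in self.maf_per_snp):
            raise ValueError("all minor-allele frequencies must lie in (0, 0.5]")
        if len(self.beta_sd_per_snp) != self.n_snps or len(self.trait_per_snp) != self.n_snps:
            raise ValueError("beta_sd_per_snp / trait_per_snp length mismatch with maf_per_snp")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        unknown = set(self.trait_per_snp) - set(ref.TRAIT_SCALE_MGDL)
        if unknown:
            raise ValueError(f"unknown target traits: {sorted(unknown)}")


def _subpop_freqs(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_subpops, n_snps) Balding–Nichols frequencies; fst=0 copies the mean."""
    q = np.asarray(cfg.maf_per_snp)
    if cfg.fst == 0.0 or cfg.n_subpops == 1:
        return np.tile(q, (cfg.n_subpops, 1))
    a = q * (1.0 - cfg.fst) / cfg.fst
    b = (1.0 - q) * (1.0 - cfg.fst) / cfg.fst
    return rng.beta(a, b, size=(cfg.n_subpops, cfg.n_snps))


def _mendelian_sibs(freq: np.ndarray, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Two sib dosage matrices from per-pair allele frequencies (n_pairs, n_snps)."""
    shape = freq.shape
    father = (rng.random((2, *shape)) < freq).astype(np.int8)
    mother = (rng.random((2, *shape)) < freq).astype(np.int8)
    sibs = []
    for _ in range(2):
        fpick = rng.integers(0, 2, size=shape)
        mpick = rng.integers(0, 2, size=shape)
        g = (np.take_along_axis(father, fpick[None], axis=0)[0]
             + np.take_along_axis(mother, mpick[None], axis=0)[0])
        sibs.append(g.astype(float))
    return sibs[0], sibs[1]


def simulate_cohort(config: SimulationConfig) -> SibPairCohort:
    """Draw a complete sib-pair cohort under ``config``.

    Returns a cohort of ``2 * n_pairs`` individuals with dosages, mg/dl and
    standardized lipid traits, covariates, blood pressures and the derived
    hypertension indicator.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_pairs, cfg.n_snps
    q = np.asarray(cfg.maf_per_snp)
    betas = np.asarray(cfg.beta_sd_per_snp)

    subpop = rng.integers(0, cfg.n_subpops, size=n)
    pop_freq = _subpop_freqs(cfg, rng)
    g1, g2 = _mendelian_sibs(pop_freq[subpop], rng)

    # confounded trait shift: proportional to the standardized aggregate
    # allele-frequency deviation, so frequency and trait mean covary
    shift = np.zeros(cfg.n_subpops)
    if cfg.confounding_shift != 0.0 and cfg.n_subpops > 1:
        dev = (pop_freq - q).sum(axis=1)
        sd = dev.std(ddof=0)
        if sd > 0:
            shift = cfg.confounding_shift * (dev - dev.mean()) / sd

    # covariates ----------------------------------------------------------
    ce = {**DEFAULT_COVARIATE_EFFECTS, **(cfg.covariate_effects or {})}
    pair_male = rng.random(n) < ref.MALE_FRACTION          # same-sex pairs
    base_age = rng.normal(ref.AGE_MEAN, np.sqrt(ref.AGE_SD**2 - 16.0), size=n)
    age = np.repeat(base_age, 2) + rng.normal(0.0, 4.0, size=2 * n)
    migrant = rng.random(n) < cfg.migrant_pair_fraction
    loc1 = np.full(n, "urban", dtype=object)
    loc2 = np.where(migrant, "rural", "urban").astype(object)
    fat_shared = rng.normal(size=n)
    fat_score = 0.6 * np.repeat(fat_shared, 2) + 0.8 * rng.normal(size=2 * n)

    male_i = np.repeat(pair_male, 2).astype(float)
    urban_i = np.where(np.stack([loc1, loc2], axis=1).ravel() == "urban", 1.0, 0.0)
    z_age = (age - ref.AGE_MEAN) / ref.AGE_SD
    cov_term = ce["age"] * z_age + ce["male"] * male_i + ce["urban"] * urban_i
    cov_var = ce["age"] ** 2 + ce["male"] ** 2 * 0.25 + ce["urban"] ** 2 * 0.25

    # traits --------------------------------------------------------------
    g = np.empty((2 * n, m))
    g[0::2], g[1::2] = g1, g2
    g_centered = g - 2.0 * q
    shift_i = np.repeat(shift[subpop], 2)

    explained = cov_var + float(shift.var()) if cfg.n_subpops > 1 else cov_var
    traits: dict[str, np.ndarray] = {}
    for trait in ref.TRAIT_SCALE_MGDL:
        sel = np.array([t == trait for t in cfg.trait_per_snp])
        gterm = g_centered[:, sel] @ betas[sel] if sel.any() else 0.0
        gvar = float((2 * q[sel] * (1 - q[sel]) * betas[sel] ** 2).sum())
        noise_var = 1.0 - explained - gvar
        if noise_var <= 0:
            raise ValueError("systematic variance >= 1; reduce effects/shift")
        u = rng.normal(0.0, np.sqrt(cfg.icc * noise_var), size=n)
        e = rng.normal(0.0, np.sqrt((1 - cfg.icc) * noise_var), size=2 * n)
        traits[trait] = gterm + cov_term + shift_i + np.repeat(u, 2) + e

    # blood pressure / hypertension --------------------------------------
    # SBP/DBP scales solved so that P(SBP>=140 or DBP>=90) = 0.181 at
    # inter-pressure correlation 0.6
    bp_u = np.repeat(rng.normal(size=n), 2)
    z_sbp = np.sqrt(0.3) * bp_u + np.sqrt(0.7) * rng.normal(size=2 * n)
    sbp = 123.3 + 14.0 * z_sbp
    dbp = 79.0 + 9.0 * (0.6 * z_sbp + 0.8 * rng.normal(size=2 * n))
    if cfg.binary_logor_per_snp is not None:
        gamma = np.asarray(cfg.binary_logor_per_snp, dtype=float)
        eta = (logit(ref.HYPERTENSION_PREVALENCE) + g_centered @ gamma
               + cfg.binary_pair_sd * np.repeat(rng.normal(size=n), 2))
        hyp = (rng.random(2 * n) < expit(eta)).astype(int)
    else:
        hyp = ((sbp >= 140.0) | (dbp >= 90.0)).astype(int)

    # assemble ------------------------------------------------------------
    if cfg.geno_missing_rate > 0:
        g[rng.random(g.shape) < cfg.geno_missing_rate] = np.nan

    pair_ids = [f"P{i:05d}" for i in range(n)]
    cities = (list(ref.CITIES) if cfg.n_subpops == 4
              else [f"city{s + 1}" for s in range(cfg.n_subpops)])
    samples = pd.DataFrame({
        "fid": np.repeat(pair_ids, 2),
        "iid": [f"P{i:05d}_{k}" for i in range(n) for k in (1, 2)],
        "pair_id": np.repeat(pair_ids, 2),
        "sib_order": np.tile([1, 2], n),
        "age": np.round(age, 1),
        "sex": np.where(male_i == 1.0, "M", "F"),
        "location": np.stack([loc1, loc2], axis=1).ravel(),
        "city": np.repeat([cities[s] for s in subpop], 2),
        "fat_intake": np.where(fat_score <= np.median(fat_score), "low", "high"),
        "sbp": sbp, "dbp": dbp, "hypertension": hyp,
    })
    for trait, (mean, sd) in ref.TRAIT_SCALE_MGDL.items():
        samples[trait] = mean + sd * traits[trait]

    bases = "ACGT"
    snps = []
    for j in range(m):
        if j < len(ref.SNP_PANEL):
            p = ref.SNP_PANEL[j]
            snps.append(SnpMeta(snp=p["snp"], chrom=p["chrom"], pos=p["pos"],
                                minor=p["minor"], major=p["major"],
                                maf=float(q[j]), gene=p["gene"]))
        else:
            snps.append(SnpMeta(snp=f"snp{j + 1}", chrom=1, pos=10_000 * (j + 1),
                                minor=bases[j % 4], major=bases[(j + 1) % 4],
                                maf=float(q[j])))

    cohort = SibPairCohort(samples=samples, genotypes=g, snps=snps)
    cohort.standardize_traits()
    return cohort


# -- two-population LD panels ----------------------------------------------

@dataclass
class LDPanelConfig:
    """Two genotype-dosage panels sharing a SNP set, with population-specific
    target haplotype correlation matrices (symmetric, unit diagonal, PSD)."""

    n_subjects: tuple[int, int]
    allele_freqs: tuple[float, ...]
    target_corr_pop1: np.ndarray
    target_corr_pop2: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        m = len(self.allele_freqs)
        if not all(0.0 < f < 1.0 for f in self.allele_freqs):
            raise ValueError("allele frequencies must lie in (0, 1)")
        for name, mat in (("pop1", self.target_corr_pop1),
                          ("pop2", self.target_corr_pop2)):
            if mat is None:
                continue
            mat = np.asarray(mat, float)
            if mat.shape != (m, m):
                raise ValueError(f"{name}: correlation matrix shape {mat.shape} "
                                 f"does not match {m} allele frequencies")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"{name}: correlation matrix must be symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
                raise ValueError(f"{name}: correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(mat).min() < -1e-8:
                raise ValueError(f"{name}: correlation matrix must be positive semidefinite")


def _haplotype_dosages(n_subjects: int, freqs: np.ndarray, corr: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    m = len(freqs)
    jitter = 1e-10 * np.eye(m)
    chol = np.linalg.cholesky(corr + jitter)
    z = rng.standard_normal((2 * n_subjects, m)) @ chol.T
    alleles = (z < norm.ppf(freqs)).astype(float)
    return alleles[0::2] + alleles[1::2]


def simulate_ld_panels(config: LDPanelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Latent-Gaussian haplotypes thresholded at allele-frequency quantiles;
    two haplotypes sum to a dosage per subject.  Returns two
    (n_subjects, n_snps) dosage arrays."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.allele_freqs)
    c1 = np.asarray(config.target_corr_pop1, float)
    c2 = c1 if config.target_corr_pop2 is None else np.asarray(config.target_corr_pop2, float)
    p1 = _haplotype_dosages(config.n_subjects[0], freqs, c1, rng)
    p2 = _haplotype_dosages(config.n_subjects[1], freqs, c2, rng)
    return p1, p2


# -- derived phenotype ------------------------------------------------------

def friedewald_ldl(tc, hdl, tg):
    """LDL-C = TC − HDL-C − TG/5 (all mg/dl); valid only for TG < 400 mg/dl.

    Values with TG ≥ 400 are still returned but a warning is raised, since
    the formula's VLDL approximation breaks down there.
    """
    tc_a, hdl_a, tg_a = (np.asarray(x, dtype=float) for x in (tc, hdl, tg))
    if np.any(tg_a >= 400.0):
        warnings.warn("Friedewald LDL invalid where TG >= 400 mg/dl",
                      UserWarning, stacklevel=2)
    out = tc_a - hdl_a - tg_a / 5.0
    return float(out) if out.ndim == 0 else out
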