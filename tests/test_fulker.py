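"""Between/within decomposition and mixed-model fitting, checked against
closed forms, a REML grid oracle, and statsmodels' general mixed model."""

import numpy as np
import pytest
import statsmodels.api as sm

from sibassoc import (SeparationError, SimulationConfig, bonferroni_threshold,
                      decompose, fit_binary, fit_interaction, fit_quantitative,
                      render_threshold, simulate_cohort, stratified_screen)
from sibassoc.fulker import _build_design, reml_neg2loglik

from conftest import spawn_seeds


# -- decomposition ----------------------------------------------------------

def test_decompose_definition():
    assert decompose(2.0, 0.0) == (1.0, 1.0, -1.0)
    assert decompose(1.0, 1.0) == (1.0, 0.0, 0.0)


def test_decompose_exhaustive_reconstruction():
    for g1 in (0.0, 1.0, 2.0):
        for g2 in (0.0, 1.0, 2.0):
            b, w1, w2 = decompose(g1, g2)
            assert w1 + w2 == 0.0
            assert b + w1 == g1 and b + w2 == g2


def test_decompose_rejects_missing():
    with pytest.raises(ValueError):
        decompose(np.nan, 1.0)


# -- quantitative fits ------------------------------------------------------

def test_fixed_icc_zero_collapses_to_ols(small_cohort):
    """With the pair correlation pinned at 0 the GLS fit is ordinary least
    squares on the b/w design."""
    coh = small_cohort
    fit = fit_quantitative(coh, coh.snp_ids[0], "tg", fix_icc=0.0)
    d = _build_design(coh, coh.snp_ids[0], "z_tg",
                      ("age", "sex", "location", "city"))
    rows = np.concatenate([d.idx1, d.idx2, d.idx_single])
    ols = sm.OLS(d.y[rows], d.X[rows]).fit()
    iw = d.names.index("w")
    assert fit.beta_within == pytest.approx(ols.params[iw], abs=1e-6)
    assert fit.se_within == pytest.approx(ols.bse[iw], abs=1e-6)


def test_reml_maximizer_beats_grid(small_cohort):
    coh = small_cohort
    fit = fit_quantitative(coh, coh.snp_ids[0], "tg")
    d = _build_design(coh, coh.snp_ids[0], "z_tg",
                      ("age", "sex", "location", "city"))
    icc_hat = fit.varcomp.icc
    crit_hat = reml_neg2loglik(d, icc_hat)
    grid = np.linspace(0.0, 0.999, 101)
    assert crit_hat <= min(reml_neg2loglik(d, r) for r in grid) + 1e-8


def test_matches_statsmodels_mixedlm(small_cohort):
    """Our profiled REML equals the general-purpose mixed model fit."""
    coh = small_cohort
    fit = fit_quantitative(coh, coh.snp_ids[0], "tg")
    d = _build_design(coh, coh.snp_ids[0], "z_tg",
                      ("age", "sex", "location", "city"))
    rows = np.concatenate([d.idx1, d.idx2, d.idx_single])
    ml = sm.MixedLM(d.y[rows], d.X[rows], groups=d.pair_codes[rows]).fit(reml=True)
    iw = d.names.index("w")
    assert fit.beta_within == pytest.approx(ml.fe_params[iw], abs=1e-6)
    assert fit.se_within == pytest.approx(ml.bse_fe[iw], rel=1e-4)
    cov_re = float(np.asarray(ml.cov_re)[0, 0])
    assert fit.varcomp.icc == pytest.approx(cov_re / (cov_re + ml.scale), abs=1e-3)


def test_within_beta_invariant_to_pair_constant_offsets(small_cohort):
    """Adding any family-level constant to both sibs' traits leaves the
    within coefficient untouched (the substructure-immunity mechanism)."""
    coh = small_cohort
    base = fit_quantitative(coh, coh.snp_ids[0], "tg", covariates=())
    rng = np.random.default_rng(3)
    offsets = rng.normal(0, 5, size=coh.n_pairs)
    shifted = coh.samples.copy()
    pair_codes = shifted["pair_id"].map(
        {p: i for i, p in enumerate(shifted["pair_id"].unique())})
    shifted["z_tg"] = shifted["z_tg"] + offsets[pair_codes]
    coh2 = type(coh)(samples=shifted, genotypes=coh.genotypes, snps=coh.snps)
    fit2 = fit_quantitative(coh2, coh.snp_ids[0], "tg", covariates=())
    assert fit2.beta_within == pytest.approx(base.beta_within, abs=1e-10)


def test_minimum_pair_requirement():
    coh = simulate_cohort(SimulationConfig(n_pairs=20, seed=1))
    with pytest.raises(ValueError, match="complete pairs"):
        fit_quantitative(coh, coh.snp_ids[0], "tg")


def test_missing_genotypes_reduce_pairs():
    cfg = SimulationConfig(n_pairs=400, maf_per_snp=(0.3,),
                           beta_sd_per_snp=(0.0,), trait_per_snp=("tg",),
                           geno_missing_rate=0.1, seed=6)
    coh = simulate_cohort(cfg)
    fit = fit_quantitative(coh, coh.snp_ids[0], "tg")
    complete = (~np.isnan(coh.genotypes[coh.pair_rows()[:, 0], 0])
                & ~np.isnan(coh.genotypes[coh.pair_rows()[:, 1], 0])).sum()
    assert fit.n_pairs == complete < 400


# -- binary outcomes --------------------------------------------------------

def test_binary_null_estimates_centre_on_unit_odds():
    ors = []
    for seed in spawn_seeds(808, 60):
        cfg = SimulationConfig(n_pairs=400, maf_per_snp=(0.3,),
                               beta_sd_per_snp=(0.0,), trait_per_snp=("tg",),
                               binary_logor_per_snp=(0.0,), seed=seed)
        coh = simulate_cohort(cfg)
        ors.append(np.log(fit_binary(coh, coh.snp_ids[0]).odds_ratio))
    mean, se = np.mean(ors), np.std(ors, ddof=1) / np.sqrt(len(ors))
    assert abs(mean) < 3 * se


def test_binary_degenerate_outcome_rejected(small_cohort):
    coh = small_cohort
    bad = coh.samples.copy()
    bad["hypertension"] = 0
    coh2 = type(coh)(samples=bad, genotypes=coh.genotypes, snps=coh.snps)
    with pytest.raises(ValueError, match="degenerate outcome"):
        fit_binary(coh2, coh.snp_ids[0])


def test_binary_separation_flagged(small_cohort):
    coh = small_cohort
    sep = coh.samples.copy()
    sep["hypertension"] = (coh.genotypes[:, 0] >= 1).astype(int)
    coh2 = type(coh)(samples=sep, genotypes=coh.genotypes, snps=coh.snps)
    with pytest.raises(SeparationError):
        fit_binary(coh2, coh.snp_ids[0], covariates=())


# -- gene-environment interaction ------------------------------------------

def _plant_interaction(coh, delta, modifier_col="sex", level="M"):
    g = coh.genotypes[:, 0]
    m = (coh.samples[modifier_col] == level).astype(float).to_numpy()
    s = coh.samples.copy()
    s["z_custom"] = s["z_tg"] + delta * (g - np.nanmean(g)) * m
    return type(coh)(samples=s, genotypes=coh.genotypes, snps=coh.snps)


def test_interaction_recovers_planted_effect():
    """Sex-specific per-allele effect difference of 0.27 s.d. is recovered."""
    est = []
    for seed in spawn_seeds(505, 60):
        cfg = SimulationConfig(n_pairs=1500, maf_per_snp=(0.07,),
                               beta_sd_per_snp=(0.1,), trait_per_snp=("ldl",),
                               icc=0.3, seed=seed)
        coh = _plant_interaction(simulate_cohort(cfg), 0.27)
        est.append(fit_interaction(coh, coh.snp_ids[0], "z_custom",
                                   "sex").interaction_beta)
    mean, se = np.mean(est), np.std(est, ddof=1) / np.sqrt(len(est))
    assert abs(mean - 0.27) < 3 * se


def test_interaction_constant_modifier_rejected(small_cohort):
    coh = small_cohort
    allm = coh.samples.copy()
    allm["sex"] = "M"
    coh2 = type(coh)(samples=allm, genotypes=coh.genotypes, snps=coh.snps)
    with pytest.raises(ValueError, match="constant"):
        fit_interaction(coh2, coh.snp_ids[0], "tg", "sex")
    with pytest.raises(ValueError, match="modifier"):
        fit_interaction(coh, coh.snp_ids[0], "tg", "city")


def test_interaction_null_leaves_main_effect(small_cohort):
    """With no planted interaction the w x modifier term is null and the main
    within effect agrees with the plain fit."""
    coh = small_cohort
    plain = fit_quantitative(coh, coh.snp_ids[0], "tg")
    inter = fit_interaction(coh, coh.snp_ids[0], "tg", "fat_intake")
    assert inter.interaction_p > 0.001
    assert inter.beta_within == pytest.approx(plain.beta_within,
                                              abs=3 * plain.se_within)


# -- stratified screens -----------------------------------------------------

def test_stratified_homogeneous_cohort_agrees():
    coh = simulate_cohort(SimulationConfig(
        n_pairs=2000, maf_per_snp=(0.2,), beta_sd_per_snp=(0.15,),
        trait_per_snp=("tg",), seed=44))
    fits = stratified_screen(coh, coh.snp_ids[0], "tg", "fat_intake")
    (fa, fb) = fits["high"], fits["low"]
    joint_se = np.hypot(fa.se_within, fb.se_within)
    assert abs(fa.beta_within - fb.beta_within) < 3 * joint_se


def test_stratified_recovers_sex_specific_effects():
    """Planted per-allele effects 0.19 (males) / 0.17 (females)."""
    cfg = SimulationConfig(n_pairs=4000, maf_per_snp=(0.19,),
                           beta_sd_per_snp=(0.0,), trait_per_snp=("tg",),
                           icc=0.3, seed=55)
    coh = simulate_cohort(cfg)
    g = coh.genotypes[:, 0]
    m = (coh.samples["sex"] == "M").astype(float).to_numpy()
    s = coh.samples.copy()
    s["z_custom"] = s["z_tg"] + (g - g.mean()) * (0.19 * m + 0.17 * (1 - m))
    coh = type(coh)(samples=s, genotypes=coh.genotypes, snps=coh.snps)
    fits = stratified_screen(coh, coh.snp_ids[0], "z_custom", "sex")
    assert fits["M"].beta_within == pytest.approx(0.19, abs=3 * fits["M"].se_within)
    assert fits["F"].beta_within == pytest.approx(0.17, abs=3 * fits["F"].se_within)


def test_stratified_small_stratum_not_assessable(small_cohort):
    coh = small_cohort
    s = coh.samples.copy()
    pair_ids = s["pair_id"].unique()
    s["rare_label"] = np.where(s["pair_id"].isin(pair_ids[:5]), "yes", "no")
    coh2 = type(coh)(samples=s, genotypes=coh.genotypes, snps=coh.snps)
    fits = stratified_screen(coh2, coh.snp_ids[0], "tg", "rare_label")
    assert fits["yes"] is None and fits["no"] is not None


def test_migrant_pairs_drop_from_location_strata(panel_cohort):
    coh = panel_cohort
    fits = stratified_screen(coh, coh.snp_ids[0], "tg", "location")
    pr = coh.pair_rows()
    loc = coh.samples["location"].to_numpy()
    both_urban = ((loc[pr[:, 0]] == "urban") & (loc[pr[:, 1]] == "urban")).sum()
    assert fits["urban"].n_pairs <= both_urban
    assert fits.get("rural") is None or fits["rural"].n_pairs < coh.n_pairs


# -- multiple testing -------------------------------------------------------

def test_bonferroni_threshold_and_rendering():
    assert bonferroni_threshold(21) == pytest.approx(0.05 / 21)
    assert render_threshold(bonferroni_threshold(21)) == "0.002"
    assert bonferroni_threshold(1) == 0.05
    assert bonferroni_threshold(42) == pytest.approx(0.00119, abs=1e-5)
    assert render_threshold(bonferroni_threshold(42)) == "0.001"
    with pytest.raises(ValueError):
        bonferroni_threshold(0)
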