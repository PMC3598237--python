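"""End-to-end screen orchestration.

``run_screen`` composes the stages: SNP QC → per-SNP primary-trait fit →
secondary-trait screen → binary (hypertension) screen → optional stratified
and gene-environment analyses → effect translation → TSV reports.  All
randomness (simulation only) funnels through the single configured seed, so
a (config, seed) pair is byte-deterministic.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference as ref
from .cohort_io import (SibPairCohort, read_cohort, write_assoc_table,
                        write_cohort)
from .effect_metrics import summarize_effect
from .fulker import (DEFAULT_COVARIATES, FulkerFit, SeparationError,
                     bonferroni_threshold, fit_binary, fit_interaction,
                     fit_quantitative, render_threshold, stratified_screen)
from .ld_compare import permutation_test, write_ld_table
from .snp_qc import qc_screen, write_qc_table
from .synthetic_data import LDPanelConfig, SimulationConfig, simulate_cohort, \
    simulate_ld_panels

log = logging.getLogger("sibassoc")

LIPID_TRAITS = ("tg", "tc", "hdl", "ldl")


@dataclass
class RunConfig:
    """Screen configuration; ``primary_traits`` maps each SNP to exactly one
    lead trait, remaining lipid traits are its secondary screen."""

    primary_traits: dict[str, str] = field(default_factory=lambda: {
        s["snp"]: s["primary_trait"] for s in ref.SNP_PANEL})
    secondary_traits: tuple[str, ...] = LIPID_TRAITS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    modifiers: tuple[str, ...] = ()
    binary_outcomes: tuple[str, ...] = ("hypertension",)
    alpha: float = 0.05
    hwe_threshold: float = 0.001
    call_rate_threshold: float = 0.95
    n_tests_override: int | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in d:
                v = d[f]
                kwargs[f] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class ScreenResult:
    qc_reports: list
    assoc_rows: list[dict]
    binary_fits: list[FulkerFit]
    stratified: dict
    interactions: list[FulkerFit]
    thresholds: dict[str, tuple[float, str]]
    excluded_snps: list[str]


def _gene_of(cohort: SibPairCohort, snp: str) -> str:
    return cohort.snps[cohort.snp_index(snp)].gene


def run_screen(cohort: SibPairCohort, config: RunConfig | None = None
               ) -> ScreenResult:
    cfg = config or RunConfig()
    t0 = time.perf_counter()
    log.info("screen start: %d pairs, %d SNPs", cohort.n_pairs, len(cohort.snps))

    reports = qc_screen(cohort, hwe_threshold=cfg.hwe_threshold,
                        call_rate_threshold=cfg.call_rate_threshold)
    maf_by_snp = {r.snp: r.maf for r in reports}
    excluded = [r.snp for r in reports if r.excluded]
    for r in reports:
        if r.excluded:
            log.info("excluding %s (%s)", r.snp, r.exclusion_reason)
    passing = [s for s in cohort.snp_ids if s not in excluded
               and s in cfg.primary_traits]

    assoc_rows: list[dict] = []
    n_secondary_tests = 0
    for snp in passing:
        primary = cfg.primary_traits[snp]
        for trait in dict.fromkeys((primary, *cfg.secondary_traits)):
            fit = fit_quantitative(cohort, snp, trait, cfg.covariates)
            sd = ref.TRAIT_SCALE_MGDL.get(trait, (np.nan, np.nan))[1]
            eff = summarize_effect(fit, max(maf_by_snp[snp], 1e-6), sd)
            assoc_rows.append({
                "gene": _gene_of(cohort, snp), "snp": snp,
                "maf": maf_by_snp[snp], "trait": trait,
                "is_primary": trait == primary,
                "beta_sd": fit.beta_within, "ci_low": fit.ci_low,
                "ci_high": fit.ci_high, "p": fit.p_within,
                "n_pairs": fit.n_pairs,
                "beta_natural_units": eff.beta_natural,
                "va": eff.va, "pve": eff.pve,
            })
            if trait != primary:
                n_secondary_tests += 1

    binary_fits = []
    for snp in passing:
        for outcome in cfg.binary_outcomes:
            try:
                binary_fits.append(fit_binary(cohort, snp, outcome,
                                              cfg.covariates))
            except (ValueError, SeparationError) as exc:
                log.warning("binary fit skipped for %s/%s: %s", snp, outcome, exc)

    stratified, interactions = {}, []
    for mod in cfg.modifiers:
        for snp in passing:
            trait = cfg.primary_traits[snp]
            stratified[(snp, mod)] = stratified_screen(
                cohort, snp, trait, mod, cfg.covariates)
            interactions.append(fit_interaction(cohort, snp, trait, mod,
                                                cfg.covariates))

    n_sec = cfg.n_tests_override or max(n_secondary_tests, 1)
    thresholds = {}
    for name, n_tests in (("primary", max(len(passing), 1)),
                          ("secondary", n_sec)):
        thr = bonferroni_threshold(n_tests, cfg.alpha)
        thresholds[name] = (thr, render_threshold(thr))

    log.info("screen done in %.2fs: %d association rows, %d excluded SNP(s)",
             time.perf_counter() - t0, len(assoc_rows), len(excluded))
    return ScreenResult(qc_reports=reports, assoc_rows=assoc_rows,
                        binary_fits=binary_fits, stratified=stratified,
                        interactions=interactions, thresholds=thresholds,
                        excluded_snps=excluded)


def write_screen_outputs(result: ScreenResult, out_dir: str | Path
                         ) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "qc": write_qc_table(result.qc_reports, out / "qc.tsv"),
        "assoc": write_assoc_table(result.assoc_rows, out / "assoc.tsv"),
    }
    with open(out / "screen.log", "w") as fh:
        for name, (thr, rendered) in result.thresholds.items():
            fh.write(f"bonferroni_{name}\t{thr:.6g}\t(rendered {rendered})\n")
        fh.write(f"excluded_snps\t{','.join(result.excluded_snps) or '-'}\n")
    paths["log"] = out / "screen.log"
    return paths


def run_ld_compare(panel_cfgs: dict[str, LDPanelConfig], n_perm: int,
                   seed: int, out_path: str | Path | None = None):
    """Permutation LD comparison per locus; one derived child seed per locus
    keeps results independent of locus ordering."""
    results, n_snps = {}, {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(panel_cfgs))
    for child, (locus, pcfg) in zip(children, sorted(panel_cfgs.items())):
        p1, p2 = simulate_ld_panels(pcfg)
        results[locus] = permutation_test(
            p1, p2, n_perm=n_perm, seed=int(child.generate_state(1)[0] % 2**31))
        n_snps[locus] = p1.shape[1]
    if out_path is not None:
        write_ld_table(results, n_snps, out_path)
    return results


def simulate_and_write(sim: SimulationConfig, prefix: str | Path):
    cohort = simulate_cohort(sim)
    return write_cohort(cohort, prefix)


def load_cohort(ped, map_, pheno) -> SibPairCohort:
    return read_cohort(ped, map_, pheno)
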