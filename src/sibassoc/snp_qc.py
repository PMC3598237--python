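"""Per-SNP quality control: exact Hardy–Weinberg test, MAF, call rate,
duplicate concordance, and the exclusion screen.

HWE is tested on an unrelated subset (the first-listed sib of every pair —
deterministic, so reruns agree) both overall and within each stratum
(city by default); a SNP is excluded if any of those exact-test p-values
falls at or below the threshold (0.001 by default), or if its call rate is
below the call-rate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort_io import SibPairCohort


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Conditional exact Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity as the minor-allele count) that is
    no more probable than the observed one.  Probabilities are built by the
    standard ratio recurrence and normalized, so the test is symmetric in
    which homozygote class is labelled minor.  Monomorphic data give 1.0.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("no genotyped subjects")
    # work with the rarer allele
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    logp = np.empty(len(hets))
    logp[0] = 0.0
    for i in range(1, len(hets)):
        h = hets[i]  # log ratio P(h) / P(h-2), accumulated to avoid overflow
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i] = logp[i - 1] + np.log(4.0 * (rare_hom + 1) * (common_hom + 1)
                                       / (h * (h - 1)))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[(hets == n_het).argmax()]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n_hom_major, n_het, n_hom_minor) from a minor-allele dosage vector."""
    d = np.asarray(dosages, float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def duplicate_concordance(dosages_a, dosages_b) -> float | None:
    """Discordance fraction over pairwise-complete entries; None if none."""
    a, b = np.asarray(dosages_a, float), np.asarray(dosages_b, float)
    if a.shape != b.shape:
        raise ValueError("duplicate vectors must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    if not ok.any():
        return None
    return float((a[ok] != b[ok]).mean())


@dataclass
class SnpQCReport:
    snp: str
    maf: float
    call_rate: float
    hwe_p_overall: float | None
    hwe_p_per_stratum: dict = field(default_factory=dict)
    duplicate_discordance: float | None = None
    excluded: bool = False
    exclusion_reason: str = ""


def _hwe_or_none(dosages: np.ndarray) -> float | None:
    counts = genotype_counts(dosages)
    if sum(counts) < 2:
        return None  # not assessable; never triggers exclusion alone
    return hwe_exact(*counts)


def qc_screen(cohort: SibPairCohort, hwe_threshold: float = 0.001,
              call_rate_threshold: float = 0.95,
              stratify_by: str = "city") -> list[SnpQCReport]:
    """QC every SNP; a SNP is excluded when its exact HWE p-value is at or
    below ``hwe_threshold`` in the overall unrelated subset *or any stratum*,
    or its call rate (all individuals) is below ``call_rate_threshold``."""
    first_sib = cohort.pair_rows()[:, 0]
    strata = cohort.samples[stratify_by].to_numpy()
    reports = []
    for j, meta in enumerate(cohort.snps):
        d = cohort.genotypes[:, j]
        called = ~np.isnan(d)
        call_rate = float(called.mean())
        maf = float(d[called].mean() / 2.0) if called.any() else 0.0
        maf = min(maf, 1.0 - maf)

        du = d[first_sib]
        p_overall = _hwe_or_none(du)
        per_stratum = {}
        for s in pd.unique(strata[first_sib]):
            per_stratum[s] = _hwe_or_none(du[strata[first_sib] == s])

        excluded, reason = False, ""
        if call_rate < call_rate_threshold:
            excluded, reason = True, "call_rate"
        else:
            candidates = [("overall", p_overall)] + sorted(per_stratum.items())
            failing = [(p, name) for name, p in candidates
                       if p is not None and p <= hwe_threshold]
            if failing:
                excluded, reason = True, f"hwe:{min(failing)[1]}"
        reports.append(SnpQCReport(snp=meta.snp, maf=maf, call_rate=call_rate,
                                   hwe_p_overall=p_overall,
                                   hwe_p_per_stratum=per_stratum,
                                   excluded=excluded, exclusion_reason=reason))
    return reports


def write_qc_table(reports: Iterable[SnpQCReport], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in reports:
        row = {"snp": r.snp, "maf": r.maf, "call_rate": r.call_rate,
               "hwe_p_overall": r.hwe_p_overall,
               "duplicate_discordance": r.duplicate_discordance,
               "excluded": r.excluded, "exclusion_reason": r.exclusion_reason}
        for s, p in sorted(r.hwe_p_per_stratum.items()):
            row[f"hwe_p_{s}"] = p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
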