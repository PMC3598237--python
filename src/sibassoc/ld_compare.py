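"""LD-matrix comparison between two populations.

Pairwise LD is measured as composite r² — the squared Pearson correlation of
genotype dosages — which is phase-free and deterministic.  The overall
difference between two populations' LD matrices is Zaykin's z₂, the sum of
squared element-wise differences over unordered off-diagonal SNP pairs.
Significance comes from permuting population labels over the pooled
subjects (group sizes preserved) and recomputing z₂; the one-sided
empirical p-value uses the add-one rule p = (1 + #{z₂_perm ≥ z₂_obs}) /
(n_perm + 1), ties conservatively counted in the greater tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class LDMatrix:
    snp_ids: list[str]
    r2: np.ndarray          # symmetric, unit diagonal; NaN = not assessable
    n_subjects: int


@dataclass
class LDComparisonResult:
    observed_z2: float
    n_permutations: int
    count_greater: int      # permuted z2 >= observed (ties here)
    count_lower: int
    empirical_p: float


def _pairwise_r2(panel: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage columns; monomorphic columns get
    NaN off-diagonal; pairwise-complete when missing values are present."""
    panel = np.asarray(panel, float)
    if np.isnan(panel).any():
        r = pd.DataFrame(panel).corr(min_periods=2).to_numpy()
    else:
        sd = panel.std(axis=0)
        ok = sd > 0
        r = np.full((panel.shape[1],) * 2, np.nan)
        if ok.sum() >= 1:
            sub = np.corrcoef(panel[:, ok], rowvar=False)
            r[np.ix_(ok, ok)] = np.atleast_2d(sub)
    r2 = r ** 2
    np.fill_diagonal(r2, 1.0)
    return r2


def r2_matrix(panel: np.ndarray | pd.DataFrame,
              snp_ids: Sequence[str] | None = None) -> LDMatrix:
    """Composite-LD r² matrix for a (subjects × SNPs) dosage panel."""
    if isinstance(panel, pd.DataFrame):
        snp_ids = snp_ids or [str(c) for c in panel.columns]
        panel = panel.to_numpy(float)
    panel = np.asarray(panel, float)
    if panel.ndim != 2 or panel.shape[0] < 2:
        raise ValueError("panel must be (subjects >= 2) x SNPs")
    ids = list(snp_ids) if snp_ids else [f"snp{j + 1}" for j in range(panel.shape[1])]
    return LDMatrix(snp_ids=ids, r2=_pairwise_r2(panel), n_subjects=panel.shape[0])


def z2_statistic(m1: LDMatrix, m2: LDMatrix) -> float:
    """Sum over unordered off-diagonal pairs of (r²₁ − r²₂)²; entries not
    assessable in either matrix are skipped in both."""
    if m1.snp_ids != m2.snp_ids:
        raise ValueError("LD matrices cover different SNP sets")
    iu = np.triu_indices(len(m1.snp_ids), k=1)
    a, b = m1.r2[iu], m2.r2[iu]
    ok = ~np.isnan(a) & ~np.isnan(b)
    return float(np.sum((a[ok] - b[ok]) ** 2))


def empirical_p_from_counts(n_greater: int, n_permutations: int) -> float:
    """Add-one one-sided empirical p from a permutation greater-count."""
    if n_permutations < 1 or n_greater < 0 or n_greater > n_permutations:
        raise ValueError("invalid permutation counts")
    return (n_greater + 1) / (n_permutations + 1)


def _fast_r2_offdiag(sub: np.ndarray, iu: tuple) -> np.ndarray:
    """Off-diagonal r² vector for a complete (no-NaN) dosage block;
    monomorphic columns yield NaN entries."""
    xc = sub - sub.mean(axis=0)
    ss = np.einsum("ij,ij->j", xc, xc)
    cov = xc.T @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (cov * cov) / np.outer(ss, ss)
    r2[:, ss == 0] = np.nan
    r2[ss == 0, :] = np.nan
    return r2[iu]


def _z2_of_split(pooled: np.ndarray, idx1: np.ndarray, idx2: np.ndarray,
                 iu: tuple, dense: bool) -> float:
    if dense:
        a = _fast_r2_offdiag(pooled[idx1], iu)
        b = _fast_r2_offdiag(pooled[idx2], iu)
    else:
        a = _pairwise_r2(pooled[idx1])[iu]
        b = _pairwise_r2(pooled[idx2])[iu]
    ok = ~np.isnan(a) & ~np.isnan(b)
    return float(np.sum((a[ok] - b[ok]) ** 2))


def permutation_test(panel1: np.ndarray, panel2: np.ndarray,
                     n_perm: int = 100_000, seed: int | None = None,
                     snp_ids: Sequence[str] | None = None) -> LDComparisonResult:
    """Label-permutation test of overall LD difference between two panels.

    Reproducible bit-for-bit given (seed, n_perm).  Group sizes are
    preserved in every permutation.
    """
    p1 = np.asarray(panel1, float)
    p2 = np.asarray(panel2, float)
    if p1.shape[1] != p2.shape[1]:
        raise ValueError("panels must share the SNP set")
    if p1.shape[0] < 2 or p2.shape[0] < 2:
        raise ValueError("each population needs at least 2 subjects")

    m1 = r2_matrix(p1, snp_ids)
    m2 = r2_matrix(p2, snp_ids)
    z2_obs = z2_statistic(m1, m2)

    pooled = np.vstack([p1, p2])
    n1 = p1.shape[0]
    dense = not np.isnan(pooled).any()
    iu = np.triu_indices(pooled.shape[1], k=1)
    rng = np.random.default_rng(seed)
    greater = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        z2p = _z2_of_split(pooled, perm[:n1], perm[n1:], iu, dense)
        if z2p >= z2_obs:
            greater += 1
    return LDComparisonResult(
        observed_z2=z2_obs, n_permutations=n_perm,
        count_greater=greater, count_lower=n_perm - greater,
        empirical_p=empirical_p_from_counts(greater, n_perm),
    )


def write_ld_table(results: dict[str, LDComparisonResult],
                   n_snps: dict[str, int], path: str | Path) -> Path:
    """Result table: locus, SNP count, greater/lower counts, empirical p."""
    rows = [{"locus": k, "n_snps": n_snps.get(k, ""),
             "observed_z2": r.observed_z2,
             "n_permutations": r.n_permutations,
             "count_greater": r.count_greater, "count_lower": r.count_lower,
             "empirical_p": r.empirical_p}
            for k, r in results.items()]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
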