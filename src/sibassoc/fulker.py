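"""Between/within sib-pair (Fulker) association models.

Each sib's dosage g is recoded into the pair mean b = (g1+g2)/2 and the
deviation w = g − b.  Regressing the trait on b and w separately splits the
association into a between-family component (confounded by anything that
differs across families, population substructure included) and a
within-family component (a pure sibling contrast, immune to substructure).
Inference is drawn on the within coefficient.

Quantitative traits use the linear mixed model

    y_ij = mu + beta_b * b_j + beta_w * w_ij + covariates + u_j + e_ij,
    u_j ~ N(0, sigma2_pair),  e_ij ~ N(0, sigma2_resid),

fitted by REML profiled over the intraclass correlation
icc = sigma2_pair / (sigma2_pair + sigma2_resid): for fixed icc the pair
covariance is known up to scale, so the fixed effects come from generalized
least squares via an exact per-pair whitening transform, and a scalar
search over icc in [0, 0.999] maximizes the restricted likelihood.  With
two-member clusters this profiling is exact.  Wald normal inference
throughout (samples are in the thousands).

Binary outcomes use a logistic model on the same b/w design with a
cluster-robust (sandwich) covariance grouped on pair id; the reported
effect is the within-pair odds ratio exp(beta_w).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .cohort_io import SibPairCohort

Z975 = norm.ppf(0.975)

DEFAULT_COVARIATES = ("age", "sex", "location", "city")

ICC_UPPER = 0.999


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit; no finite estimate exists."""


# -- genotype decomposition -------------------------------------------------

def decompose(g1: float, g2: float) -> tuple[float, float, float]:
    """Fulker coding of one pair: (b, w1, w2) with b=(g1+g2)/2, w_i=g_i−b.

    Both dosages must be non-missing; pairs with a missing dosage are
    excluded from that SNP's analysis upstream.
    """
    if np.isnan(g1) or np.isnan(g2):
        raise ValueError("decompose requires both sib dosages non-missing")
    b = (g1 + g2) / 2.0
    return b, g1 - b, g2 - b


@dataclass
class VarianceComponents:
    sigma2_pair: float
    sigma2_resid: float

    @property
    def icc(self) -> float:
        tot = self.sigma2_pair + self.sigma2_resid
        return self.sigma2_pair / tot if tot > 0 else 0.0


@dataclass
class FulkerFit:
    """One SNP-trait model fit; within-pair inference is the headline."""

    snp: str
    trait: str
    beta_within: float
    se_within: float
    ci_low: float
    ci_high: float
    p_within: float
    beta_between: float | None = None
    se_between: float | None = None
    p_between: float | None = None
    varcomp: VarianceComponents | None = None
    n_pairs: int = 0
    n_individuals: int = 0
    covariate_coefs: dict = field(default_factory=dict)
    boundary: bool = False
    # binary-outcome fields
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    # gene-environment interaction fields (coefficient on w x modifier)
    modifier: str | None = None
    interaction_beta: float | None = None
    interaction_se: float | None = None
    interaction_ci: tuple[float, float] | None = None
    interaction_p: float | None = None


# -- design assembly --------------------------------------------------------

_BINARY_CODING = {"sex": ("M", 1.0), "location": ("urban", 1.0),
                  "fat_intake": ("high", 1.0)}


def _encode_covariates(samples: pd.DataFrame, covariates: Sequence[str]
                       ) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for c in covariates:
        v = samples[c]
        if c in _BINARY_CODING:
            level, _ = _BINARY_CODING[c]
            cols.append((v == level).astype(float).to_numpy())
            names.append(f"{c}[{level}]")
        elif v.dtype.kind in "if":
            cols.append(v.astype(float).to_numpy())
            names.append(c)
        else:  # categorical: one-hot, first (sorted) level as reference
            levels = sorted(v.dropna().unique())
            for lev in levels[1:]:
                cols.append((v == lev).astype(float).to_numpy())
                names.append(f"{c}[{lev}]")
    if not cols:
        return np.empty((len(samples), 0)), []
    return np.column_stack(cols), names


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray
    names: list[str]
    idx1: np.ndarray       # first member of each complete pair (row index)
    idx2: np.ndarray
    idx_single: np.ndarray  # rows whose sibling dropped out (trait/covariate)
    pair_codes: np.ndarray  # per-row cluster labels (for sandwich fits)
    n_pairs: int


def _build_design(cohort: SibPairCohort, snp: str, ycol: str,
                  covariates: Sequence[str],
                  extra: dict[str, np.ndarray] | None = None,
                  min_pairs: int = 30) -> _Design:
    """Rows with complete genotype pairs and non-missing y/covariates.

    Missing handling: a pair missing either sib's dosage is excluded for the
    SNP (w undefined); an individual missing trait or covariate drops only
    that row, the sibling remaining as a singleton cluster (its w is still
    defined from the genotypes).
    """
    pr = cohort.pair_rows()
    j = cohort.snp_index(snp)
    g1, g2 = cohort.genotypes[pr[:, 0], j], cohort.genotypes[pr[:, 1], j]
    pair_ok = ~np.isnan(g1) & ~np.isnan(g2)

    n = cohort.n_individuals
    b = np.full(n, np.nan)
    w = np.full(n, np.nan)
    bp = (g1 + g2) / 2.0
    b[pr[:, 0]] = bp
    b[pr[:, 1]] = bp
    w[pr[:, 0]] = g1 - bp
    w[pr[:, 1]] = g2 - bp
    geno_ok = np.zeros(n, bool)
    geno_ok[pr[pair_ok].ravel()] = True

    y = pd.to_numeric(cohort.samples[ycol], errors="coerce").to_numpy(float)
    C, cov_names = _encode_covariates(cohort.samples, covariates)
    row_ok = geno_ok & ~np.isnan(y)
    if C.shape[1]:
        row_ok &= ~np.isnan(C).any(axis=1)

    cols = [np.ones(n), b, w]
    names = ["intercept", "b", "w"]
    if C.shape[1]:
        cols.append(C)
        names += cov_names
    for nm, col in (extra or {}).items():
        cols.append(np.asarray(col, float))
        names.append(nm)
    X = np.column_stack(cols)
    row_ok &= ~np.isnan(X).any(axis=1)

    both = row_ok[pr[:, 0]] & row_ok[pr[:, 1]]
    one = row_ok[pr[:, 0]] ^ row_ok[pr[:, 1]]
    idx1, idx2 = pr[both, 0], pr[both, 1]
    idx_single = np.concatenate([pr[one & row_ok[pr[:, 0]], 0],
                                 pr[one & row_ok[pr[:, 1]], 1]])
    n_pairs = int(both.sum())
    if n_pairs < min_pairs:
        raise ValueError(
            f"{snp}/{ycol}: only {n_pairs} complete pairs after pairwise "
            f"deletion (need >= {min_pairs})")

    rows = np.concatenate([idx1, idx2, idx_single])
    # drop covariate columns constant over the analysis rows (singular design)
    keep = [0]
    for k in range(1, X.shape[1]):
        if np.ptp(X[rows, k]) > 0:
            keep.append(k)
        else:
            warnings.warn(f"dropping constant column '{names[k]}' from design",
                          UserWarning, stacklevel=3)
    X = X[:, keep]
    names = [names[k] for k in keep]

    pair_codes = pd.factorize(cohort.samples["pair_id"])[0]
    return _Design(y=y, X=X, names=names, idx1=idx1, idx2=idx2,
                   idx_single=idx_single, pair_codes=pair_codes,
                   n_pairs=n_pairs)


# -- REML over icc ----------------------------------------------------------

def _whiten(d: _Design, icc: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact GLS whitening for pair correlation icc: the pair sum and
    difference are independent with variances 2(1+icc) and 2(1−icc)."""
    a = 1.0 / np.sqrt(2.0 * (1.0 + icc))
    c = 1.0 / np.sqrt(2.0 * (1.0 - icc))
    Xs = a * (d.X[d.idx1] + d.X[d.idx2])
    Xd = c * (d.X[d.idx1] - d.X[d.idx2])
    ys = a * (d.y[d.idx1] + d.y[d.idx2])
    yd = c * (d.y[d.idx1] - d.y[d.idx2])
    Xt = np.concatenate([Xs, Xd, d.X[d.idx_single]])
    yt = np.concatenate([ys, yd, d.y[d.idx_single]])
    return Xt, yt


def _gls(d: _Design, icc: float):
    Xt, yt = _whiten(d, icc)
    beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    xtx = Xt.T @ Xt
    return beta, rss, xtx, len(yt), rank


def reml_neg2loglik(d: _Design, icc: float) -> float:
    """−2 × restricted log-likelihood at fixed icc, up to an additive
    constant, with the scale parameter profiled out."""
    beta, rss, xtx, nrow, _ = _gls(d, icc)
    p = d.X.shape[1]
    logdet_r = len(d.idx1) * np.log((1.0 + icc) * (1.0 - icc))
    sign, logdet_x = np.linalg.slogdet(xtx)
    return (nrow - p) * np.log(rss) + logdet_r + logdet_x


def fit_quantitative(cohort: SibPairCohort, snp: str, trait: str,
                     covariates: Sequence[str] = DEFAULT_COVARIATES,
                     fix_icc: float | None = None,
                     min_pairs: int = 30) -> FulkerFit:
    """REML fit of the between/within mixed model for one SNP and trait.

    ``trait`` may name a raw trait (its pre-computed z-score column
    ``z_<trait>`` is used, per the standardize-once rule) or any numeric
    column directly.  ``fix_icc`` pins the variance ratio instead of
    profiling (used for diagnostics and testing).
    """
    ycol = f"z_{trait}" if f"z_{trait}" in cohort.samples.columns else trait
    d = _build_design(cohort, snp, ycol, covariates, min_pairs=min_pairs)

    if fix_icc is not None:
        icc = float(fix_icc)
        boundary = False
    else:
        res = minimize_scalar(lambda r: reml_neg2loglik(d, r),
                              bounds=(0.0, ICC_UPPER), method="bounded",
                              options={"xatol": 1e-6})
        icc = float(res.x)
        boundary = icc < 1e-4 or icc > ICC_UPPER - 1e-4
        if not res.success:  # pragma: no cover - bounded search rarely fails
            warnings.warn("REML icc search did not converge; boundary "
                          "solution reported", UserWarning)
            boundary = True

    beta, rss, xtx, nrow, rank = _gls(d, icc)
    dof = nrow - d.X.shape[1]
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.pinv(xtx)
    se = np.sqrt(np.diag(cov))

    iw, ib = d.names.index("w"), d.names.index("b")
    bw, sw = float(beta[iw]), float(se[iw])
    z = bw / sw if sw > 0 else 0.0
    fit = FulkerFit(
        snp=snp, trait=trait,
        beta_within=bw, se_within=sw,
        ci_low=bw - Z975 * sw, ci_high=bw + Z975 * sw,
        p_within=float(min(1.0, 2.0 * norm.sf(abs(z)))) if sw > 0 else 1.0,
        beta_between=float(beta[ib]), se_between=float(se[ib]),
        p_between=float(min(1.0, 2.0 * norm.sf(abs(beta[ib] / se[ib]))))
        if se[ib] > 0 else 1.0,
        varcomp=VarianceComponents(sigma2_pair=icc * sigma2,
                                   sigma2_resid=(1.0 - icc) * sigma2),
        n_pairs=d.n_pairs, n_individuals=nrow,
        covariate_coefs={nm: float(v) for nm, v in zip(d.names, beta)
                         if nm not in ("b", "w")},
        boundary=boundary,
    )
    return fit


# -- binary outcomes --------------------------------------------------------

def fit_binary(cohort: SibPairCohort, snp: str, outcome: str = "hypertension",
               covariates: Sequence[str] = DEFAULT_COVARIATES,
               min_pairs: int = 30) -> FulkerFit:
    """Logistic b/w model with pair-clustered sandwich covariance.

    Returns the within-pair odds ratio exp(beta_w) with Wald CI.  Raises
    ``ValueError`` for a degenerate (single-class) outcome and
    :class:`SeparationError` when the likelihood has no finite maximum.
    """
    d = _build_design(cohort, snp, outcome, covariates, min_pairs=min_pairs)
    rows = np.concatenate([d.idx1, d.idx2, d.idx_single])
    y, X = d.y[rows], d.X[rows]
    if len(np.unique(y)) < 2:
        raise ValueError(f"degenerate outcome '{outcome}': only one class present")
    groups = d.pair_codes[rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, cov_type="cluster",
                                     cov_kwds={"groups": groups}, maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"{snp}/{outcome}: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 15:
        raise SeparationError(f"{snp}/{outcome}: separation suspected, "
                              "no finite estimate")

    iw, ib = d.names.index("w"), d.names.index("b")
    bw, sw = float(res.params[iw]), float(res.bse[iw])
    z = bw / sw if sw > 0 else 0.0
    return FulkerFit(
        snp=snp, trait=outcome,
        beta_within=bw, se_within=sw,
        ci_low=bw - Z975 * sw, ci_high=bw + Z975 * sw,
        p_within=float(min(1.0, 2.0 * norm.sf(abs(z)))),
        beta_between=float(res.params[ib]), se_between=float(res.bse[ib]),
        p_between=float(min(1.0, 2.0 * norm.sf(abs(res.params[ib] / res.bse[ib])))),
        n_pairs=d.n_pairs, n_individuals=len(rows),
        covariate_coefs={nm: float(v) for nm, v in zip(d.names, res.params)
                         if nm not in ("b", "w")},
        odds_ratio=float(np.exp(bw)),
        or_ci_low=float(np.exp(bw - Z975 * sw)),
        or_ci_high=float(np.exp(bw + Z975 * sw)),
    )


# -- gene-environment interaction ------------------------------------------

def fit_interaction(cohort: SibPairCohort, snp: str, trait: str,
                    modifier: str,
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    min_pairs: int = 30) -> FulkerFit:
    """Adds w×modifier and b×modifier to the fixed effects; inference is
    reported on the w×modifier coefficient.  The modifier must be one of
    the binary factors (sex, location, fat_intake) with both levels present.
    """
    if modifier not in _BINARY_CODING:
        raise ValueError(f"modifier must be one of {sorted(_BINARY_CODING)}")
    level, _ = _BINARY_CODING[modifier]
    m = (cohort.samples[modifier] == level).astype(float).to_numpy()
    if np.ptp(m) == 0:
        raise ValueError(f"modifier '{modifier}' is constant")

    ycol = f"z_{trait}" if f"z_{trait}" in cohort.samples.columns else trait
    covs = list(covariates)
    if modifier not in covs:
        covs.append(modifier)  # main effect must accompany the interaction

    # b/w columns needed before interaction products: build via a first pass
    base = _build_design(cohort, snp, ycol, covs, min_pairs=min_pairs)
    b_col = base.X[:, base.names.index("b")]
    w_col = base.X[:, base.names.index("w")]
    d = _build_design(cohort, snp, ycol, covs,
                      extra={"w_x_mod": w_col * m, "b_x_mod": b_col * m},
                      min_pairs=min_pairs)

    res = minimize_scalar(lambda r: reml_neg2loglik(d, r),
                          bounds=(0.0, ICC_UPPER), method="bounded",
                          options={"xatol": 1e-6})
    icc = float(res.x)
    beta, rss, xtx, nrow, _ = _gls(d, icc)
    sigma2 = rss / (nrow - d.X.shape[1])
    se = np.sqrt(np.diag(sigma2 * np.linalg.pinv(xtx)))

    iw = d.names.index("w")
    ix = d.names.index("w_x_mod")
    bx, sx = float(beta[ix]), float(se[ix])
    zx = bx / sx if sx > 0 else 0.0
    fit = FulkerFit(
        snp=snp, trait=trait,
        beta_within=float(beta[iw]), se_within=float(se[iw]),
        ci_low=float(beta[iw] - Z975 * se[iw]),
        ci_high=float(beta[iw] + Z975 * se[iw]),
        p_within=float(min(1.0, 2.0 * norm.sf(abs(beta[iw] / se[iw])))),
        varcomp=VarianceComponents(icc * sigma2, (1.0 - icc) * sigma2),
        n_pairs=d.n_pairs, n_individuals=nrow,
        modifier=modifier,
        interaction_beta=bx, interaction_se=sx,
        interaction_ci=(bx - Z975 * sx, bx + Z975 * sx),
        interaction_p=float(min(1.0, 2.0 * norm.sf(abs(zx)))),
    )
    return fit


# -- stratified screens -----------------------------------------------------

def stratified_screen(cohort: SibPairCohort, snp: str, trait: str,
                      stratify_by: str,
                      covariates: Sequence[str] = DEFAULT_COVARIATES,
                      min_pairs: int = 30) -> dict[str, FulkerFit | None]:
    """Independent fits per stratum of ``stratify_by``.

    A pair contributes to a stratum only when both sibs carry that level
    (migrant pairs straddling urban/rural therefore drop from the location
    strata — a deliberate, conservative reading of individual-level
    stratification).  Strata with fewer than ``min_pairs`` complete pairs
    are reported as not-assessable (None) and the screen continues.
    """
    covs = [c for c in covariates if c != stratify_by]
    lv = cohort.samples[stratify_by]
    pr = cohort.pair_rows()
    out: dict[str, FulkerFit | None] = {}
    for level in sorted(lv.dropna().unique()):
        both = (lv.iloc[pr[:, 0]].to_numpy() == level) & \
               (lv.iloc[pr[:, 1]].to_numpy() == level)
        pair_ids = cohort.samples["pair_id"].iloc[pr[both, 0]]
        if both.sum() < min_pairs:
            out[str(level)] = None
            continue
        sub = cohort.subset_pairs(pair_ids)
        try:
            out[str(level)] = fit_quantitative(sub, snp, trait, covs,
                                               min_pairs=min_pairs)
        except ValueError:
            out[str(level)] = None
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha / n_tests, unrounded; render with :func:`render_threshold`."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def render_threshold(threshold: float) -> str:
    """One-significant-figure rendering used in report headers (0.00238 ->
    '0.002')."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = int(np.floor(np.log10(threshold)))
    scale = 10.0 ** exponent
    return np.format_float_positional(np.floor(threshold / scale) * scale,
                                      trim="-")
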