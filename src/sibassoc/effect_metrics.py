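"""Post-fit effect translation.

A within-pair coefficient beta is estimated on the standardized (z-score)
trait; multiplying by the trait's mg/dl standard deviation gives the
per-allele effect in natural units.  The locus's additive genetic variance
on the standardized scale is Va = 2pq*beta^2 (p = major, q = minor allele
frequency), which for a unit-variance trait is also the proportion of
phenotypic variance explained.  This is the additive special case of the
classical genotype-means formula Va = 2pq[p(X11−X12) + q(X12−X22)]^2.

Power uses a 1-df chi-square approximation for unrelated samples with
noncentrality n*pve/(1−pve); it is an explicitly approximate, documentation-
grade calculation, not part of the headline analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2, ncx2

from .fulker import FulkerFit


@dataclass
class EffectSummary:
    beta_sd: float
    trait_sd: float
    beta_natural: float     # mg/dl per minor allele
    va: float               # additive variance, standardized scale
    pve: float              # proportion of phenotypic variance explained


def to_natural_units(beta_sd: float, trait_sd: float) -> float:
    """Per-allele effect in mg/dl: beta (s.d. units) x trait SD (mg/dl)."""
    if trait_sd <= 0:
        raise ValueError("trait_sd must be positive")
    return beta_sd * trait_sd


def additive_variance(maf: float, beta_w: float) -> tuple[float, float]:
    """(Va, pve) with Va = 2pq*beta^2, q = maf; pve = Va on a unit-variance
    trait."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    q = maf
    p = 1.0 - q
    va = 2.0 * p * q * beta_w ** 2
    return va, va


def classical_additive_variance(maf: float, x11: float, x12: float,
                                x22: float) -> float:
    """Genotype-means form Va = 2pq[p(X11−X12) + q(X12−X22)]^2, where X11,
    X12, X22 are trait means of major-homozygote, heterozygote and
    minor-homozygote classes.  Reduces to 2pq*beta^2 under additivity."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    q = maf
    p = 1.0 - q
    return 2.0 * p * q * (p * (x11 - x12) + q * (x12 - x22)) ** 2


def approx_power(pve: float, n_individuals: int, alpha: float = 0.05) -> float:
    """P(chi2_1(ncp) > chi2_1 critical value) with ncp = n*pve/(1−pve)."""
    if not 0.0 <= pve < 1.0:
        raise ValueError("pve must lie in [0, 1)")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    crit = chi2.ppf(1.0 - alpha, df=1)
    ncp = n_individuals * pve / (1.0 - pve)
    if ncp == 0.0:
        return alpha
    return float(ncx2.sf(crit, df=1, nc=ncp))


def summarize_effect(fit: FulkerFit, maf: float, trait_sd: float
                     ) -> EffectSummary:
    """Natural-unit and variance-explained summary for a quantitative fit."""
    va, pve = additive_variance(maf, fit.beta_within)
    return EffectSummary(beta_sd=fit.beta_within, trait_sd=trait_sd,
                         beta_natural=to_natural_units(fit.beta_within, trait_sd),
                         va=va, pve=pve)
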