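"""Exact binomial machinery shared by the enrichment analyses.

Two primitives recur throughout: the minimum-likelihood two-sided exact
binomial test (the convention of R's ``binom.test``) and the Clopper-Pearson
confidence interval. Both are delegated to the established implementations
(scipy / statsmodels) behind a thin validating surface, plus the five-bin
minor-allele-frequency (MAF) partition used everywhere downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MafBin",
    "MAF_BINS",
    "maf_of",
    "assign_bin",
    "binom_two_sided",
    "clopper_pearson",
]


@dataclass(frozen=True, order=True)
class MafBin:
    """One of the five equal MAF intervals partitioning (0, 0.5]."""

    index: int
    lower: float
    upper: float

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2.0

    @property
    def label(self) -> str:
        return f"({self.lower:g}-{self.upper:g})"


#: The five equal MAF intervals: (0-0.1), (0.1-0.2), ..., (0.4-0.5).
MAF_BINS: tuple[MafBin, ...] = tuple(
    MafBin(i, i / 10.0, (i + 1) / 10.0) for i in range(5)
)


def maf_of(risk_allele_frequency: float) -> float:
    """Minor allele frequency implied by a risk allele frequency: min(f, 1-f)."""
    f = risk_allele_frequency
    if f is None or (isinstance(f, float) and math.isnan(f)):
        raise ValueError("risk allele frequency is missing")
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"risk allele frequency must be in [0, 1], got {f}")
    return min(f, 1.0 - f)


def assign_bin(maf: float) -> MafBin:
    """Map a MAF to its bin: half-open [lower, upper), last bin closed at 0.5.

    A MAF of exactly 0 is monomorphic and carries no association; it is
    rejected here and should be excluded (and counted) upstream.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
    # 1e-12 guard: decimal boundaries like 0.3 sit one ulp below their value
    return MAF_BINS[min(int(math.floor(maf * 10.0 + 1e-12)), 4)]


def binom_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial P-value by the minimum-likelihood rule.

    Sums P(X = j) over every outcome j no more likely than the observed k
    under Binomial(n, p0), capped at 1. At p0 = 0.5 this coincides with
    doubling the smaller tail.
    """
    _check_kn(k, n)
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    return float(_sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def clopper_pearson(
    k: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion."""
    _check_kn(k, n)
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if n == 0:
        raise ValueError("n must be positive")
    lo, hi = proportion_confint(k, n, alpha=1.0 - confidence, method="beta")
    return float(lo), float(hi)


def _check_kn(k: int, n: int) -> None:
    if int(k) != k or int(n) != n:
        raise ValueError("k and n must be integers")
    if n < 0 or not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
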