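"""Deterministic simulation of case-control association tests under a
penetrance model.

The question the simulator answers: at the same effect size, is an
association test more significant when the *minor* allele is the risk allele
than when the *major* allele is? The chain is fully deterministic:

1. penetrances (d1, d2, d3) for 0/1/2 risk alleles from a baseline penetrance
   d1 and a common per-allele odds ratio r;
2. genotype distributions in cases and controls under Hardy-Weinberg
   equilibrium at risk-allele frequency q;
3. expected genotype counts for the chosen cohort sizes, rounded to integers;
4. a logistic regression of disease status on risk-allele dose (0/1/2), whose
   Wald (or likelihood-ratio) P-value for the dose coefficient is the result.

Running the chain with q = p (minor allele is the risk allele) and q = 1 - p
(major allele is) yields the paired comparison; the S' statistic condenses a
whole frequency sweep of such pairs into one number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as _sps
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "PenetranceModel",
    "GenotypeDistribution",
    "CohortCounts",
    "AssociationTestResult",
    "ScenarioComparison",
    "RelativeDifferenceGrid",
    "DEFAULT_P_GRID",
    "penetrances_from_or",
    "genotype_distribution",
    "expected_counts",
    "association_pvalue",
    "scenario_pair",
    "scenario_curves",
    "relative_difference",
    "s_prime",
    "sweep_r_d1",
    "sweep_r_nc",
]

#: Minor-allele frequencies 0.05, 0.10, ..., 0.50 used for the S' curves.
DEFAULT_P_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.05, 2))

_P_FLOOR = 1e-320  # keeps log10 finite without disturbing any comparison


def penetrances_from_or(d1: float, r: float) -> tuple[float, float]:
    """Penetrances d2, d3 implied by baseline d1 and per-allele odds ratio r.

    Chains the odds identity odds(d2) = r * odds(d1), odds(d3) = r * odds(d2):

        d2 = d1 r / (1 - d1 + r d1),   d3 = d2 r / (1 - d2 + r d2)
    """
    if not (0.0 < d1 < 1.0):
        raise ValueError(f"d1 must be in (0, 1), got {d1}")
    if r <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {r}")
    d2 = d1 * r / (1.0 - d1 + r * d1)
    d3 = d2 * r / (1.0 - d2 + r * d2)
    return d2, d3


@dataclass(frozen=True)
class PenetranceModel:
    """Penetrances for 0/1/2 risk alleles plus the generating parameters."""

    d1: float
    d2: float
    d3: float
    r: float
    q: float
    risk_is_minor: bool = True

    @classmethod
    def from_odds_ratio(
        cls, d1: float, r: float, q: float, risk_is_minor: bool = True
    ) -> "PenetranceModel":
        d2, d3 = penetrances_from_or(d1, r)
        return cls(d1=d1, d2=d2, d3=d3, r=r, q=q, risk_is_minor=risk_is_minor)

    @property
    def penetrances(self) -> tuple[float, float, float]:
        return (self.d1, self.d2, self.d3)


@dataclass(frozen=True)
class GenotypeDistribution:
    """Relative genotype proportions (0/1/2 risk alleles) in cases and controls."""

    case_props: tuple[float, float, float]
    control_props: tuple[float, float, float]


def genotype_distribution(
    q: float, d1: float, d2: float, d3: float
) -> GenotypeDistribution:
    """Case/control genotype proportions under HWE at risk-allele frequency q.

    Genotypes are indexed by risk-allele count, with HWE frequencies
    (1-q)^2, 2q(1-q), q^2. Case proportions weight each genotype by its
    penetrance, control proportions by one minus the penetrance; each triple
    is normalized to sum to 1.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"risk allele frequency must be in (0, 1), got {q}")
    for name, d in (("d1", d1), ("d2", d2), ("d3", d3)):
        if not (0.0 < d < 1.0):
            raise ValueError(f"{name} must be in (0, 1), got {d}")
    hwe = np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2])
    pen = np.array([d1, d2, d3])
    case = hwe * pen
    ctrl = hwe * (1.0 - pen)
    case /= case.sum()
    ctrl /= ctrl.sum()
    return GenotypeDistribution(tuple(case), tuple(ctrl))


@dataclass(frozen=True)
class CohortCounts:
    """Integer genotype counts for the two arms of a case-control cohort."""

    n_case: int
    n_control: int
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    @property
    def degenerate(self) -> bool:
        """True when the dose coefficient cannot be identified from the table:
        an empty arm, no dose variation, or perfect separation of outcomes."""
        cc = np.asarray(self.case_counts)
        nc = np.asarray(self.control_counts)
        if cc.sum() == 0 or nc.sum() == 0:
            return True
        occupied = np.flatnonzero(cc + nc)
        if occupied.size < 2:
            return True  # dose does not vary
        # perfect separation: every occupied dose level is single-outcome and
        # the outcome is monotone in dose
        mixed = (cc[occupied] > 0) & (nc[occupied] > 0)
        if not mixed.any():
            return True
        return False


def expected_counts(
    n_case: int, n_control: int, dist: GenotypeDistribution
) -> CohortCounts:
    """Expected genotype counts, rounded half-to-even per cell.

    Each cell is rounded independently, so the per-arm totals may differ from
    the nominal cohort size by one; the counts are used as-is downstream.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("cohort sizes must be at least 1")
    case = np.round(np.asarray(dist.case_props) * n_case).astype(int)
    ctrl = np.round(np.asarray(dist.control_props) * n_control).astype(int)
    return CohortCounts(
        n_case=n_case,
        n_control=n_control,
        case_counts=tuple(int(x) for x in case),
        control_counts=tuple(int(x) for x in ctrl),
    )


@dataclass(frozen=True)
class AssociationTestResult:
    """Dose-coefficient estimate and test from the logistic fit.

    ``flagged`` marks degenerate tables (separation, empty arm, constant
    dose): those carry ``beta = se = None`` and ``p_value = 1`` so sweeps can
    skip them without propagating non-finite values.
    """

    beta: float | None
    se: float | None
    p_value: float
    flagged: bool = False


def association_pvalue(
    counts: CohortCounts, *, test: Literal["wald", "lrt"] = "wald"
) -> AssociationTestResult:
    """Logistic regression of disease status on risk-allele dose.

    Fits ``logit P(disease) = beta0 + beta * dose`` on the grouped table
    (equivalent to the fit on expanded per-individual data) and tests
    ``beta = 0`` by a Wald z-test, or a likelihood-ratio chi-square test with
    ``test="lrt"``.
    """
    if counts.degenerate:
        return AssociationTestResult(beta=None, se=None, p_value=1.0, flagged=True)
    cc = np.asarray(counts.case_counts, dtype=float)
    nc = np.asarray(counts.control_counts, dtype=float)
    keep = (cc + nc) > 0
    dose = np.array([0.0, 1.0, 2.0])[keep]
    endog = np.column_stack([cc[keep], nc[keep]])
    exog = sm.add_constant(dose)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        except Exception:
            return AssociationTestResult(beta=None, se=None, p_value=1.0, flagged=True)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not (np.isfinite(beta) and np.isfinite(se)) or se > 1e6:
        return AssociationTestResult(beta=None, se=None, p_value=1.0, flagged=True)
    if test == "wald":
        p = float(fit.pvalues[1])
    elif test == "lrt":
        null = sm.GLM(
            endog, np.ones((len(dose), 1)), family=sm.families.Binomial()
        ).fit()
        lr = 2.0 * (fit.llf - null.llf)
        p = float(_sps.chi2.sf(max(lr, 0.0), df=1))
    else:
        raise ValueError(f"unknown test {test!r}")
    return AssociationTestResult(beta=beta, se=se, p_value=min(max(p, 0.0), 1.0))


@dataclass(frozen=True)
class ScenarioComparison:
    """Paired P-values with the minor vs the major allele as the risk allele."""

    n_case: int
    n_control: int
    d1: float
    r: float
    p: float
    p_minor_risk: float
    p_major_risk: float
    minor_flagged: bool = False
    major_flagged: bool = False


def _chain_pvalue(
    n_case: int,
    n_control: int,
    d1: float,
    r: float,
    q: float,
    round_counts: bool,
    test: Literal["wald", "lrt"],
) -> AssociationTestResult:
    d2, d3 = penetrances_from_or(d1, r)
    dist = genotype_distribution(q, d1, d2, d3)
    if round_counts:
        counts = expected_counts(n_case, n_control, dist)
    else:
        # exact expected tables: fractional weights, no rounding noise
        counts = CohortCounts(
            n_case=n_case,
            n_control=n_control,
            case_counts=tuple(n_case * p for p in dist.case_props),
            control_counts=tuple(n_control * p for p in dist.control_props),
        )
    return association_pvalue(counts, test=test)


def scenario_pair(
    n_case: int,
    n_control: int,
    d1: float,
    r: float,
    p: float,
    *,
    round_counts: bool = True,
    test: Literal["wald", "lrt"] = "wald",
) -> ScenarioComparison:
    """Run the full chain twice: risk allele frequency q = p, then q = 1 - p.

    ``p`` is the minor allele frequency, in (0, 0.5]. With
    ``round_counts=False`` the logistic fit uses the exact expected tables;
    with the default, expected counts are rounded to integers first (rounding
    can flip the sign of a near-tie between the two scenarios).
    """
    if not (0.0 < p <= 0.5):
        raise ValueError(f"minor allele frequency must be in (0, 0.5], got {p}")
    minor = _chain_pvalue(n_case, n_control, d1, r, p, round_counts, test)
    major = _chain_pvalue(n_case, n_control, d1, r, 1.0 - p, round_counts, test)
    return ScenarioComparison(
        n_case=n_case,
        n_control=n_control,
        d1=d1,
        r=r,
        p=p,
        p_minor_risk=minor.p_value,
        p_major_risk=major.p_value,
        minor_flagged=minor.flagged,
        major_flagged=major.flagged,
    )


def scenario_curves(
    n_case: int,
    n_control: int,
    d1: float,
    r: float,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    *,
    round_counts: bool = True,
    test: Literal["wald", "lrt"] = "wald",
) -> tuple[np.ndarray, np.ndarray, int]:
    """(p, log10 P) curves for the minor-risk and major-risk scenarios.

    Returns ``(curve_minor, curve_major, n_excluded)`` where each curve is an
    array of shape (m, 2) with columns (p, log10 P). Grid points where either
    scenario is degenerate are excluded from both curves and counted.
    """
    minor_pts, major_pts, n_excluded = [], [], 0
    for p in p_grid:
        cmp_ = scenario_pair(
            n_case, n_control, d1, r, p, round_counts=round_counts, test=test
        )
        if cmp_.minor_flagged or cmp_.major_flagged:
            n_excluded += 1
            continue
        minor_pts.append((p, np.log10(max(cmp_.p_minor_risk, _P_FLOOR))))
        major_pts.append((p, np.log10(max(cmp_.p_major_risk, _P_FLOOR))))
    return np.array(minor_pts), np.array(major_pts), n_excluded


def relative_difference(
    curve_minor: np.ndarray, curve_major: np.ndarray
) -> float:
    """S': normalized area gap between the two log-P curves.

    With A = trapezoidal integral of -log10(P) over the frequency grid,
    S' = (A_minor - A_major) / A_minor. Positive when the minor-risk scenario
    is the more significant one across the sweep; 0 for identical curves (and
    for flat curves at P = 1, where both areas vanish).
    """
    cm = np.asarray(curve_minor, dtype=float)
    cM = np.asarray(curve_major, dtype=float)
    if cm.shape != cM.shape or cm.ndim != 2 or cm.shape[1] != 2:
        raise ValueError("curves must be (m, 2) arrays on the same grid")
    if not np.allclose(cm[:, 0], cM[:, 0]):
        raise ValueError("curves are on different frequency grids")
    if cm.shape[0] < 2:
        raise ValueError("need at least two grid points")
    a_minor = float(np.trapezoid(-cm[:, 1], cm[:, 0]))
    a_major = float(np.trapezoid(-cM[:, 1], cM[:, 0]))
    if a_minor == 0.0:
        return 0.0
    return (a_minor - a_major) / a_minor


def s_prime(
    n_case: int,
    n_control: int,
    d1: float,
    r: float,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    *,
    round_counts: bool = True,
) -> tuple[float, int]:
    """S' for one parameter set; returns (value, excluded grid points)."""
    cm, cM, n_excluded = scenario_curves(
        n_case, n_control, d1, r, p_grid, round_counts=round_counts
    )
    if cm.shape[0] < 2:
        return float("nan"), n_excluded
    return relative_difference(cm, cM), n_excluded


@dataclass(frozen=True)
class RelativeDifferenceGrid:
    """S' over a 2-d parameter sweep; rows follow ``row_axis`` (odds ratios)."""

    row_axis: tuple[float, ...]
    col_axis: tuple[float, ...]
    col_name: str
    s_prime: np.ndarray
    n_excluded: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.s_prime, index=list(self.row_axis), columns=list(self.col_axis)
        ).rename_axis(index="r", columns=self.col_name)


def sweep_r_d1(
    n_case: int = 1000,
    n_control: int = 1000,
    d1_range: Sequence[float] | None = None,
    r_range: Sequence[float] | None = None,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    *,
    round_counts: bool = True,
) -> RelativeDifferenceGrid:
    """S' over the (odds ratio, baseline penetrance) grid.

    Defaults reproduce the full sweep: d1 from 0.01 to 0.25 step 0.01 and
    r from 1.06 to 2.00 step 0.01 (95 x 25 cells), with 1000 cases and 1000
    controls.
    """
    d1s = tuple(
        np.round(np.arange(1, 26) * 0.01, 2) if d1_range is None else d1_range
    )
    rs = tuple(
        np.round(1.05 + np.arange(1, 96) * 0.01, 2) if r_range is None else r_range
    )
    if not d1s or not rs:
        raise ValueError("parameter ranges must be non-empty")
    grid = np.empty((len(rs), len(d1s)))
    excluded = 0
    for i, r in enumerate(rs):
        for j, d1 in enumerate(d1s):
            grid[i, j], nex = s_prime(
                n_case, n_control, d1, r, p_grid, round_counts=round_counts
            )
            excluded += nex
    return RelativeDifferenceGrid(
        row_axis=rs, col_axis=d1s, col_name="d1", s_prime=grid, n_excluded=excluded
    )


def sweep_r_nc(
    n_total: int = 2000,
    d1: float = 0.03,
    r_range: Sequence[float] | None = None,
    nc_range: Sequence[int] | None = None,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    *,
    round_counts: bool = True,
) -> RelativeDifferenceGrid:
    """S' over the (odds ratio, number of controls) grid at fixed total size.

    Defaults: total cohort 2000, d1 = 0.03, controls from 200 to 1800 step
    100 (cases make up the remainder), r from 1.06 to 2.00 step 0.01.
    """
    ncs = tuple(range(200, 1801, 100)) if nc_range is None else tuple(nc_range)
    rs = tuple(
        np.round(1.05 + np.arange(1, 96) * 0.01, 2) if r_range is None else r_range
    )
    if not ncs or not rs:
        raise ValueError("parameter ranges must be non-empty")
    if any(nc >= n_total for nc in ncs) or any(nc < 1 for nc in ncs):
        raise ValueError("control counts must be in [1, n_total)")
    grid = np.empty((len(rs), len(ncs)))
    excluded = 0
    for i, r in enumerate(rs):
        for j, nc in enumerate(ncs):
            grid[i, j], nex = s_prime(
                n_total - nc, nc, d1, r, p_grid, round_counts=round_counts
            )
            excluded += nex
    return RelativeDifferenceGrid(
        row_axis=rs, col_axis=ncs, col_name="nc", s_prime=grid, n_excluded=excluded
    )
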