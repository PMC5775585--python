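"""One-stage case-control GWAS power and the power-imbalance-corrected
enrichment test.

The power model is the classical allele-count two-proportion test: given a
disease prevalence K, a genotype relative risk, a genetic model and a risk
allele frequency q, the baseline penetrance is solved from
K = sum_g HWE(g) * RR(g) * f0, the expected risk-allele frequencies in cases
and controls follow, and the detection power is the normal-approximation
power of the two-proportion z-test on allele counts (variance evaluated
under the alternative, two-sided significance level). Dominant and recessive
models collapse genotypes to carrier / non-carrier and run the same
two-proportion computation on individuals.

Because a GWAS is better powered to detect a risk allele at frequency q than
at 1 - q, a catalog of significant hits over-represents minor risk alleles
even without any frequency asymmetry in the underlying biology. The expected
minor fraction under detectability alone is y_minor / (y_minor + y_major);
the corrected enrichment test replaces the naive null proportion of 0.5 with
that expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .stats import MAF_BINS, MafBin, binom_two_sided, clopper_pearson

__all__ = [
    "DiseaseModel",
    "PowerSpec",
    "PowerResult",
    "CorrectedBinEnrichment",
    "genotype_risks",
    "baseline_penetrance",
    "case_control_allele_freqs",
    "gas_power",
    "power_curve",
    "expected_minor_proportion",
    "corrected_enrichment",
]


class DiseaseModel(str, Enum):
    MULTIPLICATIVE = "multiplicative"
    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


@dataclass(frozen=True)
class PowerSpec:
    """Design of a one-stage case-control association study.

    ``grr`` is the genotype relative risk of the heterozygote relative to the
    zero-risk-allele baseline; the homozygote risk follows from ``model``.
    ``raf`` is the population frequency of the risk allele.
    """

    n_case: int
    n_control: int
    prevalence: float
    grr: float
    alpha: float = 5.0e-8
    model: DiseaseModel = DiseaseModel.MULTIPLICATIVE
    raf: float | None = None

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("cohort sizes must be at least 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.grr <= 0.0:
            raise ValueError("genotype relative risk must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.raf is not None and not (0.0 < self.raf < 1.0):
            raise ValueError("risk allele frequency must be in (0, 1)")

    def at(self, raf: float) -> "PowerSpec":
        return replace(self, raf=raf)


@dataclass(frozen=True)
class PowerResult:
    spec: PowerSpec
    power: float


def genotype_risks(model: DiseaseModel | str, grr: float) -> tuple[float, float, float]:
    """Relative risks for 0/1/2 risk alleles under the four genetic models."""
    if grr <= 0.0:
        raise ValueError("genotype relative risk must be positive")
    model = DiseaseModel(model)
    if model is DiseaseModel.MULTIPLICATIVE:
        return (1.0, grr, grr * grr)
    if model is DiseaseModel.ADDITIVE:
        rr2 = 2.0 * grr - 1.0
        if rr2 <= 0.0:
            raise ValueError("additive model needs 2*grr - 1 > 0")
        return (1.0, grr, rr2)
    if model is DiseaseModel.DOMINANT:
        return (1.0, grr, grr)
    return (1.0, 1.0, grr)  # recessive


def _hwe(q: float) -> np.ndarray:
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2])


def baseline_penetrance(
    q: float, prevalence: float, risks: Sequence[float]
) -> float:
    """Penetrance of the zero-risk-allele genotype consistent with prevalence.

    Solves K = f0 * sum_g HWE(g) * RR(g); errors out when the implied top
    penetrance f0 * max(RR) reaches 1 (model inconsistent with prevalence).
    """
    if not (0.0 < q < 1.0):
        raise ValueError("allele frequency must be in (0, 1)")
    f0 = prevalence / float(np.dot(_hwe(q), np.asarray(risks, dtype=float)))
    if f0 * max(risks) >= 1.0:
        raise ValueError(
            "genetic model implies a penetrance of at least 1; "
            "prevalence and relative risks are inconsistent"
        )
    return f0


def case_control_allele_freqs(
    spec: PowerSpec, raf: float | None = None
) -> tuple[float, float]:
    """Expected risk-allele frequencies in cases and in controls."""
    q = spec.raf if raf is None else raf
    if q is None:
        raise ValueError("spec carries no risk allele frequency")
    risks = genotype_risks(spec.model, spec.grr)
    f0 = baseline_penetrance(q, spec.prevalence, risks)
    k = spec.prevalence
    f_case = f0 * (q * q * risks[2] + q * (1.0 - q) * risks[1]) / k
    f_ctrl = (q - k * f_case) / (1.0 - k)
    return f_case, f_ctrl


def _carrier_probs(spec: PowerSpec, q: float) -> tuple[float, float]:
    """P(carrier | case) and P(carrier | control) after genotype collapsing.

    Dominant: carrier = at least one risk allele. Recessive: carrier = risk
    homozygote.
    """
    risks = genotype_risks(spec.model, spec.grr)
    f0 = baseline_penetrance(q, spec.prevalence, risks)
    hwe = _hwe(q)
    pen = f0 * np.asarray(risks)
    k = spec.prevalence
    carrier = slice(1, 3) if spec.model is DiseaseModel.DOMINANT else slice(2, 3)
    p_case = float((pen[carrier] * hwe[carrier]).sum()) / k
    p_ctrl = float(((1.0 - pen[carrier]) * hwe[carrier]).sum()) / (1.0 - k)
    return p_case, p_ctrl


def gas_power(spec: PowerSpec, raf: float | None = None) -> PowerResult:
    """Detection power of the study design at a given risk allele frequency.

    Multiplicative/additive models use the allele-count two-proportion test
    (2 * n alleles per arm); dominant/recessive use the carrier-collapsed
    two-proportion test on individuals. The normal approximation evaluates
    the variance under the alternative and applies a two-sided threshold:

        power = Phi(z - z*) + Phi(-z - z*),  z* = Phi^-1(1 - alpha / 2)
    """
    q = spec.raf if raf is None else raf
    if q is None:
        raise ValueError("spec carries no risk allele frequency")
    if spec.model in (DiseaseModel.MULTIPLICATIVE, DiseaseModel.ADDITIVE):
        f_case, f_ctrl = case_control_allele_freqs(spec, q)
        m_case, m_ctrl = 2 * spec.n_case, 2 * spec.n_control
    else:
        f_case, f_ctrl = _carrier_probs(spec, q)
        m_case, m_ctrl = spec.n_case, spec.n_control
    se = np.sqrt(
        f_case * (1.0 - f_case) / m_case + f_ctrl * (1.0 - f_ctrl) / m_ctrl
    )
    z = abs(f_case - f_ctrl) / se
    z_star = _sps.norm.isf(spec.alpha / 2.0)
    power = float(_sps.norm.cdf(z - z_star) + _sps.norm.cdf(-z - z_star))
    return PowerResult(spec=spec.at(q), power=power)


def power_curve(spec: PowerSpec, rafs: Sequence[float]) -> list[PowerResult]:
    return [gas_power(spec, q) for q in rafs]


def expected_minor_proportion(power_minor: float, power_major: float) -> float:
    """Fraction of detected risk alleles expected to be minor from power alone:
    y_minor / (y_minor + y_major)."""
    if power_minor < 0.0 or power_major < 0.0:
        raise ValueError("powers must be non-negative")
    total = power_minor + power_major
    if total == 0.0:
        raise ValueError("both powers are zero; expected proportion undefined")
    return power_minor / total


@dataclass(frozen=True)
class CorrectedBinEnrichment:
    """Observed vs power-expected minor-risk proportion in one MAF bin.

    ``p_original`` tests the observed count against a null proportion of 0.5;
    ``p_corrected`` tests it against ``expected_prop``, the proportion implied
    by the study's detection-power imbalance. The confidence interval is the
    Clopper-Pearson interval for the observed proportion. Empty bins are
    flagged and carry no statistics.
    """

    bin: MafBin
    n_minor_risk: int
    n_major_risk: int
    observed_prop: float | None
    power_minor: float
    power_major: float
    expected_prop: float
    p_original: float | None
    p_corrected: float | None
    ci_lower: float | None
    ci_upper: float | None
    flagged: bool = False


def corrected_enrichment(
    bin_counts: Sequence[tuple[int, int]],
    spec: PowerSpec,
    bin_representative_rafs: Sequence[float] | None = None,
    *,
    confidence: float = 0.95,
) -> list[CorrectedBinEnrichment]:
    """Power-imbalance-corrected enrichment test, one row per MAF bin.

    ``bin_counts`` holds (minor-risk count, major-risk count) for each of the
    five MAF bins. Each bin is represented by its midpoint frequency (0.05,
    0.15, ..., 0.45) for the minor-risk power and by the mirrored frequency
    (0.95, ...) for the major-risk power, unless explicit representative
    frequencies are given.
    """
    if len(bin_counts) != len(MAF_BINS):
        raise ValueError(f"expected {len(MAF_BINS)} bin counts")
    reps = (
        [b.midpoint for b in MAF_BINS]
        if bin_representative_rafs is None
        else list(bin_representative_rafs)
    )
    if len(reps) != len(MAF_BINS):
        raise ValueError("need one representative frequency per bin")
    out: list[CorrectedBinEnrichment] = []
    for bin_, (k, m), rep in zip(MAF_BINS, bin_counts, reps):
        if k < 0 or m < 0:
            raise ValueError("counts must be non-negative")
        y_minor = gas_power(spec, rep).power
        y_major = gas_power(spec, 1.0 - rep).power
        expected = expected_minor_proportion(y_minor, y_major)
        n = k + m
        if n == 0:
            out.append(
                CorrectedBinEnrichment(
                    bin=bin_,
                    n_minor_risk=k,
                    n_major_risk=m,
                    observed_prop=None,
                    power_minor=y_minor,
                    power_major=y_major,
                    expected_prop=expected,
                    p_original=None,
                    p_corrected=None,
                    ci_lower=None,
                    ci_upper=None,
                    flagged=True,
                )
            )
            continue
        lo, hi = clopper_pearson(k, n, confidence)
        out.append(
            CorrectedBinEnrichment(
                bin=bin_,
                n_minor_risk=k,
                n_major_risk=m,
                observed_prop=k / n,
                power_minor=y_minor,
                power_major=y_major,
                expected_prop=expected,
                p_original=binom_two_sided(k, n, 0.5),
                p_corrected=binom_two_sided(k, n, expected),
                ci_lower=lo,
                ci_upper=hi,
            )
        )
    return out
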