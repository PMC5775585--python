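"""Minor-allele enrichment model: are risk alleles enriched in minor alleles?

The core question of the package, posed as a fitted model. The data are
disease-associated SNVs with risk allele frequencies; the model bins them
into five equal minor-allele-frequency (MAF) intervals and, per bin, treats
"risk allele is the minor allele" as a binomial outcome. ``fit()`` tests the
minor fraction of each bin against 0.5 with the exact minimum-likelihood
two-sided binomial test and attaches Clopper-Pearson intervals, with a
Bonferroni-corrected significance level of 0.05 / 5 across the bins.
Supplying a study design refits the null per bin at the proportion expected
from the design's detection-power imbalance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import AssociationRecord, RiskClass, classify_risk_allele
from .power import PowerSpec, corrected_enrichment
from .stats import MAF_BINS, MafBin, assign_bin, binom_two_sided, clopper_pearson, maf_of

__all__ = [
    "BinEnrichment",
    "DiseaseSummary",
    "BinnedRecords",
    "bin_by_maf",
    "enrichment_table",
    "disease_summaries",
    "MinorAlleleEnrichment",
    "EnrichmentResults",
]


@dataclass(frozen=True)
class BinEnrichment:
    """Enrichment statistics for one MAF bin.

    Empty bins carry ``None`` statistics (never 0 or 1) and are flagged.
    """

    bin: MafBin
    n_total: int
    n_minor_risk: int
    proportion: float | None
    ci_lower: float | None
    ci_upper: float | None
    p_value: float | None
    alpha_corrected: float
    flagged: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < self.alpha_corrected


@dataclass(frozen=True)
class DiseaseSummary:
    disease: str
    n_snvs: int
    mean_risk_allele_frequency: float
    fraction_minor: float


@dataclass(frozen=True)
class BinnedRecords(Mapping):
    """Mapping MAF bin -> records, with exclusion tallies."""

    bins: Mapping[MafBin, tuple[AssociationRecord, ...]]
    n_monomorphic: int
    n_missing_raf: int

    def __getitem__(self, key: MafBin):
        return self.bins[key]

    def __iter__(self):
        return iter(self.bins)

    def __len__(self):
        return len(self.bins)


def bin_by_maf(records: Iterable[AssociationRecord]) -> BinnedRecords:
    """Assign each record to exactly one MAF bin by min(RAF, 1 - RAF).

    Bins are half-open [lower, upper) with the last bin closed at 0.5.
    Records with missing frequency or a monomorphic MAF of 0 are excluded
    and counted.
    """
    bins: dict[MafBin, list[AssociationRecord]] = {b: [] for b in MAF_BINS}
    n_mono = n_missing = 0
    for rec in records:
        raf = rec.risk_allele_frequency
        if raf is None or (isinstance(raf, float) and math.isnan(raf)):
            n_missing += 1
            continue
        maf = maf_of(raf)
        if maf == 0.0:
            n_mono += 1
            continue
        bins[assign_bin(maf)].append(rec)
    return BinnedRecords(
        bins={b: tuple(v) for b, v in bins.items()},
        n_monomorphic=n_mono,
        n_missing_raf=n_missing,
    )


class MinorAlleleEnrichment:
    """Model of minor-risk-allele enrichment across MAF bins.

    Parameters
    ----------
    records:
        Association records with risk allele frequencies. Records with a
        missing frequency, a monomorphic frequency, or a frequency of exactly
        0.5 (neither minor nor major) are excluded from the binomial tallies
        and reported on the results object.
    unique_snvs:
        Count each SNV once (keeping its most significant association) rather
        than once per disease association.
    """

    def __init__(
        self,
        records: Sequence[AssociationRecord],
        *,
        unique_snvs: bool = False,
    ) -> None:
        records = tuple(records)
        if unique_snvs:
            best: dict[str, AssociationRecord] = {}
            for rec in records:
                cur = best.get(rec.snv_id)
                if cur is None or (rec.p_value, rec.disease) < (cur.p_value, cur.disease):
                    best[rec.snv_id] = rec
            records = tuple(best[s] for s in sorted(best))
        self.records = records
        self.unique_snvs = unique_snvs

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        *,
        raf_col: str = "risk_allele_frequency",
        disease_col: str = "disease",
        snv_col: str = "snv_id",
        p_col: str | None = "p_value",
        unique_snvs: bool = False,
    ) -> "MinorAlleleEnrichment":
        """Build the model from a tidy frame with one association per row."""
        records = []
        for i, row in data.reset_index(drop=True).iterrows():
            raf = row[raf_col]
            records.append(
                AssociationRecord(
                    snv_id=str(row[snv_col]) if snv_col in data.columns else f"row{i}",
                    disease=str(row[disease_col]) if disease_col in data.columns else "",
                    risk_allele="?",
                    risk_allele_frequency=None if pd.isna(raf) else float(raf),
                    p_value=float(row[p_col]) if p_col and p_col in data.columns else 1e-9,
                )
            )
        return cls(records, unique_snvs=unique_snvs)

    def fit(
        self,
        *,
        alpha: float = 0.05,
        power_spec: PowerSpec | None = None,
        confidence: float = 0.95,
    ) -> "EnrichmentResults":
        """Run the per-bin exact binomial tests.

        ``alpha`` is Bonferroni-divided by the number of bins. With a
        ``power_spec`` the results also carry the power-corrected columns
        (expected proportion and the test against it).
        """
        binned = bin_by_maf(self.records)
        alpha_corrected = alpha / len(MAF_BINS)
        rows: list[BinEnrichment] = []
        counts: list[tuple[int, int]] = []
        n_ambiguous = binned.n_missing_raf
        for bin_ in MAF_BINS:
            k = n = 0
            for rec in binned[bin_]:
                cls_ = classify_risk_allele(rec.risk_allele_frequency)
                if cls_ is RiskClass.MINOR:
                    k += 1
                    n += 1
                elif cls_ is RiskClass.MAJOR:
                    n += 1
                else:
                    n_ambiguous += 1
            counts.append((k, n - k))
            if n == 0:
                rows.append(
                    BinEnrichment(
                        bin=bin_,
                        n_total=0,
                        n_minor_risk=0,
                        proportion=None,
                        ci_lower=None,
                        ci_upper=None,
                        p_value=None,
                        alpha_corrected=alpha_corrected,
                        flagged=True,
                    )
                )
                continue
            lo, hi = clopper_pearson(k, n, confidence)
            rows.append(
                BinEnrichment(
                    bin=bin_,
                    n_total=n,
                    n_minor_risk=k,
                    proportion=k / n,
                    ci_lower=lo,
                    ci_upper=hi,
                    p_value=binom_two_sided(k, n, 0.5),
                    alpha_corrected=alpha_corrected,
                )
            )
        corrected = (
            corrected_enrichment(counts, power_spec, confidence=confidence)
            if power_spec is not None
            else None
        )
        return EnrichmentResults(
            model=self,
            bins=tuple(rows),
            corrected=tuple(corrected) if corrected is not None else None,
            power_spec=power_spec,
            n_ambiguous=n_ambiguous,
            n_monomorphic=binned.n_monomorphic,
            alpha=alpha,
        )


class EnrichmentResults:
    """Fitted per-bin enrichment estimates, intervals and tests."""

    def __init__(
        self,
        model: MinorAlleleEnrichment,
        bins,
        corrected,
        power_spec,
        n_ambiguous: int,
        n_monomorphic: int,
        alpha: float,
    ) -> None:
        self.model = model
        self.bins = bins
        self.corrected = corrected
        self.power_spec = power_spec
        self.n_ambiguous = n_ambiguous
        self.n_monomorphic = n_monomorphic
        self.alpha = alpha
        self.alpha_corrected = alpha / len(bins)

    @property
    def table(self) -> pd.DataFrame:
        """Per-bin statistics; the corrected columns appear when a study
        design was supplied to ``fit``."""
        rows = []
        for i, b in enumerate(self.bins):
            row = {
                "maf_bin": b.bin.label,
                "n_total": b.n_total,
                "n_minor_risk": b.n_minor_risk,
                "proportion": b.proportion,
                "ci_lower": b.ci_lower,
                "ci_upper": b.ci_upper,
                "p_value": b.p_value,
                "significant": b.significant,
            }
            if self.corrected is not None:
                c = self.corrected[i]
                row.update(
                    power_minor=c.power_minor,
                    power_major=c.power_major,
                    expected_prop=c.expected_prop,
                    p_corrected=c.p_corrected,
                    significant_corrected=(
                        c.p_corrected is not None
                        and c.p_corrected < self.alpha_corrected
                    ),
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self, float_format: str = "%.4g") -> str:
        """Human-readable report in the spirit of a regression summary."""
        df = self.table
        lines = [
            "Minor-allele enrichment by MAF bin",
            "=" * 34,
            f"records: {len(self.model.records)}   "
            f"ambiguous (RAF missing or 0.5): {self.n_ambiguous}   "
            f"monomorphic: {self.n_monomorphic}",
            f"null: proportion = 0.5   "
            f"Bonferroni level: {self.alpha_corrected:g}",
        ]
        if self.power_spec is not None:
            s = self.power_spec
            lines.append(
                f"power-corrected null: {s.n_case} cases / {s.n_control} controls, "
                f"K={s.prevalence:g}, GRR={s.grr:g}, alpha={s.alpha:g}, {s.model.value}"
            )
        lines.append("")
        lines.append(df.to_string(index=False, float_format=lambda x: float_format % x))
        return "\n".join(lines)


def enrichment_table(
    records: Sequence[AssociationRecord],
    *,
    alpha: float = 0.05,
    confidence: float = 0.95,
) -> tuple[BinEnrichment, ...]:
    """Per-bin enrichment rows (functional face of the model)."""
    return MinorAlleleEnrichment(records).fit(alpha=alpha, confidence=confidence).bins


def disease_summaries(
    records: Iterable[AssociationRecord],
) -> tuple[DiseaseSummary, ...]:
    """Per-disease SNV count, mean risk allele frequency and minor fraction.

    Only records with a numeric frequency contribute; diseases with no such
    records are omitted. Sorted by ascending mean frequency, so diseases whose
    risk alleles sit at the rare end come first.
    """
    by_disease: dict[str, list[float]] = {}
    for rec in records:
        if rec.risk_allele_frequency is not None:
            by_disease.setdefault(rec.disease, []).append(rec.risk_allele_frequency)
    out = []
    for disease, rafs in by_disease.items():
        arr = np.asarray(rafs)
        out.append(
            DiseaseSummary(
                disease=disease,
                n_snvs=len(rafs),
                mean_risk_allele_frequency=float(arr.mean()),
                fraction_minor=float((arr < 0.5).mean()),
            )
        )
    return tuple(sorted(out, key=lambda s: (s.mean_risk_allele_frequency, s.disease)))
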