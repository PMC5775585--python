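"""Reading, filtering and LD-pruning of GWAS-catalog-style association tables.

The NHGRI-EBI GWAS Catalog ships associations as a tab-separated table with one
row per SNV-trait association. This module parses that dialect into
:class:`AssociationRecord` objects, applies the standard significance /
risk-allele-frequency / ancestry / disease filters, classifies each risk allele
as minor or major, and collapses linkage-disequilibrium (LD) blocks down to
their most significant member.
"""

from __future__ import annotations

import csv
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Mapping

__all__ = [
    "Ancestry",
    "RiskClass",
    "AssociationRecord",
    "FilterCriteria",
    "LdTable",
    "CatalogFormatError",
    "ParseResult",
    "FilterResult",
    "parse_association_table",
    "filter_associations",
    "classify_risk_allele",
    "ld_prune",
    "write_association_tsv",
    "DEFAULT_COLUMNS",
]


class CatalogFormatError(ValueError):
    """The input table does not conform to the expected catalog dialect."""


class Ancestry(str, Enum):
    EUROPEAN = "european"
    OTHER = "other"


class RiskClass(str, Enum):
    MINOR = "minor"
    MAJOR = "major"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class AssociationRecord:
    """One SNV-disease association.

    ``risk_allele_frequency`` is ``None`` when the catalog reported a
    non-numeric value ("NR", "pending", ...). ``p_value`` is always a valid
    probability in (0, 1]; rows violating that are rejected at parse time.
    """

    snv_id: str
    disease: str
    risk_allele: str
    risk_allele_frequency: float | None
    p_value: float
    ancestry_label: Ancestry = Ancestry.EUROPEAN
    study_id: str = ""
    is_disease_trait: bool = True

    def __post_init__(self) -> None:
        if not self.snv_id:
            raise ValueError("snv_id must be non-empty")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        raf = self.risk_allele_frequency
        if raf is not None and not (0.0 <= raf <= 1.0):
            raise ValueError(f"risk_allele_frequency must be in [0, 1], got {raf}")

    @property
    def risk_class(self) -> RiskClass:
        return classify_risk_allele(self.risk_allele_frequency)


def classify_risk_allele(risk_allele_frequency: float | None) -> RiskClass:
    """Classify a risk allele as minor (RAF < 0.5), major (> 0.5) or ambiguous.

    A frequency of exactly 0.5, or a missing frequency, is ambiguous: the
    minor/major partition is defined only away from 0.5.
    """
    f = risk_allele_frequency
    if f is None or (isinstance(f, float) and math.isnan(f)):
        return RiskClass.AMBIGUOUS
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"risk allele frequency must be in [0, 1], got {f}")
    if f < 0.5:
        return RiskClass.MINOR
    if f > 0.5:
        return RiskClass.MAJOR
    return RiskClass.AMBIGUOUS


#: Logical field -> header name in the NHGRI-EBI export dialect.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "snv_id": "SNPS",
    "disease": "DISEASE/TRAIT",
    "p_value": "P-VALUE",
    "risk_allele": "STRONGEST SNP-RISK ALLELE",
    "risk_allele_frequency": "RISK ALLELE FREQUENCY",
    "sample_description": "INITIAL SAMPLE SIZE",
}

_OPTIONAL_COLUMNS: Mapping[str, str] = {"study_id": "STUDY ACCESSION"}


@dataclass(frozen=True)
class ParseResult(Sequence):
    """Parsed records plus a row-level error report."""

    records: tuple[AssociationRecord, ...]
    skipped: tuple[tuple[int, str], ...] = ()

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _parse_raf(text: str) -> float | None:
    # The catalog uses "NR", "pending", ranges etc.; anything that is not a
    # plain number inside [0, 1] counts as missing.
    try:
        value = float(text)
    except (TypeError, ValueError):
        return None
    if math.isnan(value) or not (0.0 <= value <= 1.0):
        return None
    return value


def _risk_allele_symbol(text: str) -> str:
    # Catalog style: "rs12345-A"; keep the trailing base symbol, "?" marks
    # an unknown risk allele.
    text = (text or "").strip()
    if "-" in text:
        return text.rsplit("-", 1)[1] or "?"
    return text or "?"


def parse_association_table(
    stream: IO[str],
    columns: Mapping[str, str] | None = None,
    *,
    european_keywords: Sequence[str] = ("european",),
    disease_allowlist: Iterable[str] | None = None,
    disease_denylist: Iterable[str] | None = None,
) -> ParseResult:
    """Parse a catalog-dialect TSV stream into association records.

    Rows with malformed or out-of-range P-values are skipped and reported in
    ``ParseResult.skipped``; unparseable risk-allele frequencies become missing
    values (to be removed later by filtering). Ancestry is derived from the
    initial-sample-size description: any of ``european_keywords`` (matched
    case-insensitively) marks the study as European.

    ``disease_allowlist`` / ``disease_denylist`` implement the disease-versus-
    trait curation: with an allowlist only listed phenotypes count as diseases;
    with a denylist all but the listed ones do; with neither, every row does.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None:
        return ParseResult(records=())
    for logical, header in colmap.items():
        if header not in reader.fieldnames:
            raise CatalogFormatError(
                f"missing mandatory column {header!r} (for {logical})"
            )
    study_col = _OPTIONAL_COLUMNS["study_id"]
    has_study = study_col in reader.fieldnames
    allow = {d.casefold() for d in disease_allowlist} if disease_allowlist else None
    deny = {d.casefold() for d in disease_denylist} if disease_denylist else set()
    keywords = tuple(k.casefold() for k in european_keywords)

    records: list[AssociationRecord] = []
    skipped: list[tuple[int, str]] = []
    for i, row in enumerate(reader, start=2):  # 1-based, after the header
        snv_id = (row.get(colmap["snv_id"]) or "").strip()
        if not snv_id:
            skipped.append((i, "empty SNP id"))
            continue
        try:
            p_value = float(row.get(colmap["p_value"]) or "")
        except ValueError:
            skipped.append((i, "malformed P-value"))
            continue
        if not (0.0 < p_value <= 1.0):
            skipped.append((i, f"P-value out of (0, 1]: {p_value}"))
            continue
        disease = (row.get(colmap["disease"]) or "").strip()
        sample = (row.get(colmap["sample_description"]) or "").casefold()
        ancestry = (
            Ancestry.EUROPEAN
            if any(k in sample for k in keywords)
            else Ancestry.OTHER
        )
        key = disease.casefold()
        is_disease = key not in deny if allow is None else key in allow
        records.append(
            AssociationRecord(
                snv_id=snv_id,
                disease=disease,
                risk_allele=_risk_allele_symbol(row.get(colmap["risk_allele"], "")),
                risk_allele_frequency=_parse_raf(
                    row.get(colmap["risk_allele_frequency"], "")
                ),
                p_value=p_value,
                ancestry_label=ancestry,
                study_id=(row.get(study_col) or "").strip() if has_study else "",
                is_disease_trait=is_disease,
            )
        )
    return ParseResult(records=tuple(records), skipped=tuple(skipped))


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion rules for association records.

    Defaults follow the conventional genome-wide pipeline: genome-wide
    significance below 5e-8, a numeric risk allele frequency, European
    studies only, diseases only.
    """

    p_threshold: float = 5.0e-8
    require_valid_raf: bool = True
    ancestry: Ancestry | None = Ancestry.EUROPEAN
    diseases_only: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass(frozen=True)
class FilterResult(Sequence):
    """Surviving records plus per-criterion removal counts.

    A removed record increments the counter of every criterion it fails, so
    counter totals can exceed the number of removed rows.
    """

    records: tuple[AssociationRecord, ...]
    n_input: int
    removed: Mapping[str, int]

    @property
    def n_removed(self) -> int:
        return self.n_input - len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def filter_associations(
    records: Iterable[AssociationRecord], criteria: FilterCriteria = FilterCriteria()
) -> FilterResult:
    """Apply the criteria, preserving input order; filters count, never fail."""
    kept: list[AssociationRecord] = []
    removed = {"p_value": 0, "invalid_raf": 0, "ancestry": 0, "non_disease": 0}
    n_input = 0
    for rec in records:
        n_input += 1
        ok = True
        if not (rec.p_value < criteria.p_threshold):
            removed["p_value"] += 1
            ok = False
        if criteria.require_valid_raf and rec.risk_allele_frequency is None:
            removed["invalid_raf"] += 1
            ok = False
        if criteria.ancestry is not None and rec.ancestry_label != criteria.ancestry:
            removed["ancestry"] += 1
            ok = False
        if criteria.diseases_only and not rec.is_disease_trait:
            removed["non_disease"] += 1
            ok = False
        if ok:
            kept.append(rec)
    return FilterResult(records=tuple(kept), n_input=n_input, removed=removed)


class LdTable:
    """Symmetric lookup of pairwise r-squared values.

    Pairs absent from the table are treated as unlinked (r-squared 0), so a
    partial LD table degrades gracefully; the diagonal is implicitly 1.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._r2: dict[frozenset[str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        if a == b:
            if r2 != 1.0:
                raise ValueError("r2 of a variant with itself must be 1")
            return
        self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, stream: IO[str]) -> "LdTable":
        """Read a 3-column TSV (snv_a, snv_b, r2); a header row is optional."""
        table = cls()
        for i, line in enumerate(stream, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CatalogFormatError(f"line {i}: expected 3 columns")
            try:
                r2 = float(parts[2])
            except ValueError:
                if i == 1:  # header
                    continue
                raise CatalogFormatError(f"line {i}: malformed r2 {parts[2]!r}")
            table.set(parts[0], parts[1], r2)
        return table

    def to_tsv(self, stream: IO[str]) -> None:
        stream.write("snv_a\tsnv_b\tr2\n")
        for pair in sorted(self._r2, key=sorted):
            a, b = sorted(pair)
            stream.write(f"{a}\t{b}\t{self._r2[pair]:.6g}\n")


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self._parent = {x: x for x in items}

    def find(self, x: str) -> str:
        p = self._parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self._parent[rb] = ra


def ld_prune(
    records: Sequence[AssociationRecord],
    ld_table: LdTable,
    r2_threshold: float = 0.8,
) -> tuple[AssociationRecord, ...]:
    """Collapse each per-disease LD block to its most significant SNV.

    Within each disease, SNVs are grouped into blocks by single-linkage
    transitive closure of the "r-squared strictly above threshold" relation;
    from each block the record with the lowest P-value survives (ties broken
    by lexicographic SNV id), and its risk allele frequency represents the
    block. Grouping is independent across diseases.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    by_disease: dict[str, list[AssociationRecord]] = {}
    for rec in records:
        by_disease.setdefault(rec.disease, []).append(rec)

    survivors: set[tuple[str, str]] = set()
    for disease, recs in by_disease.items():
        ids = sorted({r.snv_id for r in recs})
        uf = _UnionFind(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if ld_table.r2(a, b) > r2_threshold:
                    uf.union(a, b)
        best: dict[str, AssociationRecord] = {}
        for rec in recs:
            root = uf.find(rec.snv_id)
            cur = best.get(root)
            if cur is None or (rec.p_value, rec.snv_id) < (cur.p_value, cur.snv_id):
                best[root] = rec
        survivors.update((disease, rec.snv_id) for rec in best.values())

    out, seen = [], set()
    for rec in records:
        key = (rec.disease, rec.snv_id)
        if key in survivors and key not in seen:
            out.append(rec)
            seen.add(key)
    return tuple(out)


def write_association_tsv(
    records: Iterable[AssociationRecord], stream: IO[str]
) -> None:
    """Write records back out in the catalog dialect plus a risk_class column."""
    headers = [
        DEFAULT_COLUMNS["snv_id"],
        DEFAULT_COLUMNS["disease"],
        DEFAULT_COLUMNS["risk_allele"],
        DEFAULT_COLUMNS["risk_allele_frequency"],
        DEFAULT_COLUMNS["p_value"],
        DEFAULT_COLUMNS["sample_description"],
        _OPTIONAL_COLUMNS["study_id"],
        "RISK CLASS",
    ]
    stream.write("\t".join(headers) + "\n")
    for rec in records:
        raf = "NR" if rec.risk_allele_frequency is None else f"{rec.risk_allele_frequency:.6g}"
        sample = "European ancestry" if rec.ancestry_label is Ancestry.EUROPEAN else "other ancestry"
        stream.write(
            "\t".join(
                [
                    rec.snv_id,
                    rec.disease,
                    f"{rec.snv_id}-{rec.risk_allele}",
                    raf,
                    f"{rec.p_value:.6g}",
                    sample,
                    rec.study_id,
                    rec.risk_class.value,
                ]
            )
            + "\n"
        )
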