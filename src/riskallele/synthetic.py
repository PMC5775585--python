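"""Seeded generators for catalog-like tables, LD tables and sampled cohorts.

Every pipeline stage is testable without external downloads: the catalog
generator emits association tables in the exact TSV dialect the parser
consumes, with known ground truth (per-record MAF bin, risk-class and
contaminant label); the LD generator emits block-structured r-squared tables
with known block membership; the cohort sampler draws case/control genotype
counts from the distributions a study design implies, serving as the
Monte-Carlo oracle for the analytic power calculator.

A single root seed fans out to fixed per-component substreams, so adding a
generator never perturbs the output of an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .catalog import Ancestry, AssociationRecord, LdTable
from .power import PowerSpec, baseline_penetrance, genotype_risks
from .penetrance import CohortCounts
from .stats import MAF_BINS

__all__ = [
    "SyntheticCatalogSpec",
    "SyntheticLdSpec",
    "SyntheticCatalog",
    "generate_catalog",
    "generate_ld_table",
    "sample_cohort",
    "empirical_power",
]

# substream salts: catalog=0, ld=1, cohort=2
_SALT_CATALOG, _SALT_LD, _SALT_COHORT = 0, 1, 2

#: Per-bin minor-risk probabilities echoing the observed catalog asymmetry.
_DEFAULT_PI = (0.79, 0.63, 0.60, 0.61, 0.59)
#: Per-bin weights proportional to the observed bin occupancies.
_DEFAULT_WEIGHTS = tuple(n / 3284 for n in (476, 616, 698, 723, 771))


@dataclass(frozen=True)
class SyntheticCatalogSpec:
    """Recipe for a catalog-like association table.

    Clean rows are genome-wide significant European disease associations
    with a valid risk allele frequency; contaminant rows (one per failure
    mode: invalid frequency, non-European study, sub-threshold significance,
    non-disease trait) are injected at the stated fractions so the default
    filter removes exactly them.
    """

    seed: int = 0
    n_diseases: int = 280
    snvs_per_disease_mean: float = 11.7
    per_bin_minor_risk_prob: tuple[float, ...] = _DEFAULT_PI
    per_bin_weights: tuple[float, ...] = _DEFAULT_WEIGHTS
    p_value_range: tuple[float, float] = (1e-30, 5e-8)
    fraction_invalid_raf: float = 0.08
    fraction_non_european: float = 0.28
    fraction_high_p: float = 0.10
    fraction_trait: float = 0.05
    maf_density: str = "uniform"  # or "decreasing" (rarer alleles commoner)

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.snvs_per_disease_mean <= 0:
            raise ValueError("need at least one disease and a positive SNV mean")
        if len(self.per_bin_minor_risk_prob) != 5 or len(self.per_bin_weights) != 5:
            raise ValueError("per-bin parameters must have five entries")
        if any(not (0.0 <= p <= 1.0) for p in self.per_bin_minor_risk_prob):
            raise ValueError("minor-risk probabilities must be in [0, 1]")
        if abs(sum(self.per_bin_weights) - 1.0) > 1e-9:
            raise ValueError("per-bin weights must sum to 1")
        lo, hi = self.p_value_range
        if not (0.0 < lo < hi <= 5e-8):
            raise ValueError("p_value_range must satisfy 0 < low < high <= 5e-8")
        fracs = (
            self.fraction_invalid_raf,
            self.fraction_non_european,
            self.fraction_high_p,
            self.fraction_trait,
        )
        if any(f < 0.0 for f in fracs) or sum(fracs) >= 1.0:
            raise ValueError("contaminant fractions must be non-negative, sum < 1")
        if self.maf_density not in ("uniform", "decreasing"):
            raise ValueError("maf_density must be 'uniform' or 'decreasing'")


@dataclass(frozen=True)
class SyntheticLdSpec:
    """Recipe for a block-structured LD table.

    Within-block pairs draw r-squared strictly above the conventional 0.8
    pruning threshold, cross-block pairs strictly below it.
    """

    seed: int = 0
    mean_block_size: float = 3.0
    within_block_r2_range: tuple[float, float] = (0.85, 1.0)
    between_block_r2_range: tuple[float, float] = (0.0, 0.5)
    cross_pair_fraction: float = 0.25  # fraction of cross-block pairs emitted

    def __post_init__(self) -> None:
        wlo, whi = self.within_block_r2_range
        blo, bhi = self.between_block_r2_range
        if not (0.8 < wlo <= whi <= 1.0):
            raise ValueError("within-block r2 range must sit strictly above 0.8")
        if not (0.0 <= blo <= bhi <= 0.8):
            raise ValueError("between-block r2 range must sit at or below 0.8")
        if self.mean_block_size < 1.0:
            raise ValueError("mean block size must be at least 1")


@dataclass(frozen=True)
class SyntheticCatalog:
    """Generated records plus their ground truth.

    ``truth`` has one row per record: snv_id, disease, bin_index (pandas NA
    for rows without a usable frequency), risk_is_minor, contaminant (empty
    string for clean rows) — everything a test needs to check recovery.
    """

    records: tuple[AssociationRecord, ...]
    truth: pd.DataFrame
    disease_allowlist: frozenset[str]
    spec: SyntheticCatalogSpec

    def truth_to_json(self, stream: IO[str]) -> None:
        stream.write(self.truth.to_json(orient="records", indent=1))


def _draw_maf(rng: np.random.Generator, bin_index: int, density: str) -> float:
    lo, hi = MAF_BINS[bin_index].lower, MAF_BINS[bin_index].upper
    lo = max(lo, 1e-4)  # keep clear of monomorphic 0
    if density == "decreasing":
        # triangular density sloping down across the bin
        u = rng.random()
        return hi - (hi - lo) * np.sqrt(u)
    return float(rng.uniform(lo, hi))


def generate_catalog(spec: SyntheticCatalogSpec) -> SyntheticCatalog:
    """Generate a reproducible catalog with known per-bin composition."""
    rng = np.random.default_rng([spec.seed, _SALT_CATALOG])
    records: list[AssociationRecord] = []
    truth_rows: list[dict] = []
    allow: set[str] = set()
    pi = np.asarray(spec.per_bin_minor_risk_prob)
    weights = np.asarray(spec.per_bin_weights)
    log_lo, log_hi = np.log(spec.p_value_range)
    contam_fracs = np.array(
        [
            spec.fraction_invalid_raf,
            spec.fraction_non_european,
            spec.fraction_high_p,
            spec.fraction_trait,
        ]
    )
    contam_kinds = ("invalid_raf", "non_european", "high_p", "trait")
    probs = np.concatenate([[1.0 - contam_fracs.sum()], contam_fracs])

    snv_serial = 0
    for d in range(spec.n_diseases):
        disease = f"disease {d:04d}"
        allow.add(disease)
        n_snv = max(1, int(rng.poisson(spec.snvs_per_disease_mean)))
        for _ in range(n_snv):
            snv_serial += 1
            snv_id = f"rs{snv_serial:07d}"
            bin_index = int(rng.choice(5, p=weights))
            maf = _draw_maf(rng, bin_index, spec.maf_density)
            risk_is_minor = bool(rng.random() < pi[bin_index])
            raf: float | None = maf if risk_is_minor else 1.0 - maf
            p_value = float(np.exp(rng.uniform(log_lo, log_hi)))
            ancestry = Ancestry.EUROPEAN
            label = disease
            is_disease = True
            k = int(rng.choice(5, p=probs))
            kind = contam_kinds[k - 1] if k else ""
            if kind == "invalid_raf":
                raf = None
            elif kind == "non_european":
                ancestry = Ancestry.OTHER
            elif kind == "high_p":
                p_value = float(np.exp(rng.uniform(np.log(6e-8), np.log(1e-2))))
            elif kind == "trait":
                label = f"trait {d:04d}"
                is_disease = False
            records.append(
                AssociationRecord(
                    snv_id=snv_id,
                    disease=label,
                    risk_allele=str(rng.choice(list("ACGT"))),
                    risk_allele_frequency=raf,
                    p_value=p_value,
                    ancestry_label=ancestry,
                    study_id=f"GCST{d:06d}",
                    is_disease_trait=is_disease,
                )
            )
            truth_rows.append(
                {
                    "snv_id": snv_id,
                    "disease": label,
                    "bin_index": pd.NA if raf is None else bin_index,
                    "risk_is_minor": pd.NA if raf is None else risk_is_minor,
                    "contaminant": kind,
                }
            )
    return SyntheticCatalog(
        records=tuple(records),
        truth=pd.DataFrame(truth_rows),
        disease_allowlist=frozenset(allow),
        spec=spec,
    )


def generate_ld_table(
    records: Sequence[AssociationRecord], spec: SyntheticLdSpec
) -> tuple[LdTable, dict[tuple[str, str], str]]:
    """Partition each disease's SNVs into LD blocks and emit pairwise r2.

    Returns the table and the ground-truth block label for every
    (disease, snv_id), labels of the form ``"<disease>#<block index>"``.
    """
    rng = np.random.default_rng([spec.seed, _SALT_LD])
    table = LdTable()
    labels: dict[tuple[str, str], str] = {}
    by_disease: dict[str, list[str]] = {}
    for rec in records:
        ids = by_disease.setdefault(rec.disease, [])
        if rec.snv_id not in ids:
            ids.append(rec.snv_id)
    wlo, whi = spec.within_block_r2_range
    blo, bhi = spec.between_block_r2_range
    for disease in sorted(by_disease):
        ids = by_disease[disease]
        blocks: list[list[str]] = []
        i = 0
        while i < len(ids):
            size = max(1, int(rng.poisson(spec.mean_block_size - 1.0)) + 1)
            blocks.append(ids[i : i + size])
            i += size
        for b, members in enumerate(blocks):
            for snv in members:
                labels[(disease, snv)] = f"{disease}#{b}"
            for j, a in enumerate(members):
                for c in members[j + 1 :]:
                    table.set(a, c, float(rng.uniform(wlo, min(whi, 1.0 - 1e-12))))
        for bi in range(len(blocks)):
            for bj in range(bi + 1, len(blocks)):
                for a in blocks[bi]:
                    for c in blocks[bj]:
                        if rng.random() < spec.cross_pair_fraction:
                            table.set(a, c, float(rng.uniform(blo, bhi)))
    return table, labels


def _cohort_distributions(
    spec: PowerSpec, raf: float
) -> tuple[np.ndarray, np.ndarray]:
    risks = np.asarray(genotype_risks(spec.model, spec.grr))
    f0 = baseline_penetrance(raf, spec.prevalence, risks)
    hwe = np.array([(1.0 - raf) ** 2, 2.0 * raf * (1.0 - raf), raf**2])
    pen = f0 * risks
    case = hwe * pen
    ctrl = hwe * (1.0 - pen)
    return case / case.sum(), ctrl / ctrl.sum()


def sample_cohort(
    spec: PowerSpec,
    seed: int | np.random.Generator,
    raf: float | None = None,
) -> CohortCounts:
    """Draw one case-control cohort from the genotype distributions the
    study design implies."""
    q = spec.raf if raf is None else raf
    if q is None:
        raise ValueError("spec carries no risk allele frequency")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng([int(seed), _SALT_COHORT])
    )
    case_p, ctrl_p = _cohort_distributions(spec, q)
    case = rng.multinomial(spec.n_case, case_p)
    ctrl = rng.multinomial(spec.n_control, ctrl_p)
    return CohortCounts(
        n_case=spec.n_case,
        n_control=spec.n_control,
        case_counts=tuple(int(x) for x in case),
        control_counts=tuple(int(x) for x in ctrl),
    )


def empirical_power(
    spec: PowerSpec,
    n_reps: int,
    seed: int,
    raf: float | None = None,
    *,
    variance: str = "design",
) -> float:
    """Monte-Carlo detection rate of the two-proportion allele test.

    Vectorized over ``n_reps`` cohorts. ``variance="design"`` thresholds the
    case/control allele-frequency gap at z* times the standard error at the
    design (true) frequencies — the convention of the analytic calculator —
    while ``variance="plugin"`` uses the per-replicate estimated standard
    error (the test a practitioner actually runs; for small cohorts its
    rejection rate sits slightly off the analytic approximation).
    """
    q = spec.raf if raf is None else raf
    if q is None:
        raise ValueError("spec carries no risk allele frequency")
    if variance not in ("design", "plugin"):
        raise ValueError("variance must be 'design' or 'plugin'")
    rng = np.random.default_rng([int(seed), _SALT_COHORT])
    case_p, ctrl_p = _cohort_distributions(spec, q)
    cg = rng.multinomial(spec.n_case, case_p, size=n_reps)
    ng = rng.multinomial(spec.n_control, ctrl_p, size=n_reps)
    m_case, m_ctrl = 2 * spec.n_case, 2 * spec.n_control
    f_case = (cg[:, 1] + 2 * cg[:, 2]) / m_case
    f_ctrl = (ng[:, 1] + 2 * ng[:, 2]) / m_ctrl
    z_star = _sps.norm.isf(spec.alpha / 2.0)
    if variance == "design":
        from .power import case_control_allele_freqs

        fc, fn = case_control_allele_freqs(spec, q)
        se = np.sqrt(fc * (1.0 - fc) / m_case + fn * (1.0 - fn) / m_ctrl)
        reject = np.abs(f_case - f_ctrl) > z_star * se
    else:
        se = np.sqrt(
            f_case * (1.0 - f_case) / m_case + f_ctrl * (1.0 - f_ctrl) / m_ctrl
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(f_case - f_ctrl) / se
        reject = np.nan_to_num(z, nan=0.0) > z_star
    return float(reject.mean())
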