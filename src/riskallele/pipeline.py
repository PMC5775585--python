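"""End-to-end orchestration: filter -> prune -> bin -> enrich -> correct.

``run_pipeline`` drives the whole catalog analysis from a config object or
YAML file and writes machine-readable artifacts (filtered table, per-bin
enrichment CSV, power-corrected CSV per study, per-disease summary CSV) plus
a JSON run report. ``run_simulation_suite`` emits the S' grids and the
log-P curve sweeps. Reruns with identical config and inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    Ancestry,
    AssociationRecord,
    FilterCriteria,
    LdTable,
    filter_associations,
    ld_prune,
    parse_association_table,
    write_association_tsv,
)
from .enrichment import MinorAlleleEnrichment, disease_summaries
from .penetrance import DEFAULT_P_GRID, scenario_curves, sweep_r_d1, sweep_r_nc
from .power import DiseaseModel, PowerSpec
from .synthetic import SyntheticCatalogSpec, generate_catalog

__all__ = ["PipelineConfig", "run_pipeline", "run_simulation_suite"]

log = logging.getLogger("riskallele")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs. Exactly one of ``catalog_path`` or
    ``synthetic`` must be set."""

    output_dir: Path
    catalog_path: Path | None = None
    ld_path: Path | None = None
    synthetic: SyntheticCatalogSpec | None = None
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    prune: bool = False
    r2_threshold: float = 0.8
    studies: Mapping[str, PowerSpec] = field(default_factory=dict)
    disease_allowlist: Sequence[str] | None = None
    unique_snvs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.catalog_path is None) == (self.synthetic is None):
            raise ValueError(
                "provide exactly one of catalog_path or a synthetic spec"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        crit = raw.get("criteria", {})
        if "ancestry" in crit and crit["ancestry"] is not None:
            crit["ancestry"] = Ancestry(crit["ancestry"])
        studies = {}
        for name, s in (raw.get("studies") or {}).items():
            if "model" in s:
                s["model"] = DiseaseModel(s["model"])
            studies[name] = PowerSpec(**s)
        synth = raw.get("synthetic")
        return cls(
            output_dir=Path(raw["output_dir"]),
            catalog_path=Path(raw["catalog_path"]) if raw.get("catalog_path") else None,
            ld_path=Path(raw["ld_path"]) if raw.get("ld_path") else None,
            synthetic=SyntheticCatalogSpec(**synth) if synth else None,
            criteria=FilterCriteria(**crit),
            prune=bool(raw.get("prune", False)),
            r2_threshold=float(raw.get("r2_threshold", 0.8)),
            studies=studies,
            disease_allowlist=raw.get("disease_allowlist"),
            unique_snvs=bool(raw.get("unique_snvs", False)),
            seed=int(raw.get("seed", 0)),
        )


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, lineterminator="\n")
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the catalog analysis; returns (and writes) the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}
    report: dict = {"artifacts": artifacts, "seed": config.seed}

    if config.synthetic is not None:
        cat = generate_catalog(config.synthetic)
        records: Sequence[AssociationRecord] = cat.records
        allowlist = cat.disease_allowlist
        truth_path = out / "truth.json"
        with truth_path.open("w") as fh:
            cat.truth_to_json(fh)
        artifacts["truth"] = {"path": truth_path.name, "rows": len(cat.truth)}
    else:
        with Path(config.catalog_path).open() as fh:
            parsed = parse_association_table(
                fh, disease_allowlist=config.disease_allowlist
            )
        log.info("parsed %d records, skipped %d rows", len(parsed), parsed.n_skipped)
        records = parsed.records
        allowlist = None
        report["parse"] = {"records": len(parsed), "skipped": parsed.n_skipped}

    filtered = filter_associations(records, config.criteria)
    report["filter"] = {
        "input": filtered.n_input,
        "survivors": len(filtered),
        "removed": dict(filtered.removed),
    }
    records = list(filtered.records)
    if not records:
        log.warning("no records survive filtering; emitting empty artifacts")

    if config.prune:
        if config.ld_path is not None:
            with Path(config.ld_path).open() as fh:
                ld = LdTable.from_tsv(fh)
        else:
            ld = LdTable()
        n_before = len(records)
        records = list(ld_prune(records, ld, config.r2_threshold))
        report["prune"] = {"input": n_before, "survivors": len(records)}

    filtered_path = out / "filtered.tsv"
    with filtered_path.open("w") as fh:
        write_association_tsv(records, fh)
    artifacts["filtered"] = {"path": filtered_path.name, "rows": len(records)}

    model = MinorAlleleEnrichment(records, unique_snvs=config.unique_snvs)
    results = model.fit()
    enrich_path = out / "enrichment.csv"
    artifacts["enrichment"] = {
        "path": enrich_path.name,
        "rows": _write_csv(results.table, enrich_path),
    }
    report["ambiguous"] = results.n_ambiguous
    report["monomorphic"] = results.n_monomorphic

    for name, spec in config.studies.items():
        # a study keyed by a disease label corrects that disease's records;
        # otherwise the whole filtered set is corrected under that design
        sub = [r for r in records if r.disease == name] or records
        corrected = MinorAlleleEnrichment(sub, unique_snvs=config.unique_snvs).fit(
            power_spec=spec
        )
        path = out / f"corrected_{name}.csv"
        artifacts[f"corrected_{name}"] = {
            "path": path.name,
            "rows": _write_csv(corrected.table, path),
        }

    summaries = disease_summaries(records)
    dis_path = out / "diseases.csv"
    artifacts["diseases"] = {
        "path": dis_path.name,
        "rows": _write_csv(pd.DataFrame([s.__dict__ for s in summaries]), dis_path),
    }

    report["params"] = {
        "criteria": {
            "p_threshold": config.criteria.p_threshold,
            "require_valid_raf": config.criteria.require_valid_raf,
            "ancestry": config.criteria.ancestry.value if config.criteria.ancestry else None,
            "diseases_only": config.criteria.diseases_only,
        },
        "prune": config.prune,
        "r2_threshold": config.r2_threshold,
        "unique_snvs": config.unique_snvs,
    }
    if allowlist is not None:
        report["n_diseases_allowlisted"] = len(allowlist)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_simulation_suite(
    output_dir: str | Path,
    *,
    n_case: int = 1000,
    n_control: int = 1000,
    d1_range: Sequence[float] | None = None,
    r_range: Sequence[float] | None = None,
    nc_range: Sequence[int] | None = None,
    n_total: int = 2000,
    d1_fixed: float = 0.03,
    curve_rs: Sequence[float] = tuple(np.round(np.arange(1.1, 2.01, 0.1), 2)),
    round_counts: bool = True,
) -> dict:
    """Emit the S' grids and the per-odds-ratio log-P curves as CSV.

    Defaults reproduce the full published grids (25 baseline penetrances x
    95 odds ratios; 17 control counts); pass thinned ranges for a quick run.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict] = {}

    grid1 = sweep_r_d1(
        n_case, n_control, d1_range, r_range, round_counts=round_counts
    )
    g1 = out / "sprime_r_by_d1.csv"
    grid1.to_frame().to_csv(g1, lineterminator="\n")
    artifacts["sprime_r_by_d1"] = {
        "path": g1.name,
        "shape": list(grid1.s_prime.shape),
        "excluded": grid1.n_excluded,
    }

    grid2 = sweep_r_nc(
        n_total, d1_fixed, r_range, nc_range, round_counts=round_counts
    )
    g2 = out / "sprime_r_by_nc.csv"
    grid2.to_frame().to_csv(g2, lineterminator="\n")
    artifacts["sprime_r_by_nc"] = {
        "path": g2.name,
        "shape": list(grid2.s_prime.shape),
        "excluded": grid2.n_excluded,
    }

    rows = []
    for r in curve_rs:
        cm, cM, _ = scenario_curves(
            n_case, n_control, d1_fixed, r, round_counts=round_counts
        )
        for (p, lm), (_, lM) in zip(cm, cM):
            rows.append(
                {"r": r, "p": p, "log10_p_minor": lm, "log10_p_major": lM}
            )
    curves = out / "curves.csv"
    n = _write_csv(pd.DataFrame(rows), curves)
    artifacts["curves"] = {"path": curves.name, "rows": n}

    report = {
        "artifacts": artifacts,
        "params": {
            "n_case": n_case,
            "n_control": n_control,
            "n_total": n_total,
            "d1_fixed": d1_fixed,
            "round_counts": round_counts,
        },
    }
    (out / "simulation_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    return report
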