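"""End-to-end orchestration: dissect → descriptors → rotatable-bond filter
→ efficiency scoring → normalization → comparisons, with TSV/JSON outputs.

Two entry modes exist because a study's structures and its tables need not
travel together:

* **structure mode** — molecules in (SMILES file), full dissection, scaffold
  descriptors, filtering and scoring against a binding-energy table;
* **table mode** — a descriptor table and a binding table in, scoring and
  ranking only (used when only the printed tables of a study are at hand).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chem_graph, comparison, descriptors, dissection, efficiency
from .synthetic_data import parse_ic50

logger = logging.getLogger("fragrank")


@dataclass
class RunConfig:
    mode: str = "structure"  # "structure" | "table"
    molecules: str | None = None  # .smi or .sdf path (structure mode)
    binding: str | None = None  # TSV: id, delta_g_kcal_mol[, ic50_nM]
    descriptor_table: str | None = None  # TSV: id, HAC, MW (table mode)
    out_dir: str = "fragrank_out"
    temperature_K: float = efficiency.STANDARD_TEMPERATURE_K
    rotb_threshold: int = 10
    normalization: str = "minmax"
    tie_tolerance: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotb_threshold < 0:
            raise ValueError("rotatable-bond threshold must be >= 0")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.mode not in ("structure", "table"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunSummary:
    parsed: int
    kept: int
    discarded: int
    scored: int
    outputs: dict[str, str] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    if logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)
    return handler


def read_binding_tsv(path) -> list[efficiency.BindingRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        ic50 = None
        for col in ("ic50_nM", "ic50_nm"):
            if col in df.columns and not pd.isna(row[col]):
                ic50 = parse_ic50(row[col])
        records.append(
            efficiency.BindingRecord(
                id=str(row["id"]),
                delta_g=float(row["delta_g_kcal_mol"]),
                ic50_nM=ic50,
            )
        )
    return records


def _score_and_write(
    records: list[efficiency.BindingRecord],
    descs: dict[str, descriptors.DescriptorSet],
    config: RunConfig,
    out_dir: Path,
) -> dict[str, efficiency.EfficiencyScores]:
    constants = efficiency.ThermoConstants(T=config.temperature_K)
    scores = efficiency.score_fragments(records, descs, constants)
    ids = [r.id for r in records]
    rows = {
        "id": ids,
        "pKi": [scores[i].pki for i in ids],
        "LE": [scores[i].le for i in ids],
        "BEI": [scores[i].bei for i in ids],
    }
    if len(ids) >= 2:
        try:
            be_n = efficiency.normalize_series(
                [r.delta_g for r in records], magnitude=True
            )
            le_n = efficiency.normalize_series(rows["LE"])
            bei_n = efficiency.normalize_series(rows["BEI"])
            rows["BE_norm"] = be_n
            rows["LE_norm"] = le_n
            rows["BEI_norm"] = bei_n
            rows["delta_E"] = efficiency.delta_e_series(bei_n, le_n)
        except efficiency.DegenerateRangeError as exc:
            logger.warning("normalization skipped: %s", exc)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "scores.tsv", sep="\t", index=False,
              float_format="%.4f")
    return scores


def _comparison_report(
    records: list[efficiency.BindingRecord],
    scores: dict[str, efficiency.EfficiencyScores],
    config: RunConfig,
) -> dict:
    report: dict = {}
    ids = [r.id for r in records]
    if len(ids) >= 2:
        for metric, vals, larger, tol in (
            ("BE", {r.id: r.delta_g for r in records}, False, 0.0),
            ("LE", {i: scores[i].le for i in ids}, True, config.tie_tolerance),
            ("BEI", {i: scores[i].bei for i in ids}, True, 0.0),
        ):
            po = comparison.priority_order(
                vals, larger_is_better=larger, tolerance=tol, metric=metric
            )
            report[f"priority_{metric}"] = po.as_string()
        with_ic50 = {
            r.id: r.ic50_nM for r in records if r.ic50_nM is not None
        }
        if len(with_ic50) >= 2:
            exp = comparison.priority_order(
                with_ic50, larger_is_better=False, metric="IC50"
            )
            report["priority_IC50"] = exp.as_string()
            metrics = {
                i: {"BE": next(r.delta_g for r in records if r.id == i),
                    "LE": scores[i].le, "BEI": scores[i].bei}
                for i in with_ic50
            }
            side = comparison.side_chain_effect_report(
                with_ic50, metrics, le_tolerance=config.tie_tolerance
            )
            report["side_chain_effect"] = {
                "experimental_order": side.experimental_order.as_string(),
                "metric_orders": {
                    m: po.as_string() for m, po in side.metric_orders.items()
                },
                "discordant": side.discordant,
                "any_discordant": side.any_discordant,
            }
    return report


def run_pipeline(config: RunConfig) -> RunSummary:
    """Run the full analysis; writes outputs into ``config.out_dir`` and
    returns per-stage counts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir)
    try:
        return _run(config, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> RunSummary:
    outputs: dict[str, str] = {}

    if config.mode == "structure":
        if not config.molecules:
            raise StageError("parse", "structure mode needs a molecules path")
        try:
            path = Path(config.molecules)
            if path.suffix.lower() in (".sdf", ".mol"):
                mols = chem_graph.read_sdf(path)
            else:
                mols = chem_graph.read_smiles_file(path)
        except (chem_graph.SmilesParseError, chem_graph.SdfFormatError) as exc:
            raise StageError("parse", str(exc)) from exc
        logger.info("parsed %d molecules", len(mols))

        try:
            results = {m.identifier: dissection.dissect(m) for m in mols}
        except dissection.EmptyScaffoldError as exc:
            raise StageError("dissection", str(exc)) from exc
        dissection.write_dissection_json(out_dir / "dissection.json", mols)
        dissection.write_frameworks_tsv(out_dir / "frameworks.tsv", mols)
        outputs["dissection"] = str(out_dir / "dissection.json")
        outputs["frameworks"] = str(out_dir / "frameworks.tsv")

        scaffolds = [results[m.identifier].scaffold for m in mols]
        kept, discarded = descriptors.filter_by_rotb(
            scaffolds, config.rotb_threshold
        )
        kept_ids = {s.identifier.split("|")[0] for s in kept}
        logger.info(
            "rotatable-bond filter (<= %d): kept %d, discarded %d",
            config.rotb_threshold, len(kept), len(discarded),
        )
        if not kept:
            logger.warning("no molecule passed the rotatable-bond filter")
        descriptors.write_descriptors_tsv(out_dir / "descriptors.tsv", kept)
        outputs["descriptors"] = str(out_dir / "descriptors.tsv")

        descs = {
            s.identifier.split("|")[0]: descriptors.compute_descriptors(s)
            for s in kept
        }
        records = []
        if config.binding:
            records = [
                r for r in read_binding_tsv(config.binding) if r.id in descs
            ]
        parsed_n, kept_n, disc_n = len(mols), len(kept), len(discarded)
    else:  # table mode
        if not (config.descriptor_table and config.binding):
            raise StageError(
                "load", "table mode needs descriptor_table and binding paths"
            )
        df = pd.read_csv(config.descriptor_table, sep="\t")
        descs = {
            str(row["id"]): descriptors.DescriptorSet(
                hac=int(row["HAC"]), mw=float(row["MW"]),
                hbd=int(row.get("HBD", 0)), hba=int(row.get("HBA", 0)),
                rotb=int(row.get("RotB", 0)),
            )
            for _, row in df.iterrows()
        }
        records = read_binding_tsv(config.binding)
        missing = [r.id for r in records if r.id not in descs]
        if missing:
            raise StageError("score", f"no descriptors for {missing}")
        parsed_n = kept_n = len(records)
        disc_n = 0

    scores: dict[str, efficiency.EfficiencyScores] = {}
    if records:
        try:
            scores = _score_and_write(records, descs, config, out_dir)
        except (KeyError, ValueError) as exc:
            raise StageError("score", str(exc)) from exc
        outputs["scores"] = str(out_dir / "scores.tsv")
        report = _comparison_report(records, scores, config)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        outputs["report"] = str(out_dir / "report.json")
    else:
        logger.warning("no binding records: scoring stage skipped")
        pd.DataFrame(columns=["id", "pKi", "LE", "BEI"]).to_csv(
            out_dir / "scores.tsv", sep="\t", index=False
        )
        outputs["scores"] = str(out_dir / "scores.tsv")

    summary = RunSummary(
        parsed=parsed_n, kept=kept_n, discarded=disc_n,
        scored=len(scores), outputs=outputs,
    )
    logger.info(
        "run complete: parsed=%d kept=%d discarded=%d scored=%d",
        summary.parsed, summary.kept, summary.discarded, summary.scored,
    )
    return summary
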