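"""Run-configuration plumbing: stage chaining, seed fan-out, manifest.

A YAML run config holds one block per stage; every block is validated
against its module's parameter contract before any stage runs, any stage
error aborts with the stage name, and the manifest records parameters,
derived seeds, output checksums and row counts so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import matrix_io, qc, scoring, screen, synthetic
from .errors import ConfigError, SigcorrError

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "qc", "score", "screen", "shift"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: first 8 hex digits of sha256('seed:stage')."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        out_dir = raw.get("out_dir")
        if out_dir is None:
            raise ConfigError("run config needs out_dir")
        stages = {k: v for k, v in raw.items() if k in STAGE_ORDER}
        return cls(out_dir=Path(out_dir), seed=int(raw.get("seed", 0)), stages=stages)

    def validate(self) -> None:
        for name in self.stages:
            if name not in STAGE_ORDER:
                raise ConfigError(f"unknown stage {name!r}")
        if "simulate" in self.stages:
            self._synthetic_config().validate()
        if "qc" in self.stages:
            self._thresholds()
        if "screen" in self.stages:
            blk = self.stages["screen"]
            if "target" not in blk or "candidates" not in blk:
                raise ConfigError("screen stage needs target and candidates")
            self._screen_config()

    def _synthetic_config(self) -> synthetic.SyntheticConfig:
        blk = dict(self.stages["simulate"])
        modules = [synthetic.ModuleSpec(**m) for m in blk.pop("modules", [])]
        blk.setdefault("seed", stage_seed(self.seed, "simulate"))
        return synthetic.SyntheticConfig(modules=modules, **blk)

    def _thresholds(self) -> qc.QCThresholds:
        blk = self.stages.get("qc", {})
        return qc.QCThresholds(
            min_features=int(blk.get("min_features", 200)),
            max_features=int(blk.get("max_features", 7000)),
            max_percent_mt=float(blk.get("max_percent_mt", 20.0)),
            min_cells_per_gene=int(blk.get("min_cells", 3)),
        )

    def _screen_config(self) -> screen.ScreenConfig:
        blk = self.stages.get("screen", {})
        return screen.ScreenConfig(
            r_min_pos=blk.get("r_min"),
            r_max_neg=blk.get("r_max_neg"),
            top_k=int(blk.get("top_k", 20)),
            min_cells=int(blk.get("min_cells", 10)),
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    matrix = None
    annotation = None
    score_tbl = None

    for name in STAGE_ORDER:
        if name not in config.stages:
            continue
        blk = config.stages[name] or {}
        entry: dict = {"params": blk, "outputs": {}}
        try:
            if name == "simulate":
                scfg = config._synthetic_config()
                result = synthetic.generate_counts(scfg)
                sim_dir = out_dir / "sim"
                synthetic.write_synthetic(result, sim_dir)
                matrix, annotation = result.matrix, result.annotation
                entry["seed"] = scfg.seed
                entry["rows"] = {"cells": matrix.n_cells, "genes": matrix.n_genes}
                for f in ("matrix.mtx", "features.tsv", "barcodes.tsv",
                          "annotation.tsv", "planted_truth.json"):
                    entry["outputs"][f] = file_checksum(sim_dir / f)
            elif name == "qc":
                if matrix is None:
                    in_dir = Path(blk["in_dir"])
                    matrix = matrix_io.read_mtx(in_dir)
                    annotation = matrix_io.read_annotation(in_dir / "annotation.tsv")
                thr = config._thresholds()
                matrix, report = qc.run_qc(matrix, thr)
                annotation = annotation.loc[matrix.cells]
                qc_dir = out_dir / "qc"
                matrix_io.write_mtx(matrix, qc_dir)
                matrix_io.write_annotation(annotation, qc_dir / "annotation.tsv")
                report.to_csv(qc_dir / "qc_report.tsv", sep="\t", index=False)
                entry["rows"] = {"cells": matrix.n_cells, "genes": matrix.n_genes}
                entry["outputs"]["qc_report.tsv"] = file_checksum(qc_dir / "qc_report.tsv")
            elif name == "score":
                if matrix is None:
                    raise ConfigError("score stage needs a matrix (simulate/qc first)")
                sigs = _stage_signatures(blk, out_dir)
                score_tbl = scoring.score_table(matrix, sigs, annotation)
                path = out_dir / "scores.tsv"
                scoring.write_score_table(score_tbl, path)
                entry["rows"] = {"cells": len(score_tbl), "signatures": len(sigs)}
                entry["outputs"]["scores.tsv"] = file_checksum(path)
            elif name == "screen":
                if score_tbl is None:
                    raise ConfigError("screen stage needs scores (score first)")
                scr_cfg = config._screen_config()
                tables = {}
                conditions = blk.get("conditions") or [blk.get("condition")]
                for cond in conditions:
                    tbl = screen.screen(
                        score_tbl, blk["target"], blk["candidates"],
                        cluster=blk.get("cluster"), condition=cond, config=scr_cfg,
                    )
                    path = out_dir / f"screen_{cond or 'all'}.tsv"
                    tbl.to_csv(path, sep="\t", index=False)
                    tables[cond] = tbl
                    entry["outputs"][path.name] = file_checksum(path)
                entry["rows"] = {c or "all": len(t) for c, t in tables.items()}
                manifest["_screens"] = tables
            elif name == "shift":
                screens = manifest.pop("_screens", None)
                if not screens or len(screens) != 2:
                    raise ConfigError("shift stage needs a screen stage with two conditions")
                (ca, ta), (cb, tb) = screens.items()
                tbl = screen.correlation_shift(ta, tb, floor=float(blk.get("floor", 0.1)))
                path = out_dir / "shift.tsv"
                tbl.to_csv(path, sep="\t", index=False)
                entry["rows"] = {"pairs": len(tbl)}
                entry["outputs"]["shift.tsv"] = file_checksum(path)
        except SigcorrError as exc:
            raise SigcorrError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = entry
        logger.info("stage %s done", name)

    manifest.pop("_screens", None)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_signatures(blk: dict, out_dir: Path) -> list:
    if "signatures_file" in blk:
        return matrix_io.read_signatures(blk["signatures_file"])
    if "signatures" in blk:  # inline {name: [genes]} mapping
        return [matrix_io.SignatureDefinition(name=k, genes=v)
                for k, v in blk["signatures"].items()]
    raise ConfigError("score stage needs signatures or signatures_file")
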