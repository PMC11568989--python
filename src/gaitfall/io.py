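"""Readers, writers and the end-to-end pipeline orchestration.

Signals travel as delimited text: either a headered CSV with columns
``time,v,ml,ap`` or a headerless 3-column file (V, ML, AP). A cohort is a
YAML manifest listing subject id, signal file, sampling rate and label.
A best-effort reader for PhysioNet-style records is provided behind a lazy
``wfdb`` import.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify_eval import EvaluationReport, make_mlp_eval_fn, model_select
from .errors import InvalidInputError
from .feature_table import FeatureMatrix, build_matrix, write_feature_table
from .preprocess import TriaxialRecording
from .relieff import SelectionSweepConfig, SweepResult, selection_sweep

log = logging.getLogger(__name__)

GRID_COLUMNS = [
    "K", "N", "hidden_units", "AUC", "accuracy", "sensitivity",
    "specificity", "TP", "FN", "FP", "TN",
]


def read_signal_csv(path: str | Path) -> np.ndarray:
    """Load an (n, 3) V/ML/AP signal from delimited text."""
    path = Path(path)
    first = path.open().readline()
    try:  # a first token that parses as a number means no header row
        float(first.split(",")[0])
        has_header = False
    except ValueError:
        has_header = True
    if has_header:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        missing = {"v", "ml", "ap"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
        data = df[["v", "ml", "ap"]].to_numpy(dtype=float)
    else:
        data = pd.read_csv(path, header=None).to_numpy(dtype=float)
        if data.shape[1] != 3:
            raise InvalidInputError(
                f"{path}: headerless signal must have 3 columns, got {data.shape[1]}"
            )
    return data


def write_signal_csv(path: str | Path, samples: np.ndarray, fs_hz: float) -> None:
    n = samples.shape[0]
    df = pd.DataFrame(
        {
            "time": np.arange(n) / fs_hz,
            "v": samples[:, 0],
            "ml": samples[:, 1],
            "ap": samples[:, 2],
        }
    )
    df.to_csv(path, index=False)


def write_cohort(cohort: list[TriaxialRecording], out_dir: str | Path) -> Path:
    """Write per-subject CSV signals and a YAML manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort:
        fname = f"{rec.subject_id}.csv"
        write_signal_csv(out_dir / fname, rec.samples, rec.fs_hz)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "file": fname,
                "fs_hz": rec.fs_hz,
                "label": rec.label,
            }
        )
    manifest = out_dir / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"subjects": entries}, sort_keys=False))
    return manifest


def load_cohort(manifest_path: str | Path) -> list[TriaxialRecording]:
    """Load every subject listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    spec = yaml.safe_load(manifest_path.read_text())
    cohort = []
    for entry in spec["subjects"]:
        path = manifest_path.parent / entry["file"]
        cohort.append(
            TriaxialRecording(
                subject_id=str(entry["subject_id"]),
                fs_hz=float(entry["fs_hz"]),
                samples=read_signal_csv(path),
                label=entry.get("label", "unknown"),
            )
        )
    return cohort


def read_physionet_record(record_path: str | Path, label: str = "unknown") -> TriaxialRecording:
    """Best-effort reader for PhysioNet-style signal/header file pairs.

    Requires the optional ``wfdb`` package; the CSV + manifest path is the
    supported route.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise InvalidInputError(
            "reading PhysioNet records requires the optional 'wfdb' package; "
            "convert the record to CSV instead"
        ) from exc
    record = wfdb.rdrecord(str(record_path))  # pragma: no cover
    return TriaxialRecording(  # pragma: no cover
        subject_id=Path(record_path).stem,
        fs_hz=float(record.fs),
        samples=np.asarray(record.p_signal[:, :3], dtype=float),
        label=label,
    )


def sweep_to_frame(sweep: SweepResult) -> pd.DataFrame:
    """Flatten a sweep grid into the study's result-table column layout."""
    rows = [r.as_row() for r in sweep.reports()]
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def write_grid_csv(sweep: SweepResult, path: str | Path) -> None:
    sweep_to_frame(sweep).to_csv(path, index=False)


def read_grid_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_best_report(report: EvaluationReport, path: str | Path) -> None:
    payload = report.as_row()
    payload["seed"] = report.seed
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class RunConfig:
    """Everything needed to replay an end-to-end run."""

    manifest: str
    out_dir: str
    k_range: tuple[int, ...] = tuple(range(1, 41))
    n_range: tuple[int, ...] = tuple(range(5, 41))
    hidden_sweep: tuple[int, ...] = tuple(range(10, 201, 10))
    n_folds: int = 10
    seed: int = 0


def run_pipeline(cfg: RunConfig) -> EvaluationReport:
    """manifest -> features -> selection sweep -> evaluation -> best model.

    Writes ``features.csv``, ``grid.csv``, ``best_model.json`` and
    ``run_log.json`` (config, seeds, exclusions) under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(cfg.manifest)
    matrix = build_matrix(cohort)
    write_feature_table(matrix, out / "features.csv")
    eval_fn = make_mlp_eval_fn(
        matrix, hidden_sweep=cfg.hidden_sweep, n_folds=cfg.n_folds, seed=cfg.seed
    )
    sweep = selection_sweep(
        matrix, SelectionSweepConfig(cfg.k_range, cfg.n_range), eval_fn
    )
    write_grid_csv(sweep, out / "grid.csv")
    best = model_select(sweep.reports())
    write_best_report(best, out / "best_model.json")
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "config": dataclasses.asdict(cfg),
                "n_subjects": matrix.n_subjects,
                "exclusions": matrix.exclusions,
                "n_weightings": sweep.n_weightings,
                "n_cells": sweep.n_cells,
                "skipped_cells": sweep.skipped,
            },
            indent=2,
        )
    )
    return best
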