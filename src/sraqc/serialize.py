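"""JSON-lines and TSV serialization of run and experiment records.

JSON-lines (one record per line) is the canonical intermediate format —
it streams at repository scale.  TSV carries the flat run/experiment
metrics with a fixed, documented column order; the per-position tables
only round-trip through JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .aggregate import ExperimentQuality
from .qc_metrics import PositionQuality, RunQuality

__all__ = [
    "run_to_dict",
    "run_from_dict",
    "write_jsonl",
    "read_runs_jsonl",
    "read_experiments_jsonl",
    "experiments_to_frame",
    "runs_to_frame",
    "RUN_TSV_COLUMNS",
    "EXPERIMENT_TSV_COLUMNS",
]

RUN_TSV_COLUMNS = [
    "run_id",
    "total_reads",
    "total_bases",
    "pct_gc",
    "mean_length",
    "median_length",
    "duplicate_pct",
    "mean_accuracy",
    "median_accuracy",
    "n_content_pct",
]

EXPERIMENT_TSV_COLUMNS = [
    "experiment_id",
    "n_runs",
    "total_reads",
    "total_bases",
    "mean_length",
    "median_length",
    "pct_gc",
    "duplicate_pct",
    "mean_accuracy",
    "median_accuracy",
    "n_content_pct",
]


def run_to_dict(rq: RunQuality) -> dict:
    d = asdict(rq)
    # JSON objects need string keys; keep int lengths recoverable
    d["length_distribution"] = {str(k): v for k, v in rq.length_distribution.items()}
    d["per_position_n"] = [list(t) for t in rq.per_position_n]
    return d


def run_from_dict(d: dict) -> RunQuality:
    d = dict(d)
    d["length_distribution"] = {
        (int(k) if isinstance(k, str) and k.isdigit() else k): v
        for k, v in d["length_distribution"].items()
    }
    d["per_position_quality"] = [
        PositionQuality(**row) for row in d["per_position_quality"]
    ]
    d["per_position_n"] = [tuple(t) for t in d["per_position_n"]]
    return RunQuality(**d)


def write_jsonl(records: Iterable[RunQuality | ExperimentQuality], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            d = run_to_dict(rec) if isinstance(rec, RunQuality) else asdict(rec)
            fh.write(json.dumps(d) + "\n")
            n += 1
    return n


def read_runs_jsonl(path: str | Path) -> list[RunQuality]:
    with open(path) as fh:
        return [run_from_dict(json.loads(line)) for line in fh if line.strip()]


def read_experiments_jsonl(path: str | Path) -> list[ExperimentQuality]:
    with open(path) as fh:
        return [ExperimentQuality(**json.loads(line)) for line in fh if line.strip()]


def runs_to_frame(runs: Sequence[RunQuality]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in RUN_TSV_COLUMNS} for r in runs]
    return pd.DataFrame(rows, columns=RUN_TSV_COLUMNS)


def experiments_to_frame(experiments: Sequence[ExperimentQuality]) -> pd.DataFrame:
    rows = [
        {f.name: getattr(e, f.name) for f in fields(ExperimentQuality)}
        for e in experiments
    ]
    return pd.DataFrame(rows, columns=EXPERIMENT_TSV_COLUMNS)
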