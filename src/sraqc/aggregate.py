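"""Run-to-experiment concatenation of quality values.

An SRA experiment can comprise several sequencing runs.  To make
experiments comparable, the run-level records are concatenated into one
experiment-level record: read and base totals are *added*, every other
quality value (mean/median length, %GC, duplicate percentage, mean/median
base call accuracy, N content) is *averaged* across runs.  The average is
unweighted by default; a read-weighted variant is available via
``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .qc_metrics import RunQuality

__all__ = ["ExperimentQuality", "aggregate_experiment", "group_runs"]

#: run-level fields that are averaged across runs (everything else is added)
AVERAGED_FIELDS = (
    "mean_length",
    "median_length",
    "pct_gc",
    "duplicate_pct",
    "mean_accuracy",
    "median_accuracy",
    "n_content_pct",
)


@dataclass
class ExperimentQuality:
    """Concatenated quality record of one experiment (>= 1 runs)."""

    experiment_id: str
    n_runs: int
    total_reads: int
    total_bases: int
    mean_length: float
    median_length: float
    pct_gc: float
    duplicate_pct: float
    mean_accuracy: float
    median_accuracy: float
    n_content_pct: float

    @property
    def throughput(self) -> int:
        """Total sequenced bases attributed to the experiment."""
        return self.total_bases


def aggregate_experiment(
    experiment_id: str,
    runs: Sequence[RunQuality],
    weighted: bool = False,
) -> ExperimentQuality:
    """Concatenate the runs of one experiment into a single record.

    ``weighted=True`` weights the averaged fields by each run's read
    count instead of giving every run equal weight.
    """
    if not runs:
        raise ValueError(f"experiment {experiment_id!r}: no runs")
    ids = [r.run_id for r in runs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"experiment {experiment_id!r}: duplicate run_id {dupes}")

    weights = np.array([r.total_reads for r in runs], dtype=float) if weighted else None
    if weights is not None and weights.sum() == 0:
        weights = None

    def avg(attr: str) -> float:
        vals = np.array([getattr(r, attr) for r in runs], dtype=float)
        return float(np.average(vals, weights=weights))

    return ExperimentQuality(
        experiment_id=experiment_id,
        n_runs=len(runs),
        total_reads=sum(r.total_reads for r in runs),
        total_bases=sum(r.total_bases for r in runs),
        **{f: avg(f) for f in AVERAGED_FIELDS},
    )


def group_runs(
    run_records: Sequence[RunQuality],
    mapping: Mapping[str, str],
    weighted: bool = False,
) -> list[ExperimentQuality]:
    """Group runs by experiment and aggregate each group.

    ``mapping`` takes run_id to experiment_id and must cover every run.
    Output is sorted by experiment_id.
    """
    unmapped = sorted(r.run_id for r in run_records if r.run_id not in mapping)
    if unmapped:
        raise ValueError(f"unmapped run_id(s): {', '.join(unmapped)}")
    groups: dict[str, list[RunQuality]] = {}
    for rec in run_records:
        groups.setdefault(mapping[rec.run_id], []).append(rec)
    return [
        aggregate_experiment(exp_id, runs, weighted=weighted)
        for exp_id, runs in sorted(groups.items())
    ]
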