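"""Concatenate several runs into one experiment-level record.

Read/base totals are added across runs; every other quality value is
averaged, so experiments with different run counts stay comparable.
"""

import tempfile
from pathlib import Path

from sraqc import SyntheticSpec, aggregate_experiment, compute_run_quality, generate_fastq

runs = []
with tempfile.TemporaryDirectory() as tmp:
    for i, gc in enumerate([0.40, 0.50, 0.60]):
        fastq = Path(tmp) / f"run{i}.fastq"
        generate_fastq(SyntheticSpec(n_reads=1000, gc_prob=gc, seed=100 + i), fastq)
        runs.append(compute_run_quality(f"RUN{i}", fastq))

exp = aggregate_experiment("EXP1", runs)

for r in runs:
    print(f"{r.run_id}: reads={r.total_reads}  %GC={r.pct_gc:.2f}  Q={r.mean_accuracy:.2f}")
print(
    f"{exp.experiment_id}: runs={exp.n_runs}  reads={exp.total_reads} (added)  "
    f"%GC={exp.pct_gc:.2f} (averaged)  throughput={exp.throughput} bases"
)

# With three 1000-read runs the experiment totals 3000 reads, while %GC is
# the plain mean of the three per-run values (~50), not read-weighted.
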