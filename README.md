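# sraqc

Quality metrics for high-throughput sequencing runs, experiment-level
aggregation, and repository-scale QC summaries.

## The problem

Public sequencing repositories hold millions of experiments, but their
search interfaces filter on submitter-described metadata only. To pick a
reusable subset — "human RNA-Seq with decent base quality and enough
reads" — users need *quantitative* quality values per experiment, which
otherwise requires downloading and QC-ing every candidate dataset
themselves. `sraqc` computes those values from raw FASTQ (or recovers
them from existing FastQC reports), rolls them up from runs to
experiments, joins them with experiment/sample metadata, and summarizes
whole corpora, with TSV/JSON-lines/RDF export for downstream indexing.

## The quantities

Per sequencing run (one FASTQ file, or a `_1`/`_2` paired-end pair):

| value | definition |
|---|---|
| total reads, total bases | counts over the file |
| %GC | 100·(G+C)/(A+C+G+T), N and other letters excluded |
| mean / median read length | from the length distribution; bins contribute midpoints |
| per-position quality | mean, median, quartiles of Phred Q per position |
| mean / median base call accuracy | unweighted mean of per-position means; lower median of per-position medians (Phred scale, Q = −10·log₁₀ p\_error) |
| duplicate % | 100·(1 − distinct/total) over sequence keys (reads > 75 bp keyed by their first 50 bp); a capped tracker with hypergeometric occupancy correction bounds memory at scale |
| N content % | unweighted mean of per-position percent-N |

Quantiles use lower nearest rank throughout; medians of even-sized
samples take the lower central value.

Runs concatenate to experiments by the add/average rule: read and base
totals are **added**, every other value is **averaged** (unweighted)
across runs; paired-end mates merge the same way. An experiment's
throughput is its total bases.

## Worked example

```python
from sraqc import SyntheticSpec, generate_fastq, compute_run_quality

truth = generate_fastq(
    SyntheticSpec(n_reads=5000, length=100, gc_prob=0.48, n_prob=0.005,
                  q_intercept=37, q_slope=-0.08, seed=42),
    "run.fastq",
)
rq = compute_run_quality("DEMO_RUN", "run.fastq")
```

prints (via `python examples/run_quality_from_fastq.py`):

```
total reads      5000
total bases      500000
%GC              48.05   (generator tallied 48.05)
mean length      100.0
mean accuracy Q  32.96  (unweighted over positions)
median accuracy  33.0
duplicate %      0.00
N content %      0.497
```

%GC and N content match the generator's tallied ground truth exactly —
they are deterministic functions of the emitted reads. The mean accuracy
of ~33 reflects the simulated Q37 start decaying 0.08 per position,
averaged unweighted over positions 1–100.

The other scripts in `examples/` cover run→experiment aggregation,
corpus summaries (category tables, threshold fractions, quarterly box
plots), and RDF export; each prints its results with a note on what they
mean. The `sraqc` console script exposes the same steps as subcommands
(`compute`, `from-fastqc`, `aggregate`, `join`, `summarize`, `simulate`,
`export-rdf`).

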