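# Methods

## Scope and model

`sraqc` computes comparable quality values for sequencing runs and
experiments. A *run* is one FASTQ file or a `_1`/`_2` paired-end pair; an
*experiment* groups one or more runs under a repository accession. The
package's unit of comparison is the experiment: run-level metrics are
concatenated so that experiments with different numbers of runs remain
directly comparable.

The run-level metrics mirror the FastQC module outputs a QC pipeline
would produce (Basic Statistics, Sequence Length Distribution, Per Base
Sequence Quality, Per Base N Content, Duplicate Sequences), so records
computed natively from FASTQ and records parsed from an existing
`fastqc_data.txt` report are interchangeable.

## Conventions

One quantile convention is used everywhere: **lower nearest rank** — the
p-quantile of a sorted sample of size n is the element at rank
⌈p·n⌉, and the median of an even-sized sample is the lower central
value. Stating this once removes every tie-break ambiguity from the
oracles in the test suite.

Percentages intended for publication-style tables are rounded **half
away from zero to one decimal** (`Decimal`-based, not binary-float
rounding). This convention exactly reproduces published repository
percentages from their underlying counts.

## Per-run metrics

* **%GC** counts G+C over A+C+G+T; N and other IUPAC letters are
  excluded from numerator and denominator ("called bases" semantics, so
  %GC + %AT = 100). Sequences are uppercased on input; case carries no
  information for quality metrics.
* **Length statistics** come from the length distribution. Binned
  entries ("lo-hi", as some FastQC versions emit) contribute their
  midpoint; the median is the representative value of the entry holding
  the ⌈n/2⌉-th read. Native computation never bins — binning is a
  display compaction of FastQC reports, lossy and version-dependent —
  so bins only appear when parsing foreign reports.
* **Base call accuracy** (Phred scale) is summarized per position over
  the reads covering that position, then reduced to run level
  *unweighted*: the mean accuracy is the plain mean of the per-position
  means and the median accuracy the lower median of the per-position
  medians. The unweighted choice matches reduction over a per-position
  report table, where each position is one row regardless of coverage;
  a read-count-weighted variant would require the raw file and is not
  the default.
* **N content** is the per-position percentage of N calls, reduced to
  run level as the unweighted mean over positions 1..max read length.
* **Duplicate percentage** keys each read by its sequence, truncated to
  the first 50 bases for reads longer than 75 (so long-read chemistry
  does not defeat duplicate detection). *Exact* mode reports
  100·(T−U)/T for T reads and U distinct keys. *Capped* mode (the
  default, matching FastQC v0.11 behaviour with its 100 000-key
  tracker) tracks only the first 100 000 distinct keys; each tracked
  count c is divided by the probability that such a key would have been
  seen among the first `countAtLimit` reads — a hypergeometric
  no-draw complement evaluated in log-gamma space — and the corrected
  distinct/total masses give the estimate. Capped mode equals exact
  mode whenever the tracker never fills; it is the one metric that is
  order-sensitive by construction (it tracks the *first* keys seen).

All metrics are computed in one streaming pass (per-position score
histograms, length tallies, key counters), so memory does not grow with
file size except for the bounded duplication tracker.

## Aggregation rules

Run → experiment: read and base totals are **added**; mean/median
length, %GC, duplicate %, mean/median accuracy and N content are
**averaged**, unweighted, across runs (a read-weighted option exists).
Paired-end mates merge by the same rule before aggregation. Total bases
is treated as an added field by analogy with total reads, and an
experiment's throughput is defined as this sum. For experiments mixing
paired and single-end runs, each run's already-merged record enters the
average uniformly. Per-position tables of a merged pair are averaged
positionwise over the mates covering each position; pooled length
distributions keep the count-sum invariant with the summed base total.

## FASTQ dialect and encoding detection

Only strict 4-line FASTQ is accepted (the dialect paired-end splitting
tools emit); wrapped records are rejected rather than guessed at, and
gzip is detected from magic bytes. The Phred offset is detected from the
quality characters: any ASCII below 59 forces offset 33, characters
above 74 with nothing below 59 indicate offset 64, and ambiguous files
default to 33 since all post-2011 Illumina data uses it.

## FastQC report interchange

`parse_fastqc_data` reads the tab-separated module blocks and re-derives
the accuracy summaries from the per-base table with the same unweighted
rules as native computation, making the two paths mutually consistent
(serialize → parse reproduces all eight run-level values within
rounding). Binned position fields are kept as single entries at their
midpoint. Both the "Total Duplicate Percentage" and "Total Deduplicated
Percentage" spellings of the duplication total are accepted, the latter
as its complement. Total bases is reconstructed from the length
distribution and is exact whenever the distribution is unbinned.

## Metadata and joining

Experiment metadata comes from SRA EXPERIMENT-set XML (or a flat TSV
with the same columns); organism information from BioSample XML. Parsing
ignores namespaces and element order. The instrument manufacturer is
derived from the PLATFORM child element name through a shipped, editable
mapping (ILLUMINA→Illumina, LS454→454, PACBIO_SMRT→PacBio, …;
unmapped→Unknown). Joins are left joins keyed on experiment_id then
biosample_id: quality records are never dropped or duplicated, and
match/unmatch counts are reported rather than raised. Submitter metadata
is propagated as-is; it may contain errors and correcting it is out of
scope. The date used for time series is configurable (the published
date attribute by default) because which calendar field a given archive
snapshot carries is not uniform.

## Corpus summaries

* Category tables count distinct values (missing grouped as
  "(missing)"), order by count descending with lexical tie-break, keep
  the top N and always emit an "other" remainder row so counts stay
  closed under the corpus total.
* Histograms use equal-width half-open bins [lo, hi) on a linear or
  log10 scale; the final bin additionally includes its upper edge so the
  maximum value is counted and bin totals plus exclusions equal the
  input length. Non-finite values (and non-positives under log10) are
  excluded and counted. A degenerate min==max range gets a single
  [min, min+1) bin.
* Threshold fractions use strict less-than.
* Quarterly tables group by calendar quarter ("YYYY-Qn"), emit n, the
  five-number summary (lower-nearest-rank quartiles, no whisker
  truncation — rendering concerns stay out of the table) and the mean;
  undated rows are excluded and counted, empty quarters omitted.

## Synthetic data

The generator emulates the statistical structure the metrics respond
to: iid bases with a set GC probability and per-base N probability, a
fixed or categorical read-length distribution, per-position quality
drawn as round(clamp(Normal(intercept + slope·i, sd), lo, hi)), and an
optional template pool (n templates × k copies, shuffled) giving an
exactly known duplicate percentage of 100·(1 − n/(n·k)). Defaults are
a 1000-read, 100 bp, 50% GC, N-free run with flat Q38±2 quality —
ordinary short-read values. Ground truth is **tallied from the emitted
reads**, never taken from the generating parameters, so deterministic
pipeline stages are tested for exact equality and only the
parameter-recovery tests need sampling tolerances (binomial standard
errors at the generated depth).

Corpus generation draws experiments with a set library-strategy mix,
1–3 runs each, organism labels, quarterly dates and (optionally)
per-quarter throughput targets, and emits the run records, the
run→experiment mapping, metadata as TSV-equivalent objects and as
minimal SRA/BioSample XML, plus the tallied truth tables the summaries
must reproduce.

What the generator does **not** emulate: platform error profiles,
adapter contamination, quality–base-identity correlation, or reads
drawn from a genome. Passing tests therefore demonstrate metric and
pipeline correctness, not robustness to every artifact of real
instrument data.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
oracle-equivalence over a hundred randomized files of up to a few
hundred reads, parameter recovery at 10⁴ reads, duplication pools of
10³ reads, corpora of 10³–2·10³ experiments. The metrics are
count-based, so correctness at these sizes transfers directly; only
repository-wide descriptive statistics (which depend on the actual
archive contents, not on the method) require the full corpus and are
out of scope.

## RDF export

Each record becomes one subject with an `rdf:type` triple, a
`dcterms:identifier` triple and one numeric triple per metric (10 for an
experiment, 9 for a run), serialized as Turtle. The vocabulary is
deliberately provisional — a default base URI and field-named
predicates, overridable via `RdfMapping` — rather than an invented
"official" ontology. Export round trips losslessly for the flat metric
fields; per-position tables are not part of the RDF representation.

## Known limitations

* Capped-mode duplication depends on read order (inherent to
  first-N-keys tracking); all other metrics are order-invariant.
* Accuracy summaries parsed from binned FastQC reports are approximate
  relative to unbinned native computation (one table row per bin).
* The join trusts submitter metadata; inconsistent category spellings
  surface as separate categories.
* `read_metadata_tsv` expects the package's own column names; arbitrary
  archive dump formats need reshaping first.
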