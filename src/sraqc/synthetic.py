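"""Synthetic sequencing data with known ground truth.

Every other part of the package is testable against data generated here:
FASTQ files whose GC fraction, N rate, length mix, per-position quality
model and duplication structure are chosen up front, and whole corpora of
run records with category mixes, date ranges and throughput distributions
chosen up front.  Ground truth is always *tallied from the emitted reads
or records*, never taken from the generating parameters, so deterministic
pipelines can be checked for exact equality and sampled quantities only
need sampling tolerances.

Generation is deterministic for a given spec and seed.  Emitted quality
strings always use the Phred+33 encoding; :func:`reencode_phred64`
rewrites a file to the legacy +64 encoding for encoding-detection tests.

What this generator does not emulate: platform-specific error profiles,
adapter contamination, quality-by-base-identity correlations, or any
genome — reads are iid letters, not subsequences of a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fastq_io import QualityEncoding, ReadRecord, read_fastq, write_fastq
from .metadata import ExperimentMetadata
from .qc_metrics import DuplicationConfig, RunQuality, _dup_key

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_reads",
    "generate_fastq",
    "reencode_phred64",
    "CorpusFixture",
    "generate_corpus",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic FASTQ file.

    ``length`` is a fixed read length or a categorical distribution
    ``{length: probability}``.  Per-position quality is drawn as
    ``round(clamp(Normal(q_intercept + q_slope*i, q_sd), *q_clamp))`` with
    1-based position i.  When ``n_templates`` is set the file consists of
    ``n_templates`` distinct template sequences each emitted
    ``copies_per_template`` times (shuffled), overriding ``n_reads``.
    """

    n_reads: int = 1000
    length: int | dict = 100
    gc_prob: float = 0.5
    n_prob: float = 0.0
    q_intercept: float = 38.0
    q_slope: float = 0.0
    q_sd: float = 2.0
    q_clamp: tuple = (2, 40)
    n_templates: int | None = None
    copies_per_template: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gc_prob <= 1:
            raise ValueError("gc_prob must be in [0, 1]")
        if not 0 <= self.n_prob <= 1:
            raise ValueError("n_prob must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass
class GroundTruth:
    """Metrics tallied directly from the emitted reads."""

    total_reads: int = 0
    total_bases: int = 0
    pct_gc: float = 0.0
    mean_length: float = 0.0
    median_length: float = 0.0
    n_content_pct: float = 0.0
    duplicate_pct: float = 0.0
    mean_accuracy: float = 0.0


def _draw_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.length, dict):
        lengths = sorted(spec.length)
        probs = np.array([spec.length[k] for k in lengths], dtype=float)
        probs = probs / probs.sum()
        return int(rng.choice(lengths, p=probs))
    return int(spec.length)


def _draw_sequence(length: int, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    u = rng.random(length)
    pick = rng.random(length)
    bases = np.where(
        u < spec.n_prob,
        "N",
        np.where(
            rng.random(length) < spec.gc_prob,
            np.where(pick < 0.5, "G", "C"),
            np.where(pick < 0.5, "A", "T"),
        ),
    )
    return "".join(bases)


def _draw_qualities(length: int, spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    pos = np.arange(1, length + 1)
    raw = rng.normal(spec.q_intercept + spec.q_slope * pos, spec.q_sd)
    lo, hi = spec.q_clamp
    return [int(q) for q in np.rint(np.clip(raw, lo, hi)).astype(int)]


def generate_reads(spec: SyntheticSpec) -> list[ReadRecord]:
    """Materialize the synthetic reads of a spec (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    records: list[ReadRecord] = []
    if spec.n_templates is not None:
        templates = [
            _draw_sequence(_draw_length(spec, rng), spec, rng)
            for _ in range(spec.n_templates)
        ]
        order = np.repeat(np.arange(spec.n_templates), spec.copies_per_template)
        rng.shuffle(order)
        for i, t_idx in enumerate(order):
            seq = templates[t_idx]
            records.append(
                ReadRecord(f"read{i}", seq, _draw_qualities(len(seq), spec, rng))
            )
    else:
        for i in range(spec.n_reads):
            L = _draw_length(spec, rng)
            records.append(
                ReadRecord(f"read{i}", _draw_sequence(L, spec, rng), _draw_qualities(L, spec, rng))
            )
    return records


def _tally(records: Sequence[ReadRecord]) -> GroundTruth:
    """Direct, loop-based tally of the emitted reads."""
    truth = GroundTruth()
    if not records:
        return truth
    truth.total_reads = len(records)
    lengths = sorted(len(r) for r in records)
    truth.total_bases = sum(lengths)
    truth.mean_length = truth.total_bases / truth.total_reads
    truth.median_length = float(lengths[(len(lengths) + 1) // 2 - 1])
    gc = sum(r.sequence.count("G") + r.sequence.count("C") for r in records)
    acgt = sum(
        sum(r.sequence.count(b) for b in "ACGT") for r in records
    )
    truth.pct_gc = 100.0 * gc / acgt if acgt else 0.0

    max_len = lengths[-1]
    per_pos_pct = []
    mean_q = []
    for i in range(max_len):
        covering = [r for r in records if len(r) > i]
        per_pos_pct.append(
            100.0 * sum(r.sequence[i] == "N" for r in covering) / len(covering)
        )
        mean_q.append(sum(r.qualities[i] for r in covering) / len(covering))
    truth.n_content_pct = float(np.mean(per_pos_pct))
    truth.mean_accuracy = float(np.mean(mean_q))

    cfg = DuplicationConfig(mode="exact")
    keys = {_dup_key(r.sequence, cfg) for r in records}
    truth.duplicate_pct = 100.0 * (truth.total_reads - len(keys)) / truth.total_reads
    return truth


def generate_fastq(
    spec: SyntheticSpec, out: str | Path, compress: bool = False
) -> GroundTruth:
    """Write a synthetic FASTQ file and return the tallied ground truth."""
    records = generate_reads(spec)
    write_fastq(records, out, compress=compress)
    return _tally(records)


def reencode_phred64(src: str | Path, dst: str | Path) -> int:
    """Rewrite a Phred+33 FASTQ with the legacy +64 encoding."""
    return write_fastq(
        read_fastq(src, QualityEncoding(33)), dst, encoding=QualityEncoding(64)
    )


# ---------------------------------------------------------------------------
# corpus-level fixtures
# ---------------------------------------------------------------------------

_SOURCE_BY_STRATEGY = {
    "WGS": "GENOMIC",
    "WXS": "GENOMIC",
    "ChIP-Seq": "GENOMIC",
    "POOLCLONE": "GENOMIC",
    "RNA-Seq": "TRANSCRIPTOMIC",
    "AMPLICON": "METAGENOMIC",
}

_ORGANISMS = [
    (9606, "Homo sapiens"),
    (10090, "Mus musculus"),
    (410658, "soil metagenome"),
]


@dataclass
class CorpusFixture:
    """A generated corpus plus the summaries it must reproduce."""

    runs: list[RunQuality]
    mapping: dict[str, str]  # run_id -> experiment_id
    metadata: list[ExperimentMetadata]
    biosamples: pd.DataFrame
    experiment_xml: str
    biosample_xml: str
    truth_category_counts: dict[str, dict[str, int]]
    truth_throughput: list[float]  # per experiment, emitted order
    truth_quarter_means: dict[str, float] = field(default_factory=dict)


def _synthetic_run(
    run_id: str,
    reads: int,
    length: int,
    rng: np.random.Generator,
) -> RunQuality:
    """A plausible run record without materializing reads (corpus scale)."""
    acc = float(np.clip(rng.normal(34, 3), 15, 40))
    return RunQuality(
        run_id=run_id,
        total_reads=reads,
        total_bases=reads * length,
        pct_gc=float(np.clip(rng.normal(48, 6), 20, 80)),
        length_distribution={length: reads},
        mean_length=float(length),
        median_length=float(length),
        per_position_quality=[],
        mean_accuracy=acc,
        median_accuracy=acc + float(rng.normal(0, 0.5)),
        duplicate_pct=float(np.clip(rng.normal(15, 10), 0, 95)),
        per_position_n=[],
        n_content_pct=float(np.clip(rng.exponential(0.3), 0, 40)),
    )


def generate_corpus(
    n_experiments: int,
    category_mix: dict[str, float] | None = None,
    seed: int = 0,
    runs_per_experiment: tuple[int, int] = (1, 3),
    quarterly_throughput_means: Sequence[float] | None = None,
    start_year: int = 2010,
) -> CorpusFixture:
    """Generate run records, mapping and metadata with tallied truth tables.

    ``category_mix`` gives library-strategy probabilities (must sum to 1).
    If ``quarterly_throughput_means`` is given, experiments are assigned
    uniformly to that many consecutive quarters from ``start_year`` and
    run base totals are scaled so each quarter's expected experiment
    throughput matches the requested mean.
    """
    mix = category_mix or {"WGS": 0.4, "RNA-Seq": 0.3, "AMPLICON": 0.2, "WXS": 0.1}
    probs = np.array(list(mix.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("category mix probabilities must sum to 1")
    strategies = list(mix)
    rng = np.random.default_rng(seed)

    n_quarters = (
        len(quarterly_throughput_means) if quarterly_throughput_means else 8
    )
    quarter_starts = pd.period_range(
        start=f"{start_year}Q1", periods=n_quarters, freq="Q"
    )

    runs: list[RunQuality] = []
    mapping: dict[str, str] = {}
    metadata: list[ExperimentMetadata] = []
    bios_rows = []
    strat_counts: dict[str, int] = {}
    org_counts: dict[str, int] = {}
    throughputs: list[float] = []
    quarter_sums: dict[str, list[float]] = {}

    for e in range(n_experiments):
        exp_id = f"EXP{e:06d}"
        bios_id = f"SAMN{e:08d}"
        strategy = strategies[int(rng.choice(len(strategies), p=probs))]
        strat_counts[strategy] = strat_counts.get(strategy, 0) + 1
        tax_id, organism = _ORGANISMS[int(rng.integers(len(_ORGANISMS)))]
        org_counts[organism] = org_counts.get(organism, 0) + 1

        q_idx = int(rng.integers(n_quarters))
        quarter = quarter_starts[q_idx]
        day = int(rng.integers((quarter.end_time - quarter.start_time).days))
        date = (quarter.start_time + pd.Timedelta(days=day)).strftime("%Y-%m-%d")

        n_runs = int(rng.integers(runs_per_experiment[0], runs_per_experiment[1] + 1))
        if quarterly_throughput_means is not None:
            target = quarterly_throughput_means[q_idx]
            reads_scale = max(int(target / (100 * n_runs)), 1)
        else:
            reads_scale = max(int(rng.lognormal(10, 1.5) / n_runs), 1)
        exp_bases = 0
        for r in range(n_runs):
            run_id = f"RUN{e:06d}.{r}"
            rq = _synthetic_run(run_id, reads_scale, 100, rng)
            runs.append(rq)
            mapping[run_id] = exp_id
            exp_bases += rq.total_bases
        throughputs.append(float(exp_bases))
        qlabel = f"{quarter.year}-Q{quarter.quarter}"
        quarter_sums.setdefault(qlabel, []).append(float(exp_bases))

        metadata.append(
            ExperimentMetadata(
                experiment_id=exp_id,
                biosample_id=bios_id,
                library_strategy=strategy,
                library_source=_SOURCE_BY_STRATEGY.get(strategy, "GENOMIC"),
                instrument_model="Illumina HiSeq 2000",
                manufacturer="Illumina",
                taxonomy_id=tax_id,
                scientific_name=organism,
                date=date,
            )
        )
        bios_rows.append(
            {"biosample_id": bios_id, "taxonomy_id": tax_id, "scientific_name": organism}
        )

    biosamples = pd.DataFrame(
        bios_rows, columns=["biosample_id", "taxonomy_id", "scientific_name"]
    )
    return CorpusFixture(
        runs=runs,
        mapping=mapping,
        metadata=metadata,
        biosamples=biosamples,
        experiment_xml=_experiment_xml(metadata),
        biosample_xml=_biosample_xml(bios_rows),
        truth_category_counts={
            "library_strategy": strat_counts,
            "scientific_name": org_counts,
        },
        truth_throughput=throughputs,
        truth_quarter_means={
            q: float(np.mean(v)) for q, v in sorted(quarter_sums.items())
        },
    )


def _experiment_xml(metadata: Sequence[ExperimentMetadata]) -> str:
    parts = ["<EXPERIMENT_SET>"]
    for m in metadata:
        parts.append(f'  <EXPERIMENT accession="{m.experiment_id}" published="{m.date}">')
        parts.append("    <DESIGN>")
        parts.append(
            f'      <SAMPLE_DESCRIPTOR accession="{m.biosample_id}">'
            '<IDENTIFIERS><EXTERNAL_ID namespace="BioSample">'
            f"{m.biosample_id}</EXTERNAL_ID></IDENTIFIERS></SAMPLE_DESCRIPTOR>"
        )
        parts.append("      <LIBRARY_DESCRIPTOR>")
        parts.append(f"        <LIBRARY_STRATEGY>{m.library_strategy}</LIBRARY_STRATEGY>")
        parts.append(f"        <LIBRARY_SOURCE>{m.library_source}</LIBRARY_SOURCE>")
        parts.append("      </LIBRARY_DESCRIPTOR>")
        parts.append("    </DESIGN>")
        parts.append(
            "    <PLATFORM><ILLUMINA><INSTRUMENT_MODEL>"
            f"{m.instrument_model}</INSTRUMENT_MODEL></ILLUMINA></PLATFORM>"
        )
        parts.append("  </EXPERIMENT>")
    parts.append("</EXPERIMENT_SET>")
    return "\n".join(parts)


def _biosample_xml(rows: Sequence[dict]) -> str:
    parts = ["<BioSampleSet>"]
    for r in rows:
        parts.append(f'  <BioSample accession="{r["biosample_id"]}">')
        parts.append(
            f'    <Description><Organism taxonomy_id="{r["taxonomy_id"]}" '
            f'taxonomy_name="{r["scientific_name"]}"/></Description>'
        )
        parts.append("  </BioSample>")
    parts.append("</BioSampleSet>")
    return "\n".join(parts)
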