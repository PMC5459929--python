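"""Per-run sequencing quality metrics.

Computes, for one sequencing run (one FASTQ file or a paired-end file
pair), the quality values a repository needs to make runs comparable:

* total reads, total bases and %GC (basic statistics);
* mean and median read length from the length distribution;
* per-position Phred-score statistics and the run-level mean/median base
  call accuracy derived from them;
* per-position N content and the run-level N-content percentage;
* the duplicate-read percentage, either by exact tallying or with a
  bounded tracker plus occupancy correction (the strategy FastQC's
  Duplicate Sequences module uses, so values are comparable to FastQC's).

The same eight run-level values can alternatively be recovered from an
existing FastQC ``fastqc_data.txt`` report via :func:`parse_fastqc_data`.

Conventions (used consistently across the package): quantiles by lower
nearest rank; medians of even-sized samples take the lower central value;
run-level accuracy statistics are *unweighted* over positions — each
position of the per-position table counts once regardless of how many
reads cover it.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._stats import lower_median, quantile_from_counts
from .fastq_io import MAX_PHRED, QualityEncoding, ReadRecord, read_fastq

__all__ = [
    "RunQuality",
    "PositionQuality",
    "DuplicationConfig",
    "basic_stats",
    "length_stats",
    "per_base_quality",
    "per_base_n_content",
    "duplication_pct",
    "compute_run_quality",
    "merge_paired",
    "parse_fastqc_data",
    "write_fastqc_data",
]

#: The eight run-level metrics that aggregation and serialization operate on.
METRIC_FIELDS = (
    "total_reads",
    "total_bases",
    "pct_gc",
    "mean_length",
    "median_length",
    "duplicate_pct",
    "mean_accuracy",
    "median_accuracy",
    "n_content_pct",
)


@dataclass
class PositionQuality:
    """Phred-score summary for one read position (1-based)."""

    position: float
    mean: float
    median: float
    lower_quartile: float
    upper_quartile: float
    n: int


@dataclass
class DuplicationConfig:
    """Parameters of duplicate-percentage estimation.

    Reads longer than ``truncate_above`` bases contribute only their first
    ``truncate_to`` bases as the duplication key, and in ``capped`` mode
    only the first ``track_limit`` distinct keys are tracked, with an
    occupancy correction extrapolating to the untracked remainder.  The
    defaults (50/75/100000) reproduce FastQC v0.11 behaviour.
    """

    track_limit: int = 100_000
    truncate_above: int = 75
    truncate_to: int = 50
    mode: str = "capped"

    def __post_init__(self) -> None:
        if self.truncate_to > self.truncate_above:
            raise ValueError("truncate_to must be <= truncate_above")
        if self.track_limit < 1:
            raise ValueError("track_limit must be >= 1")
        if self.mode not in ("exact", "capped"):
            raise ValueError(f"mode must be 'exact' or 'capped', got {self.mode!r}")


@dataclass
class RunQuality:
    """The quality record of one sequencing run."""

    run_id: str
    total_reads: int
    total_bases: int
    pct_gc: float
    length_distribution: dict
    mean_length: float
    median_length: float
    per_position_quality: list[PositionQuality]
    mean_accuracy: float
    median_accuracy: float
    duplicate_pct: float
    per_position_n: list[tuple[float, float]]
    n_content_pct: float


# ---------------------------------------------------------------------------
# individual metric operations
# ---------------------------------------------------------------------------

def basic_stats(reads: Iterable[ReadRecord]) -> tuple[int, int, float]:
    """Total reads, total bases and %GC of a read stream.

    %GC is 100*(G+C)/(A+C+G+T): N and other IUPAC letters are excluded
    from both numerator and denominator.  An empty denominator yields 0.
    """
    total_reads = 0
    total_bases = 0
    gc = 0
    acgt = 0
    for rec in reads:
        total_reads += 1
        total_bases += len(rec.sequence)
        for base, cnt in _base_counts(rec.sequence).items():
            if base in "GC":
                gc += cnt
            if base in "ACGT":
                acgt += cnt
    pct_gc = 100.0 * gc / acgt if acgt else 0.0
    return total_reads, total_bases, pct_gc


def _base_counts(sequence: str) -> dict[str, int]:
    return {b: sequence.count(b) for b in set(sequence)}


_BIN_RE = re.compile(r"^(\d+)-(\d+)$")


def _entry_value(key) -> float:
    """Representative length of a distribution entry (bin -> midpoint)."""
    if isinstance(key, str):
        m = _BIN_RE.match(key)
        if m is None:
            try:
                return float(int(key))
            except ValueError:
                raise ValueError(f"malformed length entry {key!r}") from None
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ValueError(f"malformed length bin {key!r}")
        return (lo + hi) / 2
    return float(key)


def _entry_interval(key) -> tuple[int, int]:
    if isinstance(key, str):
        m = _BIN_RE.match(key)
        if m is not None:
            return int(m.group(1)), int(m.group(2))
        return int(key), int(key)
    return int(key), int(key)


def length_stats(length_distribution: dict) -> tuple[float, float]:
    """Mean and median read length from a length distribution.

    Entries are exact lengths or bins "lo-hi" contributing their midpoint.
    The median is the representative value of the entry containing the
    ceil(n/2)-th read in ascending length order (lower median).
    """
    if not length_distribution:
        raise ValueError("empty length distribution")
    entries = []
    for key, count in length_distribution.items():
        if count < 0:
            raise ValueError(f"negative count for length entry {key!r}")
        entries.append((_entry_interval(key), _entry_value(key), count))
    entries.sort(key=lambda e: e[0])
    for prev, cur in zip(entries, entries[1:]):
        if cur[0][0] <= prev[0][1]:
            raise ValueError("overlapping length bins")
    n = sum(c for _, _, c in entries)
    if n <= 0:
        raise ValueError("length distribution has no reads")
    mean = sum(v * c for _, v, c in entries) / n
    target = math.ceil(n / 2)
    cum = 0
    for _, value, count in entries:
        cum += count
        if cum >= target:
            return mean, value
    raise AssertionError("unreachable")


class _QualityTally:
    """Per-position histogram of Phred scores, grown as longer reads appear."""

    def __init__(self) -> None:
        self.counts = np.zeros((0, MAX_PHRED + 1), dtype=np.int64)

    def add(self, qualities: Sequence[int]) -> None:
        L = len(qualities)
        if L > self.counts.shape[0]:
            extra = np.zeros((L - self.counts.shape[0], MAX_PHRED + 1), np.int64)
            self.counts = np.vstack([self.counts, extra])
        self.counts[np.arange(L), qualities] += 1

    def summarize(self) -> list[PositionQuality]:
        rows = []
        scores = np.arange(MAX_PHRED + 1)
        for i in range(self.counts.shape[0]):
            c = self.counts[i]
            n = int(c.sum())
            if n == 0:
                continue
            rows.append(
                PositionQuality(
                    position=i + 1,
                    mean=float((c * scores).sum() / n),
                    median=float(quantile_from_counts(c, 0.5)),
                    lower_quartile=float(quantile_from_counts(c, 0.25)),
                    upper_quartile=float(quantile_from_counts(c, 0.75)),
                    n=n,
                )
            )
        return rows


def per_base_quality(
    reads: Iterable[ReadRecord],
) -> tuple[list[PositionQuality], float, float]:
    """Per-position Phred statistics plus run-level accuracy summaries.

    For each position the mean, lower-nearest-rank median and quartiles
    are taken over all reads covering it.  The run-level mean accuracy is
    the unweighted mean of the per-position means; the median accuracy is
    the lower median of the per-position medians.
    """
    tally = _QualityTally()
    for rec in reads:
        tally.add(rec.qualities)
    rows = tally.summarize()
    if not rows:
        raise ValueError("no reads")
    mean_acc, median_acc = _accuracy_from_rows(rows)
    return rows, mean_acc, median_acc


def _accuracy_from_rows(rows: Sequence[PositionQuality]) -> tuple[float, float]:
    means = [r.mean for r in rows]
    medians = [r.median for r in rows]
    return float(np.mean(means)), float(lower_median(medians))


def per_base_n_content(
    reads: Iterable[ReadRecord],
) -> tuple[list[tuple[float, float]], float]:
    """Percent of N calls per position, and their unweighted mean."""
    n_counts: list[int] = []
    cover: list[int] = []
    got_any = False
    for rec in reads:
        got_any = True
        L = len(rec.sequence)
        while len(cover) < L:
            cover.append(0)
            n_counts.append(0)
        for i in range(L):
            cover[i] += 1
            if rec.sequence[i] == "N":
                n_counts[i] += 1
    if not got_any:
        raise ValueError("no reads")
    table = [
        (float(i + 1), 100.0 * n_counts[i] / cover[i])
        for i in range(len(cover))
        if cover[i] > 0
    ]
    pct = float(np.mean([p for _, p in table])) if table else 0.0
    return table, pct


# ---------------------------------------------------------------------------
# duplication
# ---------------------------------------------------------------------------

def _dup_key(sequence: str, config: DuplicationConfig) -> str:
    if len(sequence) > config.truncate_above:
        return sequence[: config.truncate_to]
    return sequence


def _p_seen(count: int, total: int, count_at_limit: int) -> float:
    """Probability that a key occurring `count` times among `total` reads
    appears at least once in the first `count_at_limit` observations.

    The complement is a hypergeometric no-draw probability
    prod_{i<count_at_limit} (total-count-i)/(total-i), evaluated in
    log-gamma space.  It is zero (p=1) when the key cannot be missed.
    """
    if count_at_limit >= total:
        return 1.0
    if total - count - count_at_limit < 0:
        return 1.0
    log_not = (
        math.lgamma(total - count + 1)
        - math.lgamma(total - count - count_at_limit + 1)
        - math.lgamma(total + 1)
        + math.lgamma(total - count_at_limit + 1)
    )
    p = 1.0 - math.exp(log_not)
    return min(max(p, 1e-300), 1.0)


def duplication_pct(
    reads: Iterable[ReadRecord], config: DuplicationConfig | None = None
) -> float:
    """Percentage of reads that duplicate an already-seen sequence key.

    ``exact`` mode tallies every distinct key: 100*(T-U)/T.  ``capped``
    mode tracks only the first ``track_limit`` distinct keys and corrects
    each tracked count for the chance that a key of that abundance was
    seen before the tracker filled, which makes the estimate robust at
    repository scale while keeping memory bounded.  With fewer distinct
    keys than the limit the two modes coincide.
    """
    config = config or DuplicationConfig()
    counts: dict[str, int] = {}
    total = 0
    count_at_limit: int | None = None
    capped = config.mode == "capped"
    for rec in reads:
        total += 1
        key = _dup_key(rec.sequence, config)
        if key in counts:
            counts[key] += 1
        elif not capped or len(counts) < config.track_limit:
            counts[key] = 1
            if capped and len(counts) == config.track_limit:
                count_at_limit = total
    if total == 0:
        return 0.0
    if not capped or count_at_limit is None:
        distinct = len(counts)
        return 100.0 * (total - distinct) / total
    # occupancy-corrected estimate; p depends on the count only, so cache
    p_cache: dict[int, float] = {}
    u_star = 0.0
    t_star = 0.0
    for c in counts.values():
        p = p_cache.get(c)
        if p is None:
            p = p_cache[c] = _p_seen(c, total, count_at_limit)
        u_star += 1.0 / p
        t_star += c / p
    return 100.0 * (1.0 - u_star / t_star)


# ---------------------------------------------------------------------------
# whole-run computation
# ---------------------------------------------------------------------------

def _single_run_quality(
    run_id: str,
    path: str | Path,
    duplication: DuplicationConfig,
    encoding: QualityEncoding | None,
) -> RunQuality:
    """One streaming pass computing every metric of one FASTQ file."""
    total_reads = 0
    total_bases = 0
    gc = 0
    acgt = 0
    lengths: dict[int, int] = {}
    qual_tally = _QualityTally()
    n_counts: list[int] = []
    cover: list[int] = []
    dup_counts: dict[str, int] = {}
    count_at_limit: int | None = None
    capped = duplication.mode == "capped"

    for rec in read_fastq(path, encoding):
        total_reads += 1
        L = len(rec.sequence)
        total_bases += L
        lengths[L] = lengths.get(L, 0) + 1
        for base, cnt in _base_counts(rec.sequence).items():
            if base in "GC":
                gc += cnt
            if base in "ACGT":
                acgt += cnt
        qual_tally.add(rec.qualities)
        while len(cover) < L:
            cover.append(0)
            n_counts.append(0)
        for i in range(L):
            cover[i] += 1
            if rec.sequence[i] == "N":
                n_counts[i] += 1
        key = _dup_key(rec.sequence, duplication)
        if key in dup_counts:
            dup_counts[key] += 1
        elif not capped or len(dup_counts) < duplication.track_limit:
            dup_counts[key] = 1
            if capped and len(dup_counts) == duplication.track_limit:
                count_at_limit = total_reads

    if total_reads == 0:
        raise ValueError(f"run {run_id!r}: no reads")

    pct_gc = 100.0 * gc / acgt if acgt else 0.0
    mean_len, median_len = length_stats(lengths)
    qrows = qual_tally.summarize()
    mean_acc, median_acc = _accuracy_from_rows(qrows)
    n_table = [
        (float(i + 1), 100.0 * n_counts[i] / cover[i]) for i in range(len(cover))
    ]
    n_pct = float(np.mean([p for _, p in n_table]))

    if not capped or count_at_limit is None:
        dup_pct = 100.0 * (total_reads - len(dup_counts)) / total_reads
    else:
        p_cache: dict[int, float] = {}
        u_star = t_star = 0.0
        for c in dup_counts.values():
            p = p_cache.get(c)
            if p is None:
                p = p_cache[c] = _p_seen(c, total_reads, count_at_limit)
            u_star += 1.0 / p
            t_star += c / p
        dup_pct = 100.0 * (1.0 - u_star / t_star)

    return RunQuality(
        run_id=run_id,
        total_reads=total_reads,
        total_bases=total_bases,
        pct_gc=pct_gc,
        length_distribution=lengths,
        mean_length=mean_len,
        median_length=median_len,
        per_position_quality=qrows,
        mean_accuracy=mean_acc,
        median_accuracy=median_acc,
        duplicate_pct=dup_pct,
        per_position_n=n_table,
        n_content_pct=n_pct,
    )


def merge_paired(run_id: str, mate1: RunQuality, mate2: RunQuality) -> RunQuality:
    """Combine the two mates of a paired-end run into one record.

    Read and base totals are summed; every other run-level value is the
    plain average of the two mates.  Per-position tables are averaged
    positionwise over the mates covering each position, and the length
    distributions are pooled.
    """
    lengths: dict = dict(mate1.length_distribution)
    for k, v in mate2.length_distribution.items():
        lengths[k] = lengths.get(k, 0) + v

    by_pos: dict[float, list[PositionQuality]] = {}
    for row in list(mate1.per_position_quality) + list(mate2.per_position_quality):
        by_pos.setdefault(row.position, []).append(row)
    qrows = [
        PositionQuality(
            position=pos,
            mean=float(np.mean([r.mean for r in rows])),
            median=float(np.mean([r.median for r in rows])),
            lower_quartile=float(np.mean([r.lower_quartile for r in rows])),
            upper_quartile=float(np.mean([r.upper_quartile for r in rows])),
            n=sum(r.n for r in rows),
        )
        for pos, rows in sorted(by_pos.items())
    ]
    n_by_pos: dict[float, list[float]] = {}
    for pos, pct in list(mate1.per_position_n) + list(mate2.per_position_n):
        n_by_pos.setdefault(pos, []).append(pct)
    n_table = [(pos, float(np.mean(v))) for pos, v in sorted(n_by_pos.items())]

    def avg(attr: str) -> float:
        return (getattr(mate1, attr) + getattr(mate2, attr)) / 2

    return RunQuality(
        run_id=run_id,
        total_reads=mate1.total_reads + mate2.total_reads,
        total_bases=mate1.total_bases + mate2.total_bases,
        pct_gc=avg("pct_gc"),
        length_distribution=lengths,
        mean_length=avg("mean_length"),
        median_length=avg("median_length"),
        per_position_quality=qrows,
        mean_accuracy=avg("mean_accuracy"),
        median_accuracy=avg("median_accuracy"),
        duplicate_pct=avg("duplicate_pct"),
        per_position_n=n_table,
        n_content_pct=avg("n_content_pct"),
    )


def compute_run_quality(
    run_id: str,
    fastq_paths: str | Path | Sequence[str | Path],
    duplication: DuplicationConfig | None = None,
    encoding: QualityEncoding | None = None,
) -> RunQuality:
    """Quality record of one run from its FASTQ file(s).

    One path computes that file's metrics directly.  Two paths are treated
    as a ``_1``/``_2`` paired-end pair: each mate is measured independently
    and the records merged with read/base totals summed and all other
    values averaged.
    """
    duplication = duplication or DuplicationConfig()
    if isinstance(fastq_paths, (str, Path)):
        paths = [fastq_paths]
    else:
        paths = list(fastq_paths)
    if len(paths) not in (1, 2):
        raise ValueError(f"run {run_id!r}: expected 1 or 2 FASTQ paths, got {len(paths)}")
    try:
        if len(paths) == 1:
            return _single_run_quality(run_id, paths[0], duplication, encoding)
        m1 = _single_run_quality(f"{run_id}/1", paths[0], duplication, encoding)
        m2 = _single_run_quality(f"{run_id}/2", paths[1], duplication, encoding)
    except (OSError, ValueError) as exc:
        raise type(exc)(f"run {run_id!r}: {exc}") from exc
    return merge_paired(run_id, m1, m2)


# ---------------------------------------------------------------------------
# fastqc_data.txt interchange
# ---------------------------------------------------------------------------

_REQUIRED_BLOCKS = (
    "Basic Statistics",
    "Per base sequence quality",
    "Sequence Length Distribution",
    "Per base N content",
)


def _split_blocks(text: str) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        if line.startswith(">>END_MODULE"):
            current = None
        elif line.startswith(">>"):
            current = line[2:].split("\t")[0].strip()
            blocks[current] = []
        elif current is not None:
            blocks[current].append(line)
    return blocks


def _position_value(token: str) -> float:
    m = _BIN_RE.match(token)
    if m:
        return (int(m.group(1)) + int(m.group(2))) / 2
    return float(token)


def parse_fastqc_data(text: str, run_id: str) -> RunQuality:
    """Reconstruct a :class:`RunQuality` from FastQC's ``fastqc_data.txt``.

    Position fields written as bins ("10-14") are kept as single entries at
    their midpoint position; run-level accuracy values are re-derived from
    the per-base table with the same unweighted rules used for native
    computation, so FastQC-parsed and natively computed records are
    directly comparable.  Both the "Total Duplicate Percentage" and the
    "Total Deduplicated Percentage" spellings of the duplication total are
    accepted (the latter as its complement).
    """
    if not text.lstrip().startswith("##FastQC"):
        warnings.warn("fastqc_data.txt version banner missing", stacklevel=2)
    blocks = _split_blocks(text)
    for name in _REQUIRED_BLOCKS:
        if name not in blocks:
            raise ValueError(f"missing module: {name}")

    basic: dict[str, str] = {}
    for line in blocks["Basic Statistics"]:
        if line.startswith("#") or "\t" not in line:
            continue
        key, _, value = line.partition("\t")
        basic[key.strip()] = value.strip()
    if "Total Sequences" not in basic:
        raise ValueError("missing field: Total Sequences")
    total_reads = int(float(basic["Total Sequences"]))
    pct_gc = float(basic.get("%GC", "0"))

    lengths: dict = {}
    for line in blocks["Sequence Length Distribution"]:
        if line.startswith("#") or not line.strip():
            continue
        key, _, count = line.partition("\t")
        key = key.strip()
        entry = key if _BIN_RE.match(key) else int(key)
        lengths[entry] = lengths.get(entry, 0) + float(count)
    mean_len, median_len = length_stats(lengths)
    total_bases = int(round(sum(_entry_value(k) * c for k, c in lengths.items())))

    header, rows = _parse_table(blocks["Per base sequence quality"])
    idx = {name.lower(): i for i, name in enumerate(header)}
    qrows = [
        PositionQuality(
            position=_position_value(r[0]),
            mean=float(r[idx["mean"]]),
            median=float(r[idx["median"]]),
            lower_quartile=float(r[idx.get("lower quartile", idx["mean"])]),
            upper_quartile=float(r[idx.get("upper quartile", idx["mean"])]),
            n=0,
        )
        for r in rows
    ]
    if not qrows:
        raise ValueError("empty module: Per base sequence quality")
    mean_acc, median_acc = _accuracy_from_rows(qrows)

    _, nrows = _parse_table(blocks["Per base N content"])
    n_table = [(_position_value(r[0]), float(r[1])) for r in nrows]
    if not n_table:
        raise ValueError("empty module: Per base N content")
    n_pct = float(np.mean([p for _, p in n_table]))

    dup_pct = _find_duplicate_total(text)
    if dup_pct is None:
        raise ValueError("missing module: Sequence Duplication Levels")

    return RunQuality(
        run_id=run_id,
        total_reads=total_reads,
        total_bases=total_bases,
        pct_gc=pct_gc,
        length_distribution=lengths,
        mean_length=mean_len,
        median_length=median_len,
        per_position_quality=qrows,
        mean_accuracy=mean_acc,
        median_accuracy=median_acc,
        duplicate_pct=dup_pct,
        per_position_n=n_table,
        n_content_pct=n_pct,
    )


def _parse_table(lines: list[str]) -> tuple[list[str], list[list[str]]]:
    header: list[str] = []
    rows: list[list[str]] = []
    for line in lines:
        if not line.strip():
            continue
        if line.startswith("#"):
            header = line[1:].split("\t")
        else:
            rows.append(line.split("\t"))
    return header, rows


def _find_duplicate_total(text: str) -> float | None:
    for line in text.splitlines():
        if line.startswith("#Total Duplicate Percentage"):
            return float(line.split("\t")[1])
        if line.startswith("#Total Deduplicated Percentage"):
            return 100.0 - float(line.split("\t")[1])
    return None


def write_fastqc_data(rq: RunQuality) -> str:
    """Serialize a RunQuality in the fastqc_data.txt module-block format."""
    out = ["##FastQC\t0.11 (sraqc)"]
    out += [
        ">>Basic Statistics\tpass",
        "#Measure\tValue",
        f"Filename\t{rq.run_id}",
        f"Total Sequences\t{rq.total_reads}",
        f"%GC\t{rq.pct_gc!r}",
        ">>END_MODULE",
        ">>Per base sequence quality\tpass",
        "#Base\tMean\tMedian\tLower Quartile\tUpper Quartile",
    ]
    for r in rq.per_position_quality:
        pos = int(r.position) if float(r.position).is_integer() else r.position
        out.append(
            f"{pos}\t{r.mean!r}\t{r.median!r}\t{r.lower_quartile!r}\t{r.upper_quartile!r}"
        )
    out.append(">>END_MODULE")
    out.append(">>Sequence Length Distribution\tpass")
    out.append("#Length\tCount")
    for key in sorted(rq.length_distribution, key=_entry_value):
        out.append(f"{key}\t{rq.length_distribution[key]}")
    out.append(">>END_MODULE")
    out.append(">>Sequence Duplication Levels\tpass")
    out.append(f"#Total Duplicate Percentage\t{rq.duplicate_pct!r}")
    out.append(">>END_MODULE")
    out.append(">>Per base N content\tpass")
    out.append("#Base\tN-Count")
    for pos, pct in rq.per_position_n:
        p = int(pos) if float(pos).is_integer() else pos
        out.append(f"{p}\t{pct!r}")
    out.append(">>END_MODULE")
    return "\n".join(out) + "\n"
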