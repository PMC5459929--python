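from __future__ import annotations

import pytest

from sraqc import ReadRecord, SyntheticSpec, generate_reads


@pytest.fixture
def write_fastq_text(tmp_path):
    """Write literal FASTQ text to a temp file and return its path."""

    def _write(text: str, name: str = "reads.fastq"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def simple_reads() -> list[ReadRecord]:
    return [
        ReadRecord("r1", "ACGT", [10, 20, 30, 40]),
        ReadRecord("r2", "GGCC", [40, 30, 20, 10]),
    ]


def random_read_set(seed: int, max_reads: int = 300) -> list[ReadRecord]:
    """A randomized small read set exercising mixed lengths, N's and dups."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, max_reads))
    spec = SyntheticSpec(
        n_reads=n,
        length={int(L): 1.0 for L in rng.integers(20, 120, size=3)},
        gc_prob=float(rng.uniform(0.2, 0.8)),
        n_prob=float(rng.uniform(0, 0.05)),
        q_intercept=float(rng.uniform(20, 39)),
        q_slope=float(rng.uniform(-0.2, 0.05)),
        q_sd=float(rng.uniform(0.5, 4)),
        seed=seed,
    )
    reads = generate_reads(spec)
    # salt in duplicates so the duplication path is exercised
    if n >= 10:
        reads[1] = ReadRecord("dup1", reads[0].sequence, list(reads[0].qualities))
        reads[3] = ReadRecord("dup2", reads[0].sequence, list(reads[0].qualities))
    return reads
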