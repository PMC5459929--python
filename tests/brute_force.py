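"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written the slow, obvious way — in-memory
lists, explicit sorts, no sharing with the streaming implementations — so
a disagreement points at the package, not at the oracle.
"""

from __future__ import annotations

import math


def nr(sorted_vals, p):
    """Lower-nearest-rank quantile of an ascending list."""
    return sorted_vals[math.ceil(p * len(sorted_vals)) - 1]


def gc_percent(sequences):
    gc = sum(s.count("G") + s.count("C") for s in sequences)
    acgt = sum(sum(s.count(b) for b in "ACGT") for s in sequences)
    return 100.0 * gc / acgt if acgt else 0.0


def length_mean_median(sequences):
    lengths = sorted(len(s) for s in sequences)
    return sum(lengths) / len(lengths), float(nr(lengths, 0.5))


def per_position_quality(quality_lists):
    """List of (mean, median, q1, q3, n) per position, then the run-level
    unweighted mean-of-means and lower-median-of-medians."""
    max_len = max(len(q) for q in quality_lists)
    rows = []
    for i in range(max_len):
        col = sorted(q[i] for q in quality_lists if len(q) > i)
        rows.append(
            (
                sum(col) / len(col),
                float(nr(col, 0.5)),
                float(nr(col, 0.25)),
                float(nr(col, 0.75)),
                len(col),
            )
        )
    means = [r[0] for r in rows]
    medians = sorted(r[1] for r in rows)
    return rows, sum(means) / len(means), float(nr(medians, 0.5))


def n_content(sequences):
    max_len = max(len(s) for s in sequences)
    pcts = []
    for i in range(max_len):
        col = [s[i] for s in sequences if len(s) > i]
        pcts.append(100.0 * sum(c == "N" for c in col) / len(col))
    return pcts, sum(pcts) / len(pcts)


def duplicate_percent_exact(sequences, truncate_above=75, truncate_to=50):
    keys = {
        s[:truncate_to] if len(s) > truncate_above else s for s in sequences
    }
    t = len(sequences)
    return 100.0 * (t - len(keys)) / t if t else 0.0
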