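"""Shared order-statistic helpers.

One quantile convention is used across the whole package: *lower nearest
rank*.  For a sorted sample of size n, the p-quantile is the element at
rank ceil(p*n) (1-based).  The median of an even-sized sample is therefore
the lower of the two central values.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


def nearest_rank(sorted_values: Sequence[float], p: float) -> float:
    """p-quantile of an ascending-sorted sample by lower nearest rank."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty sample")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    k = math.ceil(p * n)
    return sorted_values[k - 1]


def lower_median(values: Sequence[float]) -> float:
    """Lower median: the ceil(n/2)-th smallest value."""
    return nearest_rank(sorted(values), 0.5)


def quantile_from_counts(counts: np.ndarray, p: float) -> int:
    """p-quantile over integer values 0..len(counts)-1 held as a histogram."""
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty sample")
    k = math.ceil(p * n)
    cum = np.cumsum(counts)
    return int(np.searchsorted(cum, k))
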