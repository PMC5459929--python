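"""Repository-scale summaries of joined quality + metadata tables.

These are the tabular equivalents of the overview figures a repository
publishes about itself: top-N category counts with percentages, histograms
of throughput / accuracy / N content (optionally faceted by a metadata
category), threshold fractions ("how much of the archive has N below
1%?"), distribution moments, and quarterly box-plot tables showing how
quality changed over the repository's history.

All summaries are pure functions of the input table; re-running them on
the same data yields identical output.  Percentages are rounded half away
from zero to one decimal, the convention that reproduces published
repository percentages from their underlying counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from ._stats import nearest_rank

__all__ = [
    "category_counts",
    "percentage",
    "round_half_away",
    "histogram",
    "threshold_fraction",
    "distribution_moments",
    "quarterly_boxplots",
    "HistogramResult",
]

MISSING_LABEL = "(missing)"
OTHER_LABEL = "other"


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (not banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float:
    """100*numerator/denominator, half-away-from-zero to 1 decimal."""
    if denominator <= 0:
        raise ValueError("zero denominator")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    exact = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def category_counts(
    joined: pd.DataFrame, column: str, top_n: int = 20
) -> pd.DataFrame:
    """Top-N category count table with percentages of the corpus total.

    Unset values are grouped under "(missing)"; categories beyond the top
    N are pooled into an "other" remainder row.  Ordering is by count
    descending, ties broken lexically.  Columns: category, count, percent.
    """
    if column not in joined.columns:
        raise KeyError(f"unknown field: {column}")
    values = joined[column].fillna(MISSING_LABEL).astype(str)
    values = values.replace("None", MISSING_LABEL)
    counts = values.value_counts()
    total = int(counts.sum())
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    head = items[:top_n]
    rest = sum(c for _, c in items[top_n:])
    rows = [
        {"category": cat, "count": int(c), "percent": percentage(int(c), total)}
        for cat, c in head
    ]
    if rest:
        rows.append(
            {"category": OTHER_LABEL, "count": int(rest), "percent": percentage(int(rest), total)}
        )
    df = pd.DataFrame(rows, columns=["category", "count", "percent"])
    df.attrs["corpus_total"] = total
    return df


@dataclass
class HistogramResult:
    """Binned counts plus the bookkeeping of what could not be binned."""

    table: pd.DataFrame  # columns: bin_lo, bin_hi, [facet], count
    edges: np.ndarray  # on the binning scale (exponents for log10)
    scale: str
    n_binned: int
    n_excluded: int  # non-finite, or non-positive under log10


def _bin_edges(values: np.ndarray, bins) -> np.ndarray:
    if np.ndim(bins) > 0:
        edges = np.asarray(bins, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be increasing with >= 2 entries")
        return edges
    if int(bins) < 1:
        raise ValueError("bins must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        # degenerate range: one unit-wide bin holds everything
        return np.array([lo, lo + 1.0]) if int(bins) == 1 else np.linspace(
            lo, lo + 1.0, int(bins) + 1
        )
    return np.linspace(lo, hi, int(bins) + 1)


def _bin_index(vals: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # half-open [lo, hi); the final bin also takes its upper edge so the
    # maximum value is counted
    idx = np.searchsorted(edges, vals, side="right") - 1
    idx[vals == edges[-1]] = len(edges) - 2
    return idx


def histogram(
    values,
    scale: str = "linear",
    bins=10,
    facet=None,
) -> HistogramResult:
    """Equal-width histogram on a linear or log10 scale.

    Non-finite values (and non-positive values under log10) are excluded
    and counted, never silently dropped.  With ``facet`` (a sequence of
    category labels aligned with ``values``) the table carries one count
    row per (bin, facet) pair.
    """
    if scale not in ("linear", "log10"):
        raise ValueError(f"scale must be 'linear' or 'log10', got {scale!r}")
    vals = np.asarray(values, dtype=float)
    facets = None if facet is None else np.asarray(facet, dtype=object)
    if facets is not None and len(facets) != len(vals):
        raise ValueError("facet length must match values length")

    ok = np.isfinite(vals)
    if scale == "log10":
        ok &= vals > 0
    n_excluded = int((~ok).sum())
    vals = vals[ok]
    if facets is not None:
        facets = facets[ok]
    if len(vals) == 0:
        raise ValueError("no finite values to bin")
    tvals = np.log10(vals) if scale == "log10" else vals

    edges = _bin_edges(tvals, bins)
    inside = (tvals >= edges[0]) & (tvals <= edges[-1])
    n_excluded += int((~inside).sum())
    tvals = tvals[inside]
    if facets is not None:
        facets = facets[inside]
    idx = _bin_index(tvals, edges)

    rows = []
    if facets is None:
        counts = np.bincount(idx, minlength=len(edges) - 1)
        for b in range(len(edges) - 1):
            rows.append(
                {"bin_lo": edges[b], "bin_hi": edges[b + 1], "count": int(counts[b])}
            )
        cols = ["bin_lo", "bin_hi", "count"]
    else:
        df = pd.DataFrame({"bin": idx, "facet": facets})
        grouped = df.groupby(["bin", "facet"], sort=True).size()
        for (b, f), c in grouped.items():
            rows.append(
                {
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "facet": f,
                    "count": int(c),
                }
            )
        cols = ["bin_lo", "bin_hi", "facet", "count"]
    table = pd.DataFrame(rows, columns=cols)
    return HistogramResult(
        table=table,
        edges=edges,
        scale=scale,
        n_binned=int(len(tvals)),
        n_excluded=n_excluded,
    )


def threshold_fraction(values, threshold: float) -> tuple[int, float]:
    """Count and rounded percentage of values strictly below a threshold."""
    vals = np.asarray(values, dtype=float)
    if len(vals) == 0:
        raise ValueError("empty values")
    below = int((vals < threshold).sum())
    return below, percentage(below, len(vals))


def distribution_moments(values) -> tuple[float, float]:
    """Arithmetic mean and lower median."""
    vals = np.asarray(values, dtype=float)
    if len(vals) == 0:
        raise ValueError("empty values")
    srt = np.sort(vals)
    return float(vals.mean()), float(nearest_rank(srt, 0.5))


def quarterly_boxplots(
    joined: pd.DataFrame, value_field: str, date_field: str
) -> pd.DataFrame:
    """Quarterly five-number summaries of one quality value over time.

    Rows with an unset or unparseable date are excluded (their count is in
    the table's ``n_excluded`` attr); quarters without data are omitted.
    Quartiles use lower nearest rank.  Columns: quarter, n, min, q1,
    median, q3, max, mean.
    """
    if value_field not in joined.columns:
        raise KeyError(f"unknown field: {value_field}")
    if date_field not in joined.columns:
        raise KeyError(f"unknown field: {date_field}")
    dates = pd.to_datetime(joined[date_field], errors="coerce", format="mixed")
    vals = pd.to_numeric(joined[value_field], errors="coerce")
    ok = dates.notna() & vals.notna()
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("no dated rows")
    dates, vals = dates[ok], vals[ok]
    quarters = dates.dt.year.astype(str) + "-Q" + dates.dt.quarter.astype(str)

    rows = []
    for quarter, group in vals.groupby(quarters.values):
        srt = np.sort(group.to_numpy())
        rows.append(
            {
                "quarter": quarter,
                "n": len(srt),
                "min": float(srt[0]),
                "q1": float(nearest_rank(srt, 0.25)),
                "median": float(nearest_rank(srt, 0.5)),
                "q3": float(nearest_rank(srt, 0.75)),
                "max": float(srt[-1]),
                "mean": float(srt.mean()),
            }
        )
    rows.sort(key=lambda r: r["quarter"])
    out = pd.DataFrame(
        rows, columns=["quarter", "n", "min", "q1", "median", "q3", "max", "mean"]
    )
    out.attrs["n_excluded"] = n_excluded
    return out
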