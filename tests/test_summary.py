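import numpy as np
import pandas as pd
import pytest

import brute_force as bf
from sraqc import (
    category_counts,
    distribution_moments,
    histogram,
    percentage,
    quarterly_boxplots,
    threshold_fraction,
)
from sraqc.summary import round_half_away


class TestPercentage:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (542332, 1171313, 46.3),
            (426841, 1171313, 36.4),
            (216896, 1171313, 18.5),
            (244457, 1171313, 20.9),
            (1103515, 1171313, 94.2),
            (0, 5, 0.0),
            (5, 5, 100.0),
        ],
    )
    def test_rounded_percentages(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_half_rounds_away_from_zero(self):
        assert percentage(1, 8) == 12.5
        assert percentage(25, 200) == 12.5
        assert round_half_away(0.25, 1) == 0.3  # not banker's 0.2

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            percentage(1, 0)
        with pytest.raises(ValueError):
            percentage(6, 5)


class TestCategoryCounts:
    def _table(self):
        rows = (
            [{"library_strategy": "WGS"}] * 5
            + [{"library_strategy": "RNA-Seq"}] * 3
            + [{"library_strategy": "WXS"}] * 3
            + [{"library_strategy": None}] * 2
            + [{"library_strategy": "AMPLICON"}]
        )
        return pd.DataFrame(rows)

    def test_counts_percents_and_missing(self):
        out = category_counts(self._table(), "library_strategy", top_n=10)
        assert out.attrs["corpus_total"] == 14
        assert list(out["category"])[:2] == ["WGS", "RNA-Seq"]  # tie broken lexically
        assert out.loc[out.category == "(missing)", "count"].item() == 2
        assert out.loc[out.category == "WGS", "percent"].item() == percentage(5, 14)

    def test_other_remainder_row(self):
        out = category_counts(self._table(), "library_strategy", top_n=2)
        assert list(out["category"]) == ["WGS", "RNA-Seq", "other"]
        assert out["count"].sum() == 14  # remainder keeps the total closed

    def test_single_category_is_100_percent(self):
        df = pd.DataFrame([{"x": "only"}] * 7)
        out = category_counts(df, "x")
        assert out["percent"].tolist() == [100.0]

    def test_percent_sum_within_rounding_slack(self):
        out = category_counts(self._table(), "library_strategy", top_n=10)
        assert abs(out["percent"].sum() - 100.0) <= 0.1 * len(out)

    def test_unknown_field_rejected(self):
        with pytest.raises(KeyError):
            category_counts(self._table(), "nope")


class TestHistogram:
    def test_log10_with_explicit_exponent_edges(self):
        h = histogram([1, 10, 100, 1000], scale="log10", bins=[0, 1, 2, 3, 4])
        assert h.table["count"].tolist() == [1, 1, 1, 1]

    def test_degenerate_single_value(self):
        h = histogram([5], scale="linear", bins=1)
        assert h.table["count"].tolist() == [1]
        assert h.table["bin_lo"].iloc[0] == 5.0

    def test_counts_plus_excluded_equals_input_length(self):
        values = [1.0, -2.0, np.nan, 10.0, 100.0]
        h = histogram(values, scale="log10", bins=2)
        assert h.n_binned + h.n_excluded == len(values)
        assert h.table["count"].sum() == h.n_binned

    def test_faceted_counts(self):
        h = histogram(
            [1, 2, 3, 4],
            scale="linear",
            bins=[0, 2.5, 5],
            facet=["a", "b", "a", "b"],
        )
        got = {
            (row.bin_lo, row.facet): row.count
            for row in h.table.itertuples(index=False)
        }
        assert got == {(0.0, "a"): 1, (0.0, "b"): 1, (2.5, "a"): 1, (2.5, "b"): 1}

    def test_loguniform_draws_spread_evenly(self):
        rng = np.random.default_rng(77)
        values = 10 ** rng.uniform(6, 10, size=1000)
        h = histogram(values, scale="log10", bins=[6, 7, 8, 9, 10])
        counts = h.table["count"].to_numpy()
        assert counts.sum() == 1000
        sigma = np.sqrt(1000 * 0.25 * 0.75)
        assert np.all(np.abs(counts - 250) < 3 * sigma)

    def test_no_finite_values_is_an_error(self):
        with pytest.raises(ValueError, match="no finite values"):
            histogram([np.nan, -1], scale="log10", bins=3)


class TestThresholdAndMoments:
    def test_strict_threshold(self):
        assert threshold_fraction([0.5, 2.0, 0.0], 1) == (2, 66.7)
        assert threshold_fraction([1.0, 2.0], 1) == (0, 0.0)  # boundary not below

    def test_moments_examples(self):
        assert distribution_moments([1, 2, 3]) == (2.0, 2.0)
        mean, median = distribution_moments([1, 10**9])
        assert mean == 5.000000005e8
        assert median == 1.0

    def test_moments_match_sort_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(8, 2, size=10_001)
        mean, median = distribution_moments(values)
        assert mean == pytest.approx(values.sum() / len(values))
        assert median == bf.nr(sorted(values), 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            threshold_fraction([], 1)
        with pytest.raises(ValueError):
            distribution_moments([])


class TestQuarterlyBoxplots:
    def test_single_quarter(self):
        df = pd.DataFrame(
            {"date": ["2010-01-15", "2010-02-20"], "value": [5.0, 7.0]}
        )
        out = quarterly_boxplots(df, "value", "date")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["quarter"] == "2010-Q1"
        assert row["n"] == 2
        assert row["median"] == 5.0  # lower median
        assert row["mean"] == 6.0

    def test_quarters_sorted_across_year_boundary(self):
        df = pd.DataFrame(
            {"date": ["2011-01-02", "2010-11-30"], "value": [1.0, 2.0]}
        )
        out = quarterly_boxplots(df, "value", "date")
        assert out["quarter"].tolist() == ["2010-Q4", "2011-Q1"]

    def test_undated_rows_excluded_and_counted(self):
        df = pd.DataFrame(
            {"date": ["2010-01-15", None, "bogus"], "value": [5.0, 7.0, 9.0]}
        )
        out = quarterly_boxplots(df, "value", "date")
        assert out["n"].sum() == 1
        assert out.attrs["n_excluded"] == 2

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "date": pd.date_range("2012-01-01", periods=200, freq="5D").astype(str),
                "value": rng.normal(size=200),
            }
        )
        out = quarterly_boxplots(df, "value", "date")
        assert (out["q1"] <= out["median"]).all()
        assert (out["median"] <= out["q3"]).all()
        assert (out["min"] <= out["q1"]).all()
        assert (out["q3"] <= out["max"]).all()

    def test_no_dated_rows_is_an_error(self):
        df = pd.DataFrame({"date": [None], "value": [1.0]})
        with pytest.raises(ValueError, match="no dated rows"):
            quarterly_boxplots(df, "value", "date")
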