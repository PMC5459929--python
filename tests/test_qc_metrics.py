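import numpy as np
import pytest

import brute_force as bf
from sraqc import (
    DuplicationConfig,
    ReadRecord,
    SyntheticSpec,
    basic_stats,
    compute_run_quality,
    duplication_pct,
    generate_fastq,
    generate_reads,
    length_stats,
    per_base_n_content,
    per_base_quality,
)


class TestBasicStats:
    def test_gc_excludes_uncalled_bases(self):
        reads = [ReadRecord("a", "ACGT", [1] * 4), ReadRecord("b", "GGCC", [1] * 4)]
        assert basic_stats(reads) == (2, 8, 75.0)

    def test_all_n_gives_zero_gc(self):
        assert basic_stats([ReadRecord("a", "NNNN", [1] * 4)]) == (1, 4, 0.0)

    def test_other_iupac_letters_ignored_in_gc(self):
        # R is neither GC nor N: out of numerator and denominator
        reads = [ReadRecord("a", "GRCR", [1] * 4)]
        n, b, gc = basic_stats(reads)
        assert (n, b) == (1, 4)
        assert gc == 100.0

    def test_empty_stream_allowed(self):
        assert basic_stats([]) == (0, 0, 0.0)

    def test_simulated_gc_near_target(self):
        reads = generate_reads(SyntheticSpec(n_reads=1000, length=100, gc_prob=0.5, seed=11))
        _, _, gc = basic_stats(reads)
        assert abs(gc - 50.0) < 3.0
        assert gc == pytest.approx(bf.gc_percent([r.sequence for r in reads]))


class TestLengthStats:
    @pytest.mark.parametrize(
        "dist, mean, median",
        [
            ({4: 2}, 4.0, 4.0),
            ({"10-14": 3, "15-19": 1}, 13.25, 12.0),
            ({1: 1, 100: 1}, 50.5, 1.0),  # lower median on even n
        ],
    )
    def test_examples(self, dist, mean, median):
        assert length_stats(dist) == (mean, median)

    def test_binned_median_matches_expanded_reads(self):
        # expanding bins to explicit per-read midpoints gives the same median
        dist = {"10-14": 3, "15-19": 5, "20-24": 2}
        expanded = sorted([12.0] * 3 + [17.0] * 5 + [22.0] * 2)
        assert length_stats(dist)[1] == bf.nr(expanded, 0.5)

    @pytest.mark.parametrize("bad", [{"10-14": 1, "12-16": 1}, {"14-10": 1}, {"x": 1}])
    def test_malformed_or_overlapping_bins_rejected(self, bad):
        with pytest.raises(ValueError):
            length_stats(bad)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            length_stats({})


class TestPerBaseQuality:
    def test_single_read(self):
        rows, mean_acc, median_acc = per_base_quality(
            [ReadRecord("a", "ACG", [10, 20, 30])]
        )
        assert [r.mean for r in rows] == [10, 20, 30]
        assert mean_acc == 20.0
        assert median_acc == 20.0

    def test_symmetric_pair(self):
        rows, mean_acc, _ = per_base_quality(
            [ReadRecord("a", "AC", [0, 0]), ReadRecord("b", "AC", [40, 40])]
        )
        assert [r.mean for r in rows] == [20.0, 20.0]
        assert mean_acc == 20.0

    def test_empty_stream_is_error(self):
        with pytest.raises(ValueError, match="no reads"):
            per_base_quality([])

    def test_sloped_quality_model_recovers_analytic_mean(self):
        # E[Q_i] = 38 - 0.1 i over i=1..100 averages to 32.95; the upper
        # clamp at 40 biases early positions slightly downward
        reads = generate_reads(
            SyntheticSpec(
                n_reads=500, length=100, q_intercept=38, q_slope=-0.1, q_sd=2, seed=42
            )
        )
        _, mean_acc, _ = per_base_quality(reads)
        assert abs(mean_acc - 32.95) < 0.5
        _, oracle_mean, oracle_median = bf.per_position_quality(
            [r.qualities for r in reads]
        )
        assert mean_acc == pytest.approx(oracle_mean)

    def test_ragged_lengths_use_covering_reads_only(self):
        reads = [ReadRecord("a", "ACGT", [10, 10, 10, 30]), ReadRecord("b", "AC", [20, 20])]
        rows, _, _ = per_base_quality(reads)
        assert [r.n for r in rows] == [2, 2, 1, 1]
        assert [r.mean for r in rows] == [15.0, 15.0, 10.0, 30.0]


class TestPerBaseNContent:
    def test_examples(self):
        table, pct = per_base_n_content([ReadRecord("a", "ANNN", [1] * 4)])
        assert [p for _, p in table] == [0.0, 100.0, 100.0, 100.0]
        assert pct == 75.0

        _, pct = per_base_n_content(
            [ReadRecord("a", "ACGT", [1] * 4), ReadRecord("b", "ACGT", [1] * 4)]
        )
        assert pct == 0.0

        table, pct = per_base_n_content(
            [ReadRecord(str(i), s, [1] * 2) for i, s in enumerate(["AN", "AA", "AA", "AA"])]
        )
        assert [p for _, p in table] == [0.0, 25.0]
        assert pct == 12.5

    def test_empty_stream_is_error(self):
        with pytest.raises(ValueError, match="no reads"):
            per_base_n_content([])


class TestDuplication:
    def test_exact_mode_counts_distinct_keys(self):
        reads = [
            ReadRecord("a", "ACGT", [1] * 4),
            ReadRecord("b", "ACGT", [1] * 4),
            ReadRecord("c", "GGGG", [1] * 4),
        ]
        assert duplication_pct(reads, DuplicationConfig(mode="exact")) == pytest.approx(
            100 / 3
        )

    def test_empty_stream_gives_zero(self):
        assert duplication_pct([], DuplicationConfig(mode="exact")) == 0.0

    def test_long_reads_are_key_truncated(self):
        # identical first 50 bases, different tails beyond 75 bp
        a = "A" * 50 + "C" * 30
        b = "A" * 50 + "G" * 30
        reads = [ReadRecord("a", a, [1] * 80), ReadRecord("b", b, [1] * 80)]
        assert duplication_pct(reads, DuplicationConfig(mode="exact")) == 50.0

    def test_capped_equals_exact_below_track_limit(self):
        reads = generate_reads(
            SyntheticSpec(n_templates=30, copies_per_template=3, length=40, seed=9)
        )
        exact = duplication_pct(reads, DuplicationConfig(mode="exact"))
        capped = duplication_pct(reads, DuplicationConfig(mode="capped", track_limit=1000))
        assert capped == exact

    def test_capped_estimate_on_template_pool(self):
        # 200 templates x 5 copies: analytic duplicate percentage is 80.0
        reads = generate_reads(
            SyntheticSpec(n_templates=200, copies_per_template=5, length=50, seed=7)
        )
        exact = duplication_pct(reads, DuplicationConfig(mode="exact"))
        assert exact == pytest.approx(80.0)
        capped = duplication_pct(reads, DuplicationConfig(mode="capped", track_limit=50))
        assert abs(capped - 80.0) < 2.0

    def test_capped_error_bounded_at_higher_duplication_levels(self):
        rng = np.random.default_rng(123)
        for copies in (2, 10):
            reads = generate_reads(
                SyntheticSpec(
                    n_templates=500,
                    copies_per_template=copies,
                    length=36,
                    seed=int(rng.integers(2**31)),
                )
            )
            exact = duplication_pct(reads, DuplicationConfig(mode="exact"))
            capped = duplication_pct(
                reads, DuplicationConfig(mode="capped", track_limit=100)
            )
            assert abs(capped - exact) <= 5.0


class TestComputeRunQuality:
    def test_single_file(self, tmp_path):
        from sraqc import write_fastq

        write_fastq(
            [ReadRecord("a", "ACGT", [10] * 4), ReadRecord("b", "GGCC", [10] * 4)],
            tmp_path / "r.fastq",
        )
        rq = compute_run_quality("R", tmp_path / "r.fastq")
        assert rq.total_reads == 2
        assert rq.pct_gc == 75.0
        assert rq.mean_length == 4.0

    def test_paired_merge_averages_and_sums(self, tmp_path):
        generate_fastq(SyntheticSpec(n_reads=100, gc_prob=0.4, seed=1), tmp_path / "p_1.fastq")
        generate_fastq(SyntheticSpec(n_reads=100, gc_prob=0.6, seed=2), tmp_path / "p_2.fastq")
        m1 = compute_run_quality("m1", tmp_path / "p_1.fastq")
        m2 = compute_run_quality("m2", tmp_path / "p_2.fastq")
        pair = compute_run_quality("P", [tmp_path / "p_1.fastq", tmp_path / "p_2.fastq"])
        assert pair.total_reads == m1.total_reads + m2.total_reads
        assert pair.total_bases == m1.total_bases + m2.total_bases
        assert pair.pct_gc == pytest.approx((m1.pct_gc + m2.pct_gc) / 2)
        assert pair.mean_accuracy == pytest.approx((m1.mean_accuracy + m2.mean_accuracy) / 2)

    def test_pair_of_identical_files_changes_nothing_but_totals(self, tmp_path):
        generate_fastq(SyntheticSpec(n_reads=50, seed=5), tmp_path / "a_1.fastq")
        generate_fastq(SyntheticSpec(n_reads=50, seed=5), tmp_path / "a_2.fastq")
        single = compute_run_quality("s", tmp_path / "a_1.fastq")
        pair = compute_run_quality("p", [tmp_path / "a_1.fastq", tmp_path / "a_2.fastq"])
        assert pair.total_reads == 2 * single.total_reads
        assert pair.mean_accuracy == pytest.approx(single.mean_accuracy)
        assert pair.duplicate_pct == pytest.approx(single.duplicate_pct)

    def test_errors_carry_run_context(self, tmp_path):
        (tmp_path / "bad.fastq").write_text("@r1\nACGT\n+\nII\n")
        with pytest.raises(ValueError, match="'R9'"):
            compute_run_quality("R9", tmp_path / "bad.fastq")

    def test_read_order_invariance_except_capped_duplication(self, tmp_path):
        from sraqc import write_fastq

        reads = generate_reads(SyntheticSpec(n_reads=200, n_prob=0.02, seed=3))
        write_fastq(reads, tmp_path / "fwd.fastq")
        write_fastq(list(reversed(reads)), tmp_path / "rev.fastq")
        cfg = DuplicationConfig(mode="exact")
        fwd = compute_run_quality("f", tmp_path / "fwd.fastq", cfg)
        rev = compute_run_quality("r", tmp_path / "rev.fastq", cfg)
        for fieldname in (
            "total_reads",
            "total_bases",
            "pct_gc",
            "mean_length",
            "median_length",
            "mean_accuracy",
            "median_accuracy",
            "duplicate_pct",
            "n_content_pct",
        ):
            assert getattr(fwd, fieldname) == pytest.approx(getattr(rev, fieldname))
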