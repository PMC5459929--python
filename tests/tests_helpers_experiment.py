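"""Shared factory for experiment-quality records used by several test modules."""

from sraqc import ExperimentQuality


def make_experiments(n: int) -> list[ExperimentQuality]:
    return [
        ExperimentQuality(
            experiment_id=f"E{i}",
            n_runs=1 + i % 3,
            total_reads=1000 * (i + 1),
            total_bases=100_000 * (i + 1),
            mean_length=100.0 + i,
            median_length=100.0,
            pct_gc=45.0 + i,
            duplicate_pct=5.0 * i,
            mean_accuracy=30.0 + 0.5 * i,
            median_accuracy=31.0 + 0.5 * i,
            n_content_pct=0.1 * i,
        )
        for i in range(n)
    ]
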