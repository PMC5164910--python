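"""Side-by-side comparison of GA-FCM against the classical-FCM baseline.

For each image/truth pair both methods are run from the same child seed
(so the baseline's random initialisation matches the first chromosome the
GA would draw), confusion counts and percent metrics are computed for
each, and the results are tabulated per image with a trailing mean row —
the layout used to compare an optimised segmenter against its baseline on
a multi-slice test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import MetricSet, aggregate, confusion_counts, metrics
from .pipeline import PipelineConfig, SegmentationResult, segment, segment_fcm_baseline

__all__ = ["ComparisonReport", "run_compare", "spawn_rngs"]

_METHODS = ("gafcm", "fcm")


def spawn_rngs(master_seed: int, n: int) -> list[np.random.Generator]:
    """Fan a master seed out into ``n`` independent reproducible streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


@dataclass
class ComparisonReport:
    """Per-image metrics and counts for both methods.

    ``metrics_table`` carries one row per image plus a ``mean`` row, with
    hierarchical columns (metric, method); ``counts_table`` likewise holds
    the raw TP/TN/FP/FN.  ``errors`` records images that failed, which do
    not abort the remaining images.
    """

    metrics_table: pd.DataFrame
    counts_table: pd.DataFrame
    errors: dict[int, str]


def _result_rows(result: SegmentationResult, truth):
    counts = confusion_counts(result.vessel_mask, truth)
    return counts, metrics(counts)


def run_compare(
    images,
    truths,
    config: PipelineConfig | None = None,
    master_seed: int = 0,
) -> ComparisonReport:
    """Run both methods on every image and tabulate the comparison."""
    images = list(images)
    truths = list(truths)
    if len(images) != len(truths):
        raise ValueError(f"{len(images)} images but {len(truths)} truth masks")
    if not images:
        raise ValueError("at least one image with truth is required")
    if config is None:
        config = PipelineConfig()

    metric_rows: dict[str, list[MetricSet]] = {m: [] for m in _METHODS}
    records: list[dict] = []
    errors: dict[int, str] = {}
    rngs = spawn_rngs(master_seed, len(images))

    for idx, (image, truth, rng) in enumerate(zip(images, truths, rngs), start=1):
        try:
            seed_state = rng.bit_generator.state
            ga_res = segment(image, config, rng)
            base_rng = np.random.Generator(type(rng.bit_generator)())
            base_rng.bit_generator.state = seed_state
            base_res = segment_fcm_baseline(image, config, base_rng)
        except Exception as exc:  # record and continue with remaining images
            errors[idx] = f"{type(exc).__name__}: {exc}"
            continue
        row: dict = {"image": idx}
        for method, res in (("gafcm", ga_res), ("fcm", base_res)):
            counts, ms = _result_rows(res, truth)
            metric_rows[method].append(ms)
            row.update(
                {
                    (method, "TP"): counts.tp,
                    (method, "TN"): counts.tn,
                    (method, "FP"): counts.fp,
                    (method, "FN"): counts.fn,
                    (method, "sensitivity"): ms.sensitivity,
                    (method, "specificity"): ms.specificity,
                    (method, "accuracy"): ms.accuracy,
                    (method, "final_cost"): res.cost_trace[-1],
                }
            )
        records.append(row)

    if not records:
        raise ValueError(f"every image failed: {errors}")

    index = [r["image"] for r in records]
    metric_cols = ["sensitivity", "specificity", "accuracy", "final_cost"]
    count_cols = ["TP", "TN", "FP", "FN"]
    metrics_table = pd.DataFrame(
        {
            (method, col): [r[(method, col)] for r in records]
            for method in _METHODS
            for col in metric_cols
        },
        index=pd.Index(index, name="image"),
    )
    counts_table = pd.DataFrame(
        {
            (method, col): [r[(method, col)] for r in records]
            for method in _METHODS
            for col in count_cols
        },
        index=pd.Index(index, name="image"),
    )

    mean_metrics = {}
    for method in _METHODS:
        agg = aggregate(metric_rows[method])
        mean_metrics[(method, "sensitivity")] = agg.sensitivity
        mean_metrics[(method, "specificity")] = agg.specificity
        mean_metrics[(method, "accuracy")] = agg.accuracy
        mean_metrics[(method, "final_cost")] = metrics_table[(method, "final_cost")].mean()
    metrics_table.loc["mean"] = mean_metrics
    counts_table.loc["mean"] = counts_table.mean()

    return ComparisonReport(
        metrics_table=metrics_table, counts_table=counts_table, errors=errors
    )
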