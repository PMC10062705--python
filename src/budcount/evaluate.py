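"""Counting evaluation: per-video errors, error-fraction summaries, regression R².

The counting method is judged the way field counting methods usually are:
algorithmic counts for a set of video segments are compared against manual
(or, for simulations, ground-truth) counts via the per-video error
``predicted - true``, the mean absolute error, the fraction of videos whose
absolute error is at most a tolerance k, and the coefficient of
determination R² of an ordinary least-squares regression of predicted on
true counts (for simple linear regression with intercept this equals the
squared Pearson correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import run_video
from .tracking import TrackerConfig

__all__ = ["CountReport", "count_error_stats", "regression_r2", "evaluate_benchmark"]


def regression_r2(pred: Sequence[float], true: Sequence[float]) -> float:
    """R² of the OLS fit of predicted counts on true counts.

    Requires at least 3 pairs and a non-constant true vector; 1.0 for a
    perfect fit, near 0 when predictions carry no information about truth.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("pred and true must be equal-length 1-D sequences")
    if len(pred) < 3:
        raise ValueError("need at least 3 count pairs for a regression")
    if np.ptp(true) == 0:
        raise ValueError("R^2 is undefined for a constant true-count vector")
    result = stats.linregress(true, pred)
    return float(result.rvalue**2)


@dataclass
class CountReport:
    """Per-video count comparison plus aggregate accuracy statistics."""

    per_video: pd.DataFrame  # columns: video, predicted, true, error
    mae: float
    r2: float | None

    def fraction_abs_err_le(self, k: float) -> float:
        """Fraction of videos with |predicted - true| <= k."""
        if k < 0:
            raise ValueError("tolerance k must be non-negative")
        return float(np.mean(np.abs(self.per_video["error"]) <= k))

    def summary(self) -> str:
        lines = [
            f"videos:             {len(self.per_video)}",
            f"total predicted:    {int(self.per_video['predicted'].sum())}",
            f"total true:         {int(self.per_video['true'].sum())}",
            f"mean absolute error:{self.mae:8.3f}",
        ]
        if self.r2 is not None:
            lines.append(f"regression R^2:     {self.r2:8.4f}")
        for k in (0, 2, 4, 6, 8):
            lines.append(
                f"fraction |err| <= {k}: {self.fraction_abs_err_le(k):6.3f}"
            )
        return "\n".join(lines)


def count_error_stats(pairs: Sequence[tuple[float, float]]) -> CountReport:
    """Build a :class:`CountReport` from (predicted, true) count pairs.

    R² is included when a regression is defined (>= 3 pairs, non-constant
    truth) and left as ``None`` otherwise.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (predicted, true) pair")
    pred = np.array([p for p, _ in pairs], dtype=float)
    true = np.array([t for _, t in pairs], dtype=float)
    if np.any(pred < 0) or np.any(true < 0):
        raise ValueError("counts must be non-negative")
    errors = pred - true
    per_video = pd.DataFrame(
        {
            "video": np.arange(len(pairs)),
            "predicted": pred,
            "true": true,
            "error": errors,
        }
    )
    try:
        r2: float | None = regression_r2(pred, true)
    except ValueError:
        r2 = None
    return CountReport(per_video=per_video, mae=float(np.mean(np.abs(errors))), r2=r2)


def evaluate_benchmark(
    benchmark: Iterable[tuple[list, int]],
    cfg: TrackerConfig | None = None,
) -> CountReport:
    """Run the counting pipeline over a benchmark and score it.

    ``benchmark`` is a sequence of (detection stream, true count) pairs, as
    produced by :func:`budcount.simulate.make_benchmark`.
    """
    pairs = []
    for stream, true_count in benchmark:
        result = run_video(stream, cfg)
        pairs.append((result.count, true_count))
    return count_error_stats(pairs)
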