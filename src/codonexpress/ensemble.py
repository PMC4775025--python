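"""Evaluation metrics and per-pattern ensemble averaging.

The ensemble prediction for a pattern is the arithmetic mean, across
cross-validation repetitions, of that pattern's out-of-fold predictions.
Metrics (RMSE, squared Pearson correlation, absolute percentage error)
are then computed on the averaged vector — which is *not* the same as
averaging per-repetition metrics. Because squared error is convex, the
ensemble's MSE never exceeds the mean of the constituents' MSEs: the
ensemble shares their bias but has lower variance.

R^2 throughout this package is the squared Pearson correlation between
measured and predicted values. The coefficient of determination is
available separately (:func:`explained_variance_r2`) for diagnostics but
is never reported as R^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rmse",
    "r_squared",
    "explained_variance_r2",
    "ape",
    "ape_summary",
    "EnsembleResult",
    "ensemble_average",
]


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root mean squared error, sqrt(mean((y - yhat)^2))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 1:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Squared Pearson correlation between measured and predicted values (in [0, 1])."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least two values")
    if np.std(y) == 0.0 or np.std(yhat) == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = stats.pearsonr(y, yhat).statistic
    return float(r * r)


def explained_variance_r2(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot (diagnostic only; can be < 0)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("coefficient of determination undefined for constant y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def ape(y: Sequence[float], yhat: Sequence[float]) -> np.ndarray:
    """Absolute percentage error per pattern: 100*|y - yhat|/y. Requires y > 0."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if np.any(y <= 0):
        raise ValueError("APE requires strictly positive measured values")
    return 100.0 * np.abs(y - yhat) / y


def ape_summary(
    apes: Sequence[float],
    thresholds: Sequence[float] = (30.0, 60.0),
    bin_width: float = 10.0,
    bin_edges: Sequence[float] | None = None,
) -> dict:
    """Fractions of patterns with APE strictly below each threshold, plus a histogram.

    Default histogram bins are ``bin_width``-percent wide, from 0 to the
    maximum APE; pass ``bin_edges`` to override. Counts sum to the number
    of patterns.
    """
    apes = np.asarray(apes, dtype=float)
    if apes.size == 0:
        raise ValueError("empty APE vector")
    thresholds = [float(t) for t in thresholds]
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be positive and ascending")
    fractions = {t: float(np.mean(apes < t)) for t in thresholds}
    if bin_edges is None:
        top = max(float(apes.max()), bin_width)
        n_bins = int(np.ceil(top / bin_width))
        bin_edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, edges = np.histogram(apes, bins=np.asarray(bin_edges, dtype=float))
    return {
        "fractions_below": fractions,
        "histogram_counts": counts.tolist(),
        "histogram_edges": np.asarray(edges).tolist(),
    }


@dataclass(frozen=True)
class EnsembleResult:
    """Per-pattern averaged predictions across repetitions, with metrics."""

    predictions: np.ndarray
    rmse: float
    r2: float
    ape: np.ndarray
    ape_fractions: dict[float, float]
    pattern_ids: tuple[str, ...] | None = None
    measured: np.ndarray | None = None

    def to_table(self) -> pd.DataFrame:
        ids = (
            list(self.pattern_ids)
            if self.pattern_ids is not None
            else [str(i) for i in range(len(self.predictions))]
        )
        data = {"id": ids, "ensemble_prediction": self.predictions, "ape": self.ape}
        if self.measured is not None:
            data = {
                "id": ids,
                "measured": self.measured,
                "ensemble_prediction": self.predictions,
                "ape": self.ape,
            }
        return pd.DataFrame(data)

    def summary(self) -> dict:
        return {
            "rmse": self.rmse,
            "r2": self.r2,
            "ape_fractions_below": {str(k): v for k, v in self.ape_fractions.items()},
        }

    def save(self, table_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.to_table().to_csv(table_path, index=False)
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def ensemble_average(
    reps: Sequence,
    y: Sequence[float],
    thresholds: Sequence[float] = (30.0, 60.0),
    pattern_ids: Sequence[str] | None = None,
) -> EnsembleResult:
    """Average out-of-fold predictions pattern-wise across repetitions, then score.

    ``reps`` are repetition results (anything with a ``predictions`` vector,
    or raw prediction vectors); all must cover the same patterns as ``y``.
    """
    y = np.asarray(y, dtype=float)
    mats = []
    for rep in reps:
        p = np.asarray(getattr(rep, "predictions", rep), dtype=float)
        if p.shape != y.shape:
            raise ValueError(
                f"repetition covers {p.shape[0]} patterns, expected {y.shape[0]}"
            )
        mats.append(p)
    if not mats:
        raise ValueError("need at least one repetition")
    avg = np.mean(np.vstack(mats), axis=0)
    errors = ape(y, avg)
    summ = ape_summary(errors, thresholds=thresholds)
    return EnsembleResult(
        predictions=avg,
        rmse=rmse(y, avg),
        r2=r_squared(y, avg),
        ape=errors,
        ape_fractions=dict(summ["fractions_below"]),
        pattern_ids=tuple(pattern_ids) if pattern_ids is not None else None,
        measured=y,
    )
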