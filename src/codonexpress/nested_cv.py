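"""Nested n-fold cross-validation with repeated fold regroupings.

An inner n-fold cross-validation selects hyperparameters; an outer m-fold
cross-validation provides test predictions from models that never saw the
held-out patterns; repeating the whole procedure with re-drawn fold
groupings yields a distribution of test metrics (and the raw material for
per-pattern ensemble averaging). A final model is fit on all patterns with
hyperparameters chosen by a plain inner CV over everything.

Fold sizes differ by at most one: patterns are shuffled (seeded) and dealt
round-robin, which is the only consistent reading of "folds of equal size"
when the pattern count is not divisible by the fold count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import numpy as np

from .ensemble import r_squared, rmse
from .features import FeatureMatrix
from .regression import FittedModel, ModelSpec, fit, predict

__all__ = [
    "FoldPlan",
    "RepetitionResult",
    "make_fold_plan",
    "select_hyperparameters",
    "run_nested_cv",
    "repeat_nested_cv",
    "fit_final_model",
    "summarize_repetitions",
]


@dataclass(frozen=True)
class FoldPlan:
    """Seeded partition of patterns into outer folds and, per outer fold, inner folds.

    ``outer[i]`` is the outer-fold label (1..m_outer) of pattern i.
    ``inner[f][i]`` is the inner-fold label (1..n_inner) of pattern i within
    the inner cross-validation run while outer fold f is held out; patterns
    belonging to fold f itself carry label 0 there.
    """

    seed: int
    outer: np.ndarray
    inner: dict[int, np.ndarray]

    @property
    def n_patterns(self) -> int:
        return len(self.outer)

    @property
    def outer_labels(self) -> list[int]:
        return sorted(set(int(v) for v in self.outer))


def _deal(indices: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign shuffled indices round-robin to folds 1..n_folds (sizes differ by <=1)."""
    shuffled = rng.permutation(indices)
    labels = np.zeros(len(indices), dtype=np.int64)
    pos = {int(idx): k for k, idx in enumerate(indices)}
    for k, idx in enumerate(shuffled):
        labels[pos[int(idx)]] = 1 + k % n_folds
    return labels


def make_fold_plan(n_patterns: int, m_outer: int, n_inner: int, seed: int) -> FoldPlan:
    """Draw a seeded uniform-random nested fold assignment.

    The inner folds for each outer fold partition exactly the patterns
    outside that fold.
    """
    if not 2 <= m_outer <= n_patterns:
        raise ValueError(f"m_outer={m_outer} infeasible for {n_patterns} patterns")
    min_train = n_patterns - ceil(n_patterns / m_outer)
    if not 2 <= n_inner <= min_train:
        raise ValueError(
            f"n_inner={n_inner} infeasible: training sets have as few as {min_train} patterns"
        )
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n_patterns)
    outer_labels_per_idx = _deal(all_idx, m_outer, rng)
    outer = np.zeros(n_patterns, dtype=np.int64)
    outer[all_idx] = outer_labels_per_idx
    inner: dict[int, np.ndarray] = {}
    for f in range(1, m_outer + 1):
        train_idx = np.flatnonzero(outer != f)
        lab = np.zeros(n_patterns, dtype=np.int64)
        lab[train_idx] = _deal(train_idx, n_inner, rng)
        inner[f] = lab
    return FoldPlan(seed=seed, outer=outer, inner=inner)


@dataclass(frozen=True)
class RepetitionResult:
    """One nested-CV run: out-of-fold predictions and test metrics.

    Every pattern has exactly one out-of-fold prediction, produced by the
    model trained while that pattern's outer fold was held out. Different
    outer folds may select different hyperparameters; each fold's choice
    is recorded.
    """

    seed: int
    predictions: np.ndarray
    fold_hyperparams: dict[int, dict]
    rmse: float
    r2: float

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "predictions": self.predictions.tolist(),
            "fold_hyperparams": {str(k): v for k, v in self.fold_hyperparams.items()},
            "rmse": self.rmse,
            "r2": self.r2,
        }


def _rows(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _safe_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation, 0.0 (with a warning) for constant predictions."""
    if np.std(yhat) == 0.0 or np.std(y) == 0.0:
        warnings.warn("constant vector in R^2 computation; recording r2=0.0", stacklevel=2)
        return 0.0
    return r_squared(y, yhat)


def select_hyperparameters(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float] | np.ndarray,
    spec: ModelSpec,
    inner_folds: np.ndarray,
) -> dict:
    """Pick the grid point minimizing mean validation RMSE over the inner folds.

    ``inner_folds`` labels every provided pattern with its inner fold
    (1..n_inner). Ties go to the earliest point in declared grid order.
    """
    values = _rows(X)
    y = np.asarray(y, dtype=float)
    inner_folds = np.asarray(inner_folds)
    labels = sorted(set(int(v) for v in inner_folds))
    if not labels or 0 in labels:
        raise ValueError("inner fold labels must be positive for every pattern")
    grid = spec.grid_points()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    splits = []
    for lab in labels:
        val_mask = inner_folds == lab
        splits.append((np.flatnonzero(~val_mask), np.flatnonzero(val_mask)))
    best_point, best_score = None, np.inf
    for point in grid:
        fold_rmses = []
        for train_idx, val_idx in splits:
            model = fit(spec, point, values[train_idx], y[train_idx])
            fold_rmses.append(rmse(y[val_idx], predict(model, values[val_idx])))
        score = float(np.mean(fold_rmses))
        if score < best_score:
            best_point, best_score = point, score
    return dict(best_point)


def run_nested_cv(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float] | np.ndarray,
    spec: ModelSpec,
    plan: FoldPlan,
) -> RepetitionResult:
    """One full nested-CV pass over the given fold plan.

    For each outer fold: hyperparameters are chosen by inner CV on the
    remaining patterns, a temporary model is fit on all of them, and the
    held-out fold is predicted. Metrics are computed on the assembled
    out-of-fold prediction vector.
    """
    values = _rows(X)
    y = np.asarray(y, dtype=float)
    if plan.n_patterns != len(y):
        raise ValueError(f"fold plan covers {plan.n_patterns} patterns but data has {len(y)}")
    preds = np.full(len(y), np.nan)
    fold_hp: dict[int, dict] = {}
    for f in plan.outer_labels:
        test_idx = np.flatnonzero(plan.outer == f)
        train_idx = np.flatnonzero(plan.outer != f)
        inner_labels = plan.inner[f][train_idx]
        try:
            hp = select_hyperparameters(values[train_idx], y[train_idx], spec, inner_labels)
            model = fit(spec, hp, values[train_idx], y[train_idx])
            preds[test_idx] = predict(model, values[test_idx])
        except Exception as exc:  # annotate with fold context
            raise RuntimeError(f"nested CV failed in outer fold {f}") from exc
        fold_hp[f] = hp
    assert not np.isnan(preds).any()
    return RepetitionResult(
        seed=plan.seed,
        predictions=preds,
        fold_hyperparams=fold_hp,
        rmse=rmse(y, preds),
        r2=_safe_r2(y, preds),
    )


def repeat_nested_cv(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float] | np.ndarray,
    spec: ModelSpec,
    m_outer: int,
    n_inner: int,
    n_reps: int,
    base_seed: int,
) -> tuple[list[RepetitionResult], dict]:
    """Repeat nested CV with freshly drawn fold groupings.

    Repetition r uses seed = base_seed + r to regenerate both the outer and
    the inner groupings. Returns all repetition results plus a summary with
    the mean and SD of RMSE and R^2 across repetitions (the non-ensemble
    aggregate: metrics averaged over repetitions).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    y = np.asarray(y, dtype=float)
    reps = []
    for r in range(n_reps):
        plan = make_fold_plan(len(y), m_outer, n_inner, base_seed + r)
        reps.append(run_nested_cv(X, y, spec, plan))
    return reps, summarize_repetitions(reps)


def summarize_repetitions(reps: Sequence[RepetitionResult]) -> dict:
    rmses = np.array([r.rmse for r in reps])
    r2s = np.array([r.r2 for r in reps])
    return {
        "n_reps": len(reps),
        "rmse_mean": float(rmses.mean()),
        "rmse_sd": float(rmses.std(ddof=1)) if len(reps) > 1 else 0.0,
        "r2_mean": float(r2s.mean()),
        "r2_sd": float(r2s.std(ddof=1)) if len(reps) > 1 else 0.0,
    }


def fit_final_model(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float] | np.ndarray,
    spec: ModelSpec,
    n_inner: int,
    seed: int,
) -> FittedModel:
    """Fit on all patterns; hyperparameters chosen by plain n_inner-fold CV on all patterns.

    No patterns are reserved for an outer loop — this is the deployment
    model, whose generalization was already estimated by the nested runs.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    labels = _deal(np.arange(len(y)), n_inner, rng)
    hp = select_hyperparameters(_rows(X), y, spec, labels)
    return fit(spec, hp, X, y)
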