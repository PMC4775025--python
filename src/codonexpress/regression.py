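"""Deterministic regression backends: epsilon-SVR (RBF kernel) and PLS.

Both algorithms sit behind one fit/predict contract. Features are
standardized to zero mean / unit SD using *training* statistics only
(constant columns pass through as zeros), which keeps nested
cross-validation leak-free and gives the RBF kernel comparable scales.
The target is never standardized; instead the SVR tolerance band
``epsilon`` is expressed relative to SD(y_train) so the same grid
transfers across datasets whose expression scales differ by orders of
magnitude, and the RBF width ``gamma`` is expressed per-feature
(divided by the number of features at fit time).

After fitting, the predictor state is reduced to explicit arrays
(PLS: weight vector + intercept; SVR: support vectors, dual
coefficients, intercept, gamma), so predictions are reproducible,
independent of the backing library object, and serializable as JSON.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR

from .features import FeatureMatrix

__all__ = ["ModelSpec", "FittedModel", "fit", "predict"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm choice plus its hyperparameter grid.

    For ``algorithm="pls"`` the grid is ``components`` (numbers of latent
    components). For ``algorithm="svr_rbf"`` it is the Cartesian product of
    ``C`` (cost of points outside the epsilon band), ``epsilon_rel``
    (half-width of the insensitive band, in units of SD(y_train)) and
    ``gamma_scale`` (RBF width; effective gamma = gamma_scale / n_features).
    Grid order — and therefore tie-breaking during selection — follows the
    declared list order, with C varying slowest.
    """

    algorithm: str
    components: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    C: tuple[float, ...] = tuple(4.0**k for k in range(-2, 7))
    epsilon_rel: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5)
    gamma_scale: tuple[float, ...] = tuple(4.0**k for k in range(-5, 2))

    def __post_init__(self) -> None:
        if self.algorithm not in ("pls", "svr_rbf"):
            raise ValueError(f"algorithm must be 'pls' or 'svr_rbf', got {self.algorithm!r}")
        if self.algorithm == "pls":
            if not self.components or any(k < 1 for k in self.components):
                raise ValueError("components must be a non-empty list of positive ints")
        else:
            for name in ("C", "epsilon_rel", "gamma_scale"):
                vals = getattr(self, name)
                if not vals or any(v <= 0 for v in vals):
                    raise ValueError(f"{name} must be a non-empty list of positive values")

    def grid_points(self) -> list[dict]:
        """All hyperparameter combinations in declared (tie-break) order."""
        if self.algorithm == "pls":
            return [{"n_components": int(k)} for k in self.components]
        return [
            {"C": float(c), "epsilon_rel": float(e), "gamma_scale": float(g)}
            for c, e, g in itertools.product(self.C, self.epsilon_rel, self.gamma_scale)
        ]

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        kwargs = {"algorithm": d["algorithm"]}
        for key in ("components", "C", "epsilon_rel", "gamma_scale"):
            if key in d:
                kwargs[key] = tuple(d[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class FittedModel:
    """A trained predictor with its standardization and resolved hyperparameters.

    ``predict`` is deterministic given the model and inputs. ``columns`` is
    the training column schema; prediction inputs must match it by name and
    order when both sides carry names.
    """

    algorithm: str
    hyperparams: dict
    mean: np.ndarray
    scale: np.ndarray
    columns: tuple[str, ...] | None
    # predictor state: pls -> {"w", "b"}; svr_rbf -> {"sv", "dual", "b", "gamma"}
    state: dict

    def predict(self, X: FeatureMatrix | np.ndarray) -> np.ndarray:
        return predict(self, X)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "algorithm": self.algorithm,
            "hyperparams": self.hyperparams,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "columns": list(self.columns) if self.columns is not None else None,
            "state": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.state.items()
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedModel":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')}")
        state = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
            for k, v in d["state"].items()
        }
        return cls(
            algorithm=d["algorithm"],
            hyperparams=dict(d["hyperparams"]),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            columns=tuple(d["columns"]) if d["columns"] is not None else None,
            state=state,
        )

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_array(X: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.columns
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr, None


def fit(
    spec: ModelSpec,
    hyperparams: Mapping,
    X: FeatureMatrix | np.ndarray,
    y: Sequence[float] | np.ndarray,
) -> FittedModel:
    """Fit one grid point on (X, y) with training-set feature standardization.

    ``hyperparams`` is one element of ``spec.grid_points()``. The target stays
    on its native scale. Degenerate cases (zero-variance y, component count
    exceeding the data rank) fit with a warning rather than failing.
    """
    values, columns = _as_array(X)
    y = np.asarray(y, dtype=float)
    if values.shape[0] != y.shape[0]:
        raise ValueError(f"{values.shape[0]} rows but {y.shape[0]} targets")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 training patterns")

    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)  # constant columns standardize to 0
    Xs = (values - mean) / scale

    y_sd = float(y.std())
    if y_sd == 0.0:
        warnings.warn("target has zero variance; fitting a constant model", stacklevel=2)

    if spec.algorithm == "pls":
        k = int(hyperparams["n_components"])
        k_max = int(min(Xs.shape[1], Xs.shape[0] - 1))
        if k > k_max:
            warnings.warn(f"n_components={k} exceeds data rank bound; clipped to {k_max}", stacklevel=2)
            k = k_max
        with warnings.catch_warnings():
            # constant-residual warnings are expected on noiseless data
            warnings.filterwarnings("ignore", module="sklearn.cross_decomposition")
            pls = PLSRegression(n_components=k, scale=False)
            pls.fit(Xs, y)
        w = np.asarray(pls.coef_, dtype=float).reshape(-1)
        b = float(np.asarray(pls.intercept_, dtype=float).reshape(-1)[0])
        resolved = {"n_components": k}
        state = {"w": w, "b": b}
    else:
        C = float(hyperparams["C"])
        eps = float(hyperparams["epsilon_rel"]) * (y_sd if y_sd > 0 else 1.0)
        gamma = float(hyperparams["gamma_scale"]) / Xs.shape[1]
        svr = SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
        svr.fit(Xs, y)
        resolved = {"C": C, "epsilon": eps, "gamma": gamma}
        state = {
            "sv": np.asarray(svr.support_vectors_, dtype=float),
            "dual": np.asarray(svr.dual_coef_, dtype=float).reshape(-1),
            "b": float(svr.intercept_[0]),
            "gamma": gamma,
        }

    return FittedModel(
        algorithm=spec.algorithm,
        hyperparams=resolved,
        mean=mean,
        scale=scale,
        columns=columns,
        state=state,
    )


def predict(model: FittedModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """One prediction per row, applying the stored standardization first."""
    values, columns = _as_array(X)
    if model.columns is not None and columns is not None and columns != model.columns:
        raise ValueError(
            "feature columns do not match the training schema "
            f"({len(columns)} vs {len(model.columns)} columns or different order)"
        )
    if values.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"expected {model.mean.shape[0]} features, got {values.shape[1]}"
        )
    Xs = (values - model.mean) / model.scale
    if model.algorithm == "pls":
        return Xs @ model.state["w"] + model.state["b"]
    sv = model.state["sv"]
    sq = ((Xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-model.state["gamma"] * sq)
    return K @ model.state["dual"] + model.state["b"]
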