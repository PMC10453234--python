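"""Error metrics and a model-comparison harness.

Models enter the harness through the usual ``fit(X, y)`` / ``predict(X)``
contract, so scikit-learn regressors and :class:`tabgra.tabnet.TabNetRegressor`
can be compared side by side.  The default train/test split is the
chronological tail of the sample order (surveillance data arrive in time
order, and held-out evaluation on the most recent samples mirrors how the
model would actually be deployed); a seeded random split is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "ErrorReport",
    "error_metrics",
    "chronological_split",
    "random_split",
    "compare_models",
    "ConstantMeanBaseline",
]


@dataclass(frozen=True)
class ErrorReport:
    """RMSE, MAE and per-sample absolute errors of one prediction run.

    RMSE = sqrt(mean((y_hat - y)^2)) and MAE = mean(|y_hat - y|); the
    power-mean inequality guarantees MAE <= RMSE, and both vanish exactly
    when predictions equal targets.
    """

    rmse: float
    mae: float
    n: int
    abs_errors: np.ndarray

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.mae < 0:
            raise ValueError("error metrics are non-negative")


def error_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> ErrorReport:
    """Root-mean-squared and mean absolute prediction error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} targets vs {y_pred.shape[0]} predictions"
        )
    if y_true.size == 0:
        raise ValueError("error metrics need at least one sample")
    abs_errors = np.abs(y_pred - y_true)
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    mae = float(abs_errors.mean())
    return ErrorReport(rmse=rmse, mae=mae, n=y_true.size, abs_errors=abs_errors)


def chronological_split(
    n: int, test_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Last-samples-held-out split: test on the ``test_size`` most recent rows.

    Default test size is max(50, 5% of n), capped at n - 1 so at least one
    training row remains.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if test_size is None:
        test_size = max(50, int(np.ceil(0.05 * n)))
    test_size = min(test_size, n - 1)
    if test_size < 1:
        raise ValueError("test size must be >= 1")
    idx = np.arange(n)
    return idx[:-test_size], idx[-test_size:]


def random_split(
    n: int, test_size: int | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split with the same default test size as the chronological one."""
    if test_size is None:
        test_size = max(50, int(np.ceil(0.05 * n)))
    test_size = min(test_size, n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:-test_size]), np.sort(perm[-test_size:])


@runtime_checkable
class Regressor(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray): ...  # pragma: no cover - protocol
    def predict(self, X: np.ndarray) -> np.ndarray: ...  # pragma: no cover


class ConstantMeanBaseline:
    """Predicts the training-target mean everywhere; the no-information reference."""

    def __init__(self) -> None:
        self.mean_: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ConstantMeanBaseline":
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("baseline is not fitted")
        return np.full(np.asarray(X).shape[0], self.mean_)


def compare_models(
    X: np.ndarray,
    y: np.ndarray,
    models: Mapping[str, Regressor],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> pd.DataFrame:
    """Fit every model on the train split, score on the test split.

    Returns a table (one row per model) sorted by RMSE ascending.  The two
    index sets must be disjoint.  Determinism is the models' own contract:
    with seeded models the table is reproducible.
    """
    if not models:
        raise ValueError("at least one model is required")
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size > 0:
        raise ValueError("train and test indices overlap")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rows = []
    for name, model in models.items():
        model.fit(X[train_idx], y[train_idx])
        report = error_metrics(y[test_idx], model.predict(X[test_idx]))
        rows.append({"model": name, "rmse": report.rmse, "mae": report.mae,
                     "n_test": report.n})
    table = pd.DataFrame(rows).sort_values("rmse", kind="stable").reset_index(drop=True)
    return table
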