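"""Lasso prediction of vGRF characteristics with subject-level evaluation.

The predictor is an L1-penalized linear model minimizing

    (1/2n) * sum_i (y_i - b0 - x_i . b)^2 + lambda * ||b||_1

with an unpenalized intercept, fitted on standardized features.  The
regularization strength is selected by leave-one-subject-out cross-
validation (LOSO-CV) on the training subjects over a 20-point log-spaced
grid in [5e-6, 0.05]; standardization is re-fit inside every fold so
held-out subjects never leak into the scaler.  Reported metrics are RMSE,
MAPE (percent), and the coefficient of determination R^2 computed against
the evaluation split's own mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LinearRegression

from .features import KEY_COLUMNS, Scaler, standardize

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.geomspace(5e-6, 0.05, 20))


def split_subjects(
    subject_ids: list[str] | np.ndarray,
    test_fraction: float = 7.0 / 43.0,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Disjoint train/test subject sets; all of a subject's steps fall on one
    side.  The default fraction reproduces a 36/7 split of 43 subjects.
    """
    unique = sorted(set(map(str, subject_ids)))
    if len(unique) < 2:
        raise ValueError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_test = min(max(1, round(test_fraction * len(unique))), len(unique) - 1)
    test = sorted(unique[i] for i in order[:n_test])
    train = sorted(set(unique) - set(test))
    return train, test


@dataclass(frozen=True)
class FitResult:
    intercept: float
    coefficients: dict[str, float]
    selected_lambda: float
    scaler: Scaler | None = None
    train_subjects: tuple[str, ...] = ()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predict from a feature table already on the model's scale."""
        cols = list(self.coefficients)
        beta = np.array([self.coefficients[c] for c in cols])
        return self.intercept + X[cols].to_numpy(dtype=float) @ beta

    @property
    def l1_norm(self) -> float:
        return float(np.sum(np.abs(list(self.coefficients.values()))))


def fit_lasso(X: pd.DataFrame, y: np.ndarray, lam: float) -> FitResult:
    """Fit the Lasso at one regularization strength.

    ``X`` must be standardized (the penalty is scale-sensitive).  ``lam=0``
    reduces to ordinary least squares.  Deterministic: cyclic coordinate
    descent to tolerance 1e-7.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    cols = [c for c in X.columns if c not in KEY_COLUMNS]
    Xm = X[cols].to_numpy(dtype=float)
    if lam == 0.0:
        model = LinearRegression()
        model.fit(Xm, y)
    else:
        model = Lasso(alpha=lam, tol=1e-7, max_iter=100_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xm, y)
    return FitResult(
        intercept=float(model.intercept_),
        coefficients=dict(zip(cols, map(float, model.coef_))),
        selected_lambda=float(lam),
    )


@dataclass(frozen=True)
class MeanRegressor:
    """Baseline predicting the training-set mean of the target everywhere."""

    mean: float

    @classmethod
    def fit(cls, y_train: np.ndarray) -> "MeanRegressor":
        y_train = np.asarray(y_train, dtype=float)
        if y_train.size == 0:
            raise ValueError("empty training target")
        return cls(float(np.mean(y_train)))

    def predict(self, X) -> np.ndarray:
        n = len(X)
        return np.full(n, self.mean)


def mean_regressor(y_train: np.ndarray) -> MeanRegressor:
    return MeanRegressor.fit(y_train)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """RMSE, MAPE (percent), and R^2 against the split's own mean."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length nonempty vectors")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("pred and truth must be finite")
    if np.any(truth == 0):
        raise ValueError("MAPE undefined for zero truth values")
    err = pred - truth
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(truth)))
    sst = float(np.sum((truth - truth.mean()) ** 2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return {"rmse": rmse, "mape_percent": mape, "r2": r2, "n_steps": int(pred.size)}


def evaluate_by_speed(
    pred: np.ndarray,
    truth: np.ndarray,
    speeds: np.ndarray,
    groups: list[float] | None = None,
) -> dict[float, dict[str, float]]:
    """Metrics per speed group; empty groups are omitted with a warning."""
    speeds = np.asarray(speeds, dtype=float)
    if groups is None:
        groups = sorted(np.unique(speeds).tolist())
    out = {}
    for g in groups:
        mask = np.isclose(speeds, g)
        if not mask.any():
            logger.warning("evaluate_by_speed: empty group %s omitted", g)
            continue
        out[float(g)] = evaluate(pred[mask], truth[mask])
    return out


@dataclass(frozen=True)
class LosoResult:
    selected_lambda: float
    #: mean over folds of per-fold validation metrics at the selected lambda
    validation: dict[str, float]
    #: per-lambda mean validation RMSE
    scores: dict[float, float] = field(default_factory=dict)


def loso_cv(
    train_table: pd.DataFrame,
    y_col: str,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> LosoResult:
    """Leave-one-subject-out selection of the regularization strength.

    For every lambda each training subject is held out in turn; the scaler
    and the fit use only the remaining subjects.  The validation score is
    the unweighted mean over folds of the per-fold RMSE, and ties are broken
    toward the larger lambda (stronger shrinkage).
    """
    subjects = sorted(train_table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO-CV needs at least 2 training subjects")
    grid = sorted(lambda_grid)
    fold_metrics: dict[float, list[dict[str, float]]] = {lam: [] for lam in grid}
    for held in subjects:
        fold_train = train_table[train_table["subject_id"] != held]
        fold_val = train_table[train_table["subject_id"] == held]
        (tr_s, va_s), _ = standardize(
            fold_train.drop(columns=[y_col]), fold_val.drop(columns=[y_col])
        )
        y_tr = fold_train[y_col].to_numpy(dtype=float)
        y_va = fold_val[y_col].to_numpy(dtype=float)
        cols = [c for c in tr_s.columns if c not in KEY_COLUMNS]
        Xtr = tr_s[cols].to_numpy(dtype=float)
        Xva = va_s[cols].to_numpy(dtype=float)
        # one warm-started coordinate-descent path per fold (strong lambda
        # first); identical objective/tolerance to fit_lasso
        model = Lasso(alpha=grid[-1], tol=1e-7, max_iter=100_000, warm_start=True)
        for lam in reversed(grid):
            model.set_params(alpha=lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xtr, y_tr)
            pred = model.intercept_ + Xva @ model.coef_
            fold_metrics[lam].append(evaluate(pred, y_va))
    scores = {
        lam: float(np.mean([m["rmse"] for m in ms]))
        for lam, ms in fold_metrics.items()
    }
    best = min(scores.values())
    selected = max(lam for lam, s in scores.items() if s <= best + 1e-12)
    val = {
        "rmse": scores[selected],
        "mape_percent": float(
            np.mean([m["mape_percent"] for m in fold_metrics[selected]])
        ),
        "r2": float(np.mean([m["r2"] for m in fold_metrics[selected]])),
        "n_steps": int(len(train_table)),
    }
    return LosoResult(selected_lambda=float(selected), validation=val, scores=scores)


def fit_final(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    y_col: str,
    lam: float,
) -> tuple[FitResult, np.ndarray, np.ndarray]:
    """Standardize on the full training table, fit at ``lam``, and predict
    both splits.  Returns (fit, train_pred, test_pred)."""
    (tr_s, te_s), scaler = standardize(
        train_table.drop(columns=[y_col]), test_table.drop(columns=[y_col])
    )
    fit = fit_lasso(tr_s, train_table[y_col].to_numpy(dtype=float), lam)
    fit = FitResult(
        intercept=fit.intercept,
        coefficients=fit.coefficients,
        selected_lambda=lam,
        scaler=scaler,
        train_subjects=tuple(sorted(train_table["subject_id"].unique())),
    )
    return fit, fit.predict(tr_s), fit.predict(te_s)
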