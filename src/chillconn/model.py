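"""Nested cross-validated LASSO decoding of chills-related targets.

The decoding model is L1-penalised linear regression on standardised
connectivity features:

    min_w  (1/2n) ||y - X w - b||^2 + lambda ||w||_1

Prediction accuracy is assessed by nested leave-one-out cross-validation:
the outer loop holds out one unit (participant or trial) at a time; for
each outer fold an inner leave-one-out over the remaining units scores
every penalty on the grid [0.001, 0.01, 0.1, 1, 10, 100, 1000] by the
Pearson correlation between inner held-out predictions and actuals, the
best penalty (ties toward stronger shrinkage) is refit on the full
training fold, and the held-out unit is predicted.  Accuracy is the
Pearson r between the n held-out predictions and the actual targets.

Standardisation statistics are learned inside each training fold only —
the held-out unit never influences scaling, penalty choice or weights.

Single fits use scikit-learn's coordinate descent; the cross-validation
loops use an exact LASSO-path (homotopy) kernel (see ``_solver``), which
gives identical minimisers at a fraction of the cost.  Agreement between
the two routes is asserted in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression

from . import _solver
from .exceptions import AlignmentError, InsufficientDataError
from .features import participant_features, participant_targets
from .simulate import CohortDataset

#: The penalty grid searched by the inner loop.
DEFAULT_LAMBDA_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass(frozen=True)
class LassoFit:
    """A fitted LASSO decoder with its training scaler.

    ``weights`` act on standardised features ((x - mean) / sd with the
    *training* population statistics); constant training features carry
    sd = 1 and weight 0.  ``edges`` optionally records feature
    identities for transfer across cohorts.
    """

    weights: np.ndarray
    intercept: float
    lam: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    edges: tuple | None = None
    lambda_grid: tuple | None = None

    def __post_init__(self):
        for name in ("weights", "scaler_mean", "scaler_sd"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")
        if np.any(self.scaler_sd <= 0):
            raise ValueError("scaler sd must be positive")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X - self.scaler_mean) / self.scaler_sd
        return self.intercept + Xs @ self.weights

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.weights)


@dataclass(frozen=True)
class CvResult:
    """Held-out predictions of a nested leave-one-out run."""

    unit_ids: tuple
    y_actual: np.ndarray
    y_pred: np.ndarray
    fold_lambdas: np.ndarray
    accuracy_r: float
    n_units: int
    degenerate: bool = False


def _validate_xy(X, y, min_units=2):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (units, features) aligned with y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if X.shape[0] < min_units:
        raise InsufficientDataError(f"need >= {min_units} units, got {X.shape[0]}")
    return X, y


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float,
              tol: float = 1e-8, max_iter: int = 100000,
              edges: Sequence[tuple] | None = None) -> LassoFit:
    """One LASSO fit at a fixed penalty (coordinate descent).

    ``lam = 0`` falls back to ordinary least squares.
    """
    X, y = _validate_xy(X, y)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd_safe
    Xs[:, sd == 0] = 0.0
    if lam == 0:
        ols = LinearRegression().fit(Xs, y)
        w, b = ols.coef_, float(ols.intercept_)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = Lasso(alpha=lam, tol=tol, max_iter=max_iter).fit(Xs, y)
        w, b = est.coef_, float(est.intercept_)
    return LassoFit(weights=w, intercept=b, lam=float(lam),
                    scaler_mean=mean, scaler_sd=sd_safe,
                    edges=tuple(tuple(e) for e in edges) if edges else None)


def _accuracy(y_pred, y):
    r = _solver.pearson(np.asarray(y_pred, float), np.asarray(y, float))
    return float(r), bool(np.isnan(r))


def nested_loocv(X: np.ndarray, y: np.ndarray,
                 lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                 unit_ids: Sequence | None = None) -> CvResult:
    """Nested leave-one-out CV (participants as units)."""
    X, y = _validate_xy(X, y, min_units=4)
    grid = np.asarray(sorted(lambda_grid), dtype=float)
    y_pred, fold_lams = _solver.nested_loo(
        np.ascontiguousarray(X), np.ascontiguousarray(y), grid)
    r, degenerate = _accuracy(y_pred, y)
    if degenerate:
        warnings.warn("constant held-out predictions; accuracy undefined",
                      stacklevel=2)
    ids = tuple(unit_ids) if unit_ids is not None else tuple(range(X.shape[0]))
    return CvResult(unit_ids=ids, y_actual=y, y_pred=y_pred,
                    fold_lambdas=fold_lams,
                    accuracy_r=r if not degenerate else float("nan"),
                    n_units=X.shape[0], degenerate=degenerate)


def nested_lotocv(X_trials: np.ndarray, y_trials: np.ndarray,
                  lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                  unit_ids: Sequence | None = None) -> CvResult:
    """Nested leave-one-trial-out CV (identical machinery, trial units)."""
    return nested_loocv(X_trials, y_trials, lambda_grid=lambda_grid,
                        unit_ids=unit_ids)


def cv_accuracy(X: np.ndarray, y: np.ndarray,
                lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID) -> float:
    """Accuracy of one nested leave-one-out run (permutation statistic)."""
    return nested_loocv(X, y, lambda_grid=lambda_grid).accuracy_r


def trial_outlier_filter(y_trials: np.ndarray, sd: float = 3.0) -> np.ndarray:
    """Keep-mask excluding trials *above* mean + ``sd``·SD (one-sided)."""
    y = np.asarray(y_trials, dtype=float)
    if y.size < 2 or y.std(ddof=1) == 0:
        return np.ones(y.size, dtype=bool)
    return y <= y.mean() + sd * y.std(ddof=1)


def fit_transfer_model(X: np.ndarray, y: np.ndarray,
                       lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                       edges: Sequence[tuple] | None = None) -> LassoFit:
    """The single exportable decoder: penalty by full leave-one-out, then
    one fit on *all* units.

    This is the weight vector (plus scaler) that crosses cohorts via
    :func:`transfer_predict`.
    """
    X, y = _validate_xy(X, y, min_units=3)
    grid = np.asarray(sorted(lambda_grid), dtype=float)
    preds = _solver.inner_loo_predictions(
        np.ascontiguousarray(X), np.ascontiguousarray(y), grid)
    li = _solver.select_lambda(preds, y, grid)
    lam = float(grid[li])
    w, mu, sd, b = _solver.fit_at_lambda(
        np.ascontiguousarray(X), np.ascontiguousarray(y), lam)
    return LassoFit(weights=w, intercept=float(b), lam=lam, scaler_mean=mu,
                    scaler_sd=sd,
                    edges=tuple(tuple(e) for e in edges) if edges else None,
                    lambda_grid=tuple(grid))


def transfer_predict(model: LassoFit, X_new: np.ndarray,
                     edges_new: Sequence[tuple] | None = None) -> np.ndarray:
    """Apply a frozen decoder to a new cohort's features.

    If both the model and the call carry edge identities, columns of
    ``X_new`` are aligned to the training edge order by identity; any
    mismatch raises :class:`AlignmentError` naming the offending edges.
    """
    X_new = np.asarray(X_new, dtype=float)
    if model.edges is not None and edges_new is not None:
        new_pos = {tuple(e): i for i, e in enumerate(edges_new)}
        missing = [e for e in model.edges if e not in new_pos]
        extra = [tuple(e) for e in edges_new if tuple(e) not in set(model.edges)]
        if missing or extra:
            raise AlignmentError(
                f"edge sets differ; missing from new data: {missing[:5]}, "
                f"unexpected: {extra[:5]}")
        order = [new_pos[e] for e in model.edges]
        X_new = X_new[:, order]
    if X_new.shape[1] != model.weights.size:
        raise AlignmentError(
            f"feature count {X_new.shape[1]} != model {model.weights.size}")
    return model.predict(X_new)


def window_sweep(
    dataset: CohortDataset,
    durations: Sequence[float] | None = None,
    anchor: str = "end",
    mode: str = "cumulative",
    width: float = 26.0,
    step: float = 2.0,
    networks: Sequence[str] = ("auditory", "reward"),
    level: str = "participant",
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    shrinkage: str | float = "auto",
) -> list:
    """Re-run feature extraction + nested CV over rest-window variants.

    ``mode="cumulative"``: one window per duration in ``durations``
    (default 20..40 s in 2-s steps), anchored at the epoch end
    (``anchor="end"``, immediately before the music) or start.
    ``mode="sliding"``: successive ``width``-s windows advanced by
    ``step`` s across the rest epoch.

    Returns a list of dicts with window, accuracy_r, p (correlation
    test) per window.
    """
    from .features import trial_features, trial_targets  # local: avoid cycle
    from .stats import pearson_r_p

    rest_dur = dataset.config.rest_duration
    if mode == "cumulative":
        if durations is None:
            durations = np.arange(20.0, rest_dur + 1e-9, 2.0)
        windows = []
        for d in durations:
            if d > rest_dur + 1e-9:
                raise ValueError(f"window duration {d} exceeds rest epoch")
            windows.append((rest_dur - d, rest_dur) if anchor == "end"
                           else (0.0, d))
    elif mode == "sliding":
        if width > rest_dur + 1e-9:
            raise ValueError("sliding width exceeds rest epoch")
        windows = []
        s = 0.0
        while s + width <= rest_dur + 1e-9:
            windows.append((s, s + width))
            s += step
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")
    out = []
    for win in windows:
        if level == "participant":
            pids, X, _ = participant_features(dataset, networks=networks,
                                              window=win, shrinkage=shrinkage)
            _, y = participant_targets(dataset)
            cv = nested_loocv(X, y, lambda_grid=lambda_grid, unit_ids=pids)
        else:
            ids, X, _ = trial_features(dataset, variant="preceding",
                                       networks=networks, window=win,
                                       shrinkage=shrinkage)
            ids_y, y = trial_targets(dataset)
            assert ids == ids_y
            cv = nested_lotocv(X, y, lambda_grid=lambda_grid, unit_ids=ids)
        stat = pearson_r_p(cv.y_pred, cv.y_actual, sided="one")
        out.append({"window": win, "duration": win[1] - win[0],
                    "accuracy_r": cv.accuracy_r, "p": stat.p, "cv": cv})
    return out


def learning_curve(
    X: np.ndarray,
    y: np.ndarray,
    fractions: Sequence[float] = (0.3, 0.5, 0.7, 1.0),
    reps: int = 10,
    seed: int = 0,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> list:
    """Nested-CV accuracy as a function of sample size.

    For each fraction, ``reps`` random unit subsets are drawn (fraction 1
    is the full sample, run once) and the nested leave-one-out accuracy is
    recorded; the curve should flatten once the sample supports the model.
    """
    X, y = _validate_xy(X, y, min_units=4)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    out = []
    for frac in fractions:
        m = int(round(frac * n))
        if m < 4:
            raise ValueError(f"fraction {frac} leaves fewer than 4 units")
        n_draws = 1 if m >= n else reps
        accs = []
        for _ in range(n_draws):
            idx = (np.arange(n) if m >= n
                   else np.sort(rng.choice(n, size=m, replace=False)))
            accs.append(nested_loocv(X[idx], y[idx],
                                     lambda_grid=lambda_grid).accuracy_r)
        accs = np.asarray(accs, dtype=float)
        out.append({"fraction": float(frac), "n_units": m,
                    "mean_accuracy": float(np.nanmean(accs)),
                    "sd_accuracy": float(np.nanstd(accs)),
                    "accuracies": accs})
    return out
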