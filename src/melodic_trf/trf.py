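"""Forward temporal response function (TRF) estimation.

A TRF is a per-channel linear filter ``w(tau, n)`` mapping lagged stimulus
features to the neural response,

    r(t, n) = sum_f sum_tau w_f(tau, n) s_f(t - tau) + eps(t, n),

estimated by ridge regression on a lagged design matrix,

    w = (S'S + lambda M)^-1 S' r,    M = identity (intercept unpenalized).

Regularization strength is selected by nested leave-one-out cross-validation
over trials: each trial is held out once (outer fold); the remaining trials
form an inner leave-one-out loop that scores every lambda on the grid by
channel-mean prediction correlation; the best lambda (ties broken toward the
smaller value) is then used to refit on all training trials and evaluate on
the held-out trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "LagWindow",
    "LaggedDesign",
    "TRFModel",
    "AccuracyResult",
    "DEFAULT_LAMBDA_GRID",
    "lag_design",
    "ridge_fit",
    "predict",
    "reconstruction_accuracy",
    "nested_cv",
]

#: 13 powers of ten spanning the printed regularization range 1e-6 .. 1e6.
DEFAULT_LAMBDA_GRID: np.ndarray = 10.0 ** np.arange(-6, 7)


@dataclass(frozen=True)
class LagWindow:
    """Range of stimulus-response lags, in ms, at a given sampling rate.

    Positive lags mean the response follows the stimulus; negative lags
    capture anticipatory (pre-onset) response components.
    """

    tmin_ms: float
    tmax_ms: float
    fs: float

    def __post_init__(self) -> None:
        if not self.tmin_ms < self.tmax_ms:
            raise ValueError("LagWindow requires tmin_ms < tmax_ms")
        if self.fs <= 0:
            raise ValueError("LagWindow requires fs > 0")

    @property
    def lags(self) -> np.ndarray:
        """Integer sample lags, inclusive on both ends."""
        lo = int(np.rint(self.tmin_ms * self.fs / 1000.0))
        hi = int(np.rint(self.tmax_ms * self.fs / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def times_ms(self) -> np.ndarray:
        """Lag axis in milliseconds."""
        return self.lags * 1000.0 / self.fs

    @property
    def n_lags(self) -> int:
        return self.lags.size


@dataclass
class LaggedDesign:
    """Time x (n_lags * n_features + 1) design matrix with an intercept.

    Column ``feature_index * n_lags + lag_index`` holds feature values
    delayed by ``window.lags[lag_index]`` samples; the final column is the
    intercept (all ones).
    """

    matrix: np.ndarray
    window: LagWindow
    feature_names: tuple[str, ...]

    @property
    def n_lags(self) -> int:
        return self.window.n_lags

    def column(self, feature: str, lag: int) -> int:
        """Flat column index for (feature name, integer sample lag)."""
        f = self.feature_names.index(feature)
        lag_idx = int(np.flatnonzero(self.window.lags == lag)[0])
        return f * self.n_lags + lag_idx


@dataclass
class TRFModel:
    """Fitted TRF: weights are (n_channels, n_lags, n_features)."""

    weights: np.ndarray
    intercept: np.ndarray
    lam: float
    window: LagWindow
    feature_names: tuple[str, ...]

    @property
    def times_ms(self) -> np.ndarray:
        return self.window.times_ms

    def kernel(self, feature: str, channel: int | None = None) -> np.ndarray:
        """Weight curve over the lag axis for one feature.

        With ``channel=None`` the channel-average is returned.
        """
        f = self.feature_names.index(feature)
        if channel is None:
            return self.weights[:, :, f].mean(axis=0)
        return self.weights[channel, :, f]


@dataclass
class AccuracyResult:
    """Per-fold, per-channel reconstruction accuracy (Pearson r)."""

    fold_r: np.ndarray  # (n_folds, n_channels)
    lambdas: np.ndarray  # selected lambda per fold
    subject: str | None = None
    band: str | None = None
    model: str | None = None

    @property
    def channel_mean(self) -> np.ndarray:
        """Channel-mean r per fold (NaN channels excluded)."""
        return np.nanmean(self.fold_r, axis=1)

    @property
    def mean_r(self) -> float:
        """Grand mean: fold mean of channel means."""
        return float(self.channel_mean.mean())

    @property
    def channel_r(self) -> np.ndarray:
        """Fold-mean r per channel."""
        return np.nanmean(self.fold_r, axis=0)


def lag_design(
    features: np.ndarray,
    window: LagWindow,
    feature_names: Sequence[str] | None = None,
) -> LaggedDesign:
    """Expand a (time x feature) matrix into a lagged design matrix.

    Out-of-range samples are zero-padded, so ``design @ kernel`` equals a
    zero-padded discrete convolution of each feature with its kernel.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.size > 1 and np.ndim(features) == 1:
        X = X.T
    n, n_feat = X.shape
    lags = window.lags
    if lags.size == 0:
        raise ValueError("empty lag window")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(n_feat))
    feature_names = tuple(feature_names)
    if len(feature_names) != n_feat:
        raise ValueError("feature_names length does not match feature count")

    L = lags.size
    out = np.zeros((n, n_feat * L + 1))
    for f in range(n_feat):
        for j, tau in enumerate(lags):
            col = f * L + j
            if tau >= 0:
                if tau < n:
                    out[tau:, col] = X[: n - tau, f]
            else:
                if -tau < n:
                    out[: n + tau, col] = X[-tau:, f]
    out[:, -1] = 1.0
    return LaggedDesign(matrix=out, window=window, feature_names=feature_names)


def _lambda_scale(gram: np.ndarray) -> float:
    """Dimensionless-lambda scale: mean diagonal of the penalized block."""
    p = gram.shape[0] - 1  # excludes the intercept column
    if p == 0:
        return 1.0
    scale = float(np.trace(gram[:p, :p]) / p)
    return scale if scale > 0 else 1.0


def _solve_ridge(
    gram: np.ndarray,
    xty: np.ndarray,
    lam: float,
    normalize_lambda: bool = True,
) -> np.ndarray:
    """Solve (S'S + lam*D) w = S'r with D = identity except the intercept."""
    p = gram.shape[0]
    lam_eff = lam * (_lambda_scale(gram) if normalize_lambda else 1.0)
    A = gram.copy()
    idx = np.arange(p - 1)
    A[idx, idx] += lam_eff
    try:
        c, low = linalg.cho_factor(A, check_finite=False)
        return linalg.cho_solve((c, low), xty, check_finite=False)
    except linalg.LinAlgError:
        # Singular at lambda ~ 0 with collinear columns: minimum-norm solution.
        return np.linalg.lstsq(A, xty, rcond=None)[0]


def ridge_fit(
    design: LaggedDesign,
    response: np.ndarray,
    lam: float,
    normalize_lambda: bool = True,
) -> TRFModel:
    """Closed-form ridge solution for all channels at once.

    ``response`` is (n_channels x time). The intercept column is excluded
    from the penalty. By default ``lam`` is scaled by trace(S'S)/p of the
    penalized block so the printed grid is dimensionless across feature
    scalings; pass ``normalize_lambda=False`` for raw lambda.
    """
    R = np.atleast_2d(np.asarray(response, dtype=float))
    S = design.matrix
    if S.shape[0] != R.shape[1]:
        raise ValueError(
            f"design rows ({S.shape[0]}) != response samples ({R.shape[1]})"
        )
    gram = S.T @ S
    xty = S.T @ R.T
    w = _solve_ridge(gram, xty, lam, normalize_lambda)
    return _weights_to_model(w, design, lam)


def _weights_to_model(w: np.ndarray, design: LaggedDesign, lam: float) -> TRFModel:
    n_feat = len(design.feature_names)
    L = design.n_lags
    coeff = w[:-1, :]  # (n_feat*L, n_channels)
    intercept = w[-1, :]
    weights = coeff.T.reshape(-1, n_feat, L).transpose(0, 2, 1)
    return TRFModel(
        weights=weights,
        intercept=intercept,
        lam=lam,
        window=design.window,
        feature_names=design.feature_names,
    )


def _model_to_flat(model: TRFModel) -> np.ndarray:
    w = model.weights.transpose(0, 2, 1).reshape(model.weights.shape[0], -1)
    return np.concatenate([w.T, model.intercept[None, :]], axis=0)


def predict(model: TRFModel, features: np.ndarray,
            feature_names: Sequence[str] | None = None) -> np.ndarray:
    """Predicted EEG (n_channels x time) from a fitted TRF."""
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise ValueError("feature names do not match the fitted model")
    design = lag_design(features, model.window, model.feature_names)
    return (design.matrix @ _model_to_flat(model)).T


def reconstruction_accuracy(
    pred: np.ndarray,
    actual: np.ndarray,
    exclude_edges_s: float = 0.0,
    fs: float | None = None,
) -> np.ndarray:
    """Per-channel Pearson correlation between predicted and actual EEG.

    ``exclude_edges_s`` drops that many seconds from both ends before the
    correlation (filter/convolution edge artifacts); requires ``fs``.
    Zero-variance channels yield NaN.
    """
    P = np.atleast_2d(np.asarray(pred, dtype=float))
    A = np.atleast_2d(np.asarray(actual, dtype=float))
    if P.shape != A.shape:
        raise ValueError("pred and actual must have equal shapes")
    if exclude_edges_s > 0:
        if fs is None:
            raise ValueError("fs is required when excluding edges")
        k = int(round(exclude_edges_s * fs))
        if 2 * k >= P.shape[1]:
            raise ValueError("edge exclusion longer than the signal")
        if k:
            P, A = P[:, k:-k], A[:, k:-k]
    P = P - P.mean(axis=1, keepdims=True)
    A = A - A.mean(axis=1, keepdims=True)
    num = (P * A).sum(axis=1)
    den = np.sqrt((P**2).sum(axis=1) * (A**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


@dataclass
class _TrialCache:
    design: np.ndarray
    gram: np.ndarray
    xty: np.ndarray
    response: np.ndarray


def _prepare_trials(trials, window: LagWindow, feature_names):
    cache = []
    for X, R in trials:
        d = lag_design(X, window, feature_names)
        R = np.atleast_2d(np.asarray(R, dtype=float))
        if d.matrix.shape[0] != R.shape[1]:
            raise ValueError("feature and response lengths differ in a trial")
        cache.append(
            _TrialCache(
                design=d.matrix,
                gram=d.matrix.T @ d.matrix,
                xty=d.matrix.T @ R.T,
                response=R,
            )
        )
    return cache


def nested_cv(
    trials: Sequence[tuple[np.ndarray, np.ndarray]],
    window: LagWindow,
    lam_grid: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
    exclude_edges_s: float = 1.0,
    normalize_lambda: bool = True,
) -> tuple[list[TRFModel], AccuracyResult]:
    """Nested leave-one-out cross-validation over trials.

    Returns one fitted :class:`TRFModel` per outer fold (trained on all
    training trials at that fold's optimal lambda) and an
    :class:`AccuracyResult` with one per-channel r per fold, measured on the
    held-out trial.
    """
    if lam_grid is None:
        lam_grid = DEFAULT_LAMBDA_GRID
    lam_grid = np.sort(np.asarray(lam_grid, dtype=float))
    n_trials = len(trials)
    if n_trials < 3:
        raise ValueError("nested_cv requires at least 3 trials")
    X0 = np.atleast_2d(np.asarray(trials[0][0], dtype=float))
    if X0.shape[0] == 1 and np.ndim(trials[0][0]) == 1:
        X0 = X0.T
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X0.shape[1]))
    feature_names = tuple(feature_names)

    cache = _prepare_trials(trials, window, feature_names)
    gram_all = np.sum([c.gram for c in cache], axis=0)
    xty_all = np.sum([c.xty for c in cache], axis=0)

    models: list[TRFModel] = []
    fold_r = np.zeros((n_trials, cache[0].response.shape[0]))
    chosen = np.zeros(n_trials)

    for k in range(n_trials):
        train = [i for i in range(n_trials) if i != k]
        if len(train) < 2:
            raise ValueError("inner loop requires at least 2 training trials")
        # Inner leave-one-out: score every lambda by channel-mean r averaged
        # over inner validation trials.
        scores = np.zeros(lam_grid.size)
        for j in train:
            inner = gram_all - cache[k].gram - cache[j].gram
            inner_xty = xty_all - cache[k].xty - cache[j].xty
            for li, lam in enumerate(lam_grid):
                w = _solve_ridge(inner, inner_xty, lam, normalize_lambda)
                pred = (cache[j].design @ w).T
                r = reconstruction_accuracy(
                    pred, cache[j].response, exclude_edges_s, window.fs
                )
                scores[li] += np.nanmean(r)
        scores /= len(train)
        best = int(np.argmax(scores))  # first max -> smaller lambda on ties
        lam = float(lam_grid[best])
        chosen[k] = lam

        outer_gram = gram_all - cache[k].gram
        outer_xty = xty_all - cache[k].xty
        w = _solve_ridge(outer_gram, outer_xty, lam, normalize_lambda)
        dummy = LaggedDesign(
            matrix=cache[k].design, window=window, feature_names=feature_names
        )
        model = _weights_to_model(w, dummy, lam)
        models.append(model)
        pred = (cache[k].design @ w).T
        fold_r[k] = reconstruction_accuracy(
            pred, cache[k].response, exclude_edges_s, window.fs
        )

    return models, AccuracyResult(fold_r=fold_r, lambdas=chosen)
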