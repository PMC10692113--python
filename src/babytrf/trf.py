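"""Forward temporal response function (TRF) estimation.

A TRF is the kernel of a lagged linear model mapping stimulus feature
streams to each EEG channel:

    y_c(t) = sum_f sum_tau w_c(f, tau) x_f(t - tau) + b_c + noise

Weights are estimated by Tikhonov-regularised least squares
(``w = (X'X + lambda*M)^-1 X'y`` with M an identity or second-derivative
penalty), the regularisation parameter is tuned by an inner leave-one-trial-
out search over a logarithmic grid, and model quality is the Pearson
correlation between the cross-validated prediction of each channel and a
shared ground-truth EEG trace.  The FS-S prediction gain is the increase in
that correlation when phonetic features are added to an acoustic-only model.

Features and EEG are z-scored with training-fold statistics only; the inner
machinery caches per-trial cross-products so that fold statistics, and the
whole lambda grid (via one eigendecomposition per training fold), are cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as sla

from .config import LAMBDA_GRID, DataError

__all__ = [
    "LagWindow",
    "TRFModel",
    "PredictionScore",
    "GainScore",
    "TRFTrial",
    "lag_design_matrix",
    "ridge_solve",
    "tune_lambda",
    "cross_validated_fit_predict",
    "prediction_correlation",
    "prediction_gain",
    "fit_trf",
    "precompute_trial",
]


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class LagWindow:
    """Stimulus-to-EEG lag window in seconds at a given sampling rate.

    Lag indices run from round(tmin*fs) to round(tmax*fs) inclusive
    (round half away from zero); tmin may be negative to absorb
    regression edge artefacts.
    """

    tmin: float
    tmax: float
    fs: float

    def __post_init__(self) -> None:
        if not self.tmin < self.tmax:
            raise ValueError(f"need tmin < tmax, got ({self.tmin}, {self.tmax})")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(_round_half_away(self.tmin * self.fs),
                         _round_half_away(self.tmax * self.fs) + 1)

    @property
    def n_lags(self) -> int:
        return len(self.lags)


@dataclass
class TRFModel:
    """Fitted TRF: weights are feature x lag x channel, in input units."""

    weights: np.ndarray
    bias: np.ndarray
    lam: float
    window: LagWindow
    feature_names: list[str] = field(default_factory=list)
    penalty: str = "identity"


@dataclass
class PredictionScore:
    """Cross-validated prediction correlations against the ground-truth EEG."""

    r_per_channel: np.ndarray
    model: str = ""
    band: str = ""
    participant: str = ""
    session: str = ""
    lambdas: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_per_channel = np.asarray(self.r_per_channel, dtype=float)
        valid = self.r_per_channel[np.isfinite(self.r_per_channel)]
        if valid.size and (np.abs(valid) > 1 + 1e-9).any():
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.r_per_channel))


@dataclass
class GainScore:
    """FS-S prediction gain: r(acoustic-phonetic) - r(acoustic-only)."""

    gain: float
    participant: str = ""
    session: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        if not -2.0 <= self.gain <= 2.0:
            raise ValueError("gain out of the feasible [-2, 2] range")


@dataclass
class TRFTrial:
    """One trial's regressor matrix (time x features) and EEG (time x channels)."""

    features: np.ndarray
    eeg: np.ndarray
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features[:, None]
        self.eeg = np.asarray(self.eeg, dtype=float)
        if self.eeg.ndim == 1:
            self.eeg = self.eeg[:, None]
        if self.features.shape[0] != self.eeg.shape[0]:
            raise DataError("features and EEG must share the time axis")


# ---------------------------------------------------------------------------
# design matrix and the ridge solver
# ---------------------------------------------------------------------------

def lag_design_matrix(features: np.ndarray, window: LagWindow) -> np.ndarray:
    """Time-lagged design matrix: one column block per feature per lag.

    Column order is feature-major (``f * L + j`` for lag index j), and
    out-of-range samples are zero-padded.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if features.size == 0:
        raise ValueError("empty feature matrix")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    T, F = features.shape
    lags = window.lags
    L = len(lags)
    X = np.zeros((T, F * L))
    cols = np.arange(F) * L
    for j, lag in enumerate(lags):
        if lag >= 0:
            X[lag:, cols + j] = features[: T - lag if lag else T]
        else:
            X[:lag, cols + j] = features[-lag:]
    return X


def _penalty_matrix(p: int, kind: str, n_lags: int | None) -> np.ndarray:
    if kind == "identity":
        return np.eye(p)
    if kind == "derivative":
        if n_lags is None or p % n_lags:
            raise ValueError("derivative penalty needs p divisible by n_lags")
        L = n_lags
        D = np.diff(np.eye(L), n=2, axis=0)          # (L-2, L) second difference
        block = D.T @ D
        M = np.zeros((p, p))
        for f in range(p // L):
            M[f * L:(f + 1) * L, f * L:(f + 1) * L] = block
        return M
    raise ValueError(f"unknown penalty kind {kind!r}")


def ridge_solve(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    penalty: str = "identity",
    n_lags: int | None = None,
    fit_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``(X'X + lam*M) w = X'Y`` with an unpenalised intercept.

    Returns flat weights (p, channels) and the bias per channel.  ``lam = 0``
    requires a well-conditioned system and raises otherwise, advising a
    positive regularisation parameter.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the row (time) dimension")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = X.shape[1]
    M = _penalty_matrix(p, penalty, n_lags)
    if fit_intercept:
        Xa = np.hstack([X, np.ones((X.shape[0], 1))])
        Ma = np.zeros((p + 1, p + 1))
        Ma[:p, :p] = M
    else:
        Xa, Ma = X, M
    A = Xa.T @ Xa + lam * Ma
    b = Xa.T @ Y
    try:
        cf = sla.cho_factor(A)
    except np.linalg.LinAlgError:
        raise ValueError(
            "normal equations are singular; use lambda > 0 (Tikhonov regularisation)"
        )
    except sla.LinAlgError:
        raise ValueError(
            "normal equations are singular; use lambda > 0 (Tikhonov regularisation)"
        )
    W = sla.cho_solve(cf, b)
    if fit_intercept:
        return W[:p], W[p]
    return W, np.zeros(Y.shape[1])


# ---------------------------------------------------------------------------
# per-trial sufficient statistics (internal fast path)
# ---------------------------------------------------------------------------

class _TrialCache:
    """Lagged design matrix plus cross-products for one trial."""

    __slots__ = ("X", "Y", "G", "C", "sx", "sy", "syy", "n", "trial_id")

    def __init__(self, X: np.ndarray, Y: np.ndarray, trial_id: str = "",
                 G: np.ndarray | None = None, sx: np.ndarray | None = None):
        self.X, self.Y, self.trial_id = X, Y, trial_id
        self.G = X.T @ X if G is None else G
        self.C = X.T @ Y
        self.sx = X.sum(axis=0) if sx is None else sx
        self.sy = Y.sum(axis=0)
        self.syy = (Y ** 2).sum(axis=0)
        self.n = X.shape[0]

    def subset(self, idx: np.ndarray) -> "_TrialCache":
        sub = object.__new__(_TrialCache)
        sub.X = self.X[:, idx]
        sub.Y = self.Y
        sub.trial_id = self.trial_id
        sub.G = self.G[np.ix_(idx, idx)]
        sub.C = self.C[idx]
        sub.sx = self.sx[idx]
        sub.sy = self.sy
        sub.syy = self.syy
        sub.n = self.n
        return sub


def precompute_trial(features: np.ndarray, eeg: np.ndarray,
                     window: LagWindow, trial_id: str = "") -> _TrialCache:
    """Build the cached lagged design matrix and cross-products for a trial."""
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim == 1:
        eeg = eeg[:, None]
    X = lag_design_matrix(features, window)
    if X.shape[0] != eeg.shape[0]:
        raise DataError("features and EEG must share the time axis")
    return _TrialCache(X, eeg, trial_id)


class _FoldSolver:
    """Training-fold statistics with z-scoring and fast multi-lambda solves."""

    def __init__(self, caches: Sequence[_TrialCache], penalty: str,
                 n_lags: int | None):
        n = sum(c.n for c in caches)
        sx = np.sum([c.sx for c in caches], axis=0)
        sy = np.sum([c.sy for c in caches], axis=0)
        G = np.sum([c.G for c in caches], axis=0)
        C = np.sum([c.C for c in caches], axis=0)
        syy = np.sum([c.syy for c in caches], axis=0)
        self.mx = sx / n
        self.my = sy / n
        Sxx = G - n * np.outer(self.mx, self.mx)
        Sxy = C - n * np.outer(self.mx, self.my)
        varx = np.maximum(np.diag(Sxx) / n, 0.0)
        vary = np.maximum(syy / n - self.my ** 2, 0.0)
        self.sigx = np.where(varx > 0, np.sqrt(varx), 1.0)
        self.sigy = np.where(vary > 0, np.sqrt(vary), 1.0)
        self.A = Sxx / np.outer(self.sigx, self.sigx)
        self.B = Sxy / np.outer(self.sigx, self.sigy)
        self.penalty = penalty
        self._eig = None
        self._M = None if penalty == "identity" else _penalty_matrix(
            self.A.shape[0], penalty, n_lags)

    def weights(self, lam: float) -> np.ndarray:
        """Standardised-space weights (p, channels) for one lambda."""
        if self.penalty == "identity":
            if self._eig is None:
                self._eig = np.linalg.eigh(self.A)
                self._VtB = self._eig[1].T @ self.B
            evals, V = self._eig
            return V @ (self._VtB / (np.maximum(evals, 0.0) + lam)[:, None])
        cf = sla.cho_factor(self.A + lam * self._M)
        return sla.cho_solve(cf, self.B)

    def predict(self, cache: _TrialCache, W: np.ndarray) -> np.ndarray:
        """Predicted EEG (time x channels) for a held-out trial, standardised."""
        Xs = (cache.X - self.mx) / self.sigx
        return Xs @ W


def _mean_channel_corr(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over channels of Pearson r between columns of pred and target."""
    pc = pred - pred.mean(axis=0)
    tc = target - target.mean(axis=0)
    num = (pc * tc).sum(axis=0)
    den = np.sqrt((pc ** 2).sum(axis=0) * (tc ** 2).sum(axis=0))
    ok = den > 0
    if not ok.any():
        return np.nan
    return float(np.mean(num[ok] / den[ok]))


def _as_caches(trials: Sequence, window: LagWindow) -> list[_TrialCache]:
    caches = []
    for i, t in enumerate(trials):
        if isinstance(t, _TrialCache):
            caches.append(t)
        elif isinstance(t, TRFTrial):
            caches.append(precompute_trial(t.features, t.eeg, window,
                                           t.trial_id or f"trial{i:02d}"))
        else:
            feats, eeg = t[0], t[1]
            tid = t[2] if len(t) > 2 else f"trial{i:02d}"
            caches.append(precompute_trial(feats, eeg, window, tid))
    return caches


# ---------------------------------------------------------------------------
# lambda tuning and cross-validation
# ---------------------------------------------------------------------------

def tune_lambda(
    trials: Sequence,
    window: LagWindow,
    grid: Sequence[float] = LAMBDA_GRID,
    penalty: str = "identity",
) -> float:
    """Pick the lambda maximising inner leave-one-trial-out prediction r.

    The score for each candidate is the prediction correlation with the
    held-out trial's own EEG, averaged over channels and inner folds.  Ties
    resolve to the smaller lambda (the grid is scanned in ascending order).
    """
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    caches = _as_caches(trials, window)
    if len(caches) < 2:
        if len(grid) == 1:
            return float(grid[0])
        raise ValueError("need >= 2 training trials for inner cross-validation")
    grid = sorted(float(g) for g in grid)
    scores = _inner_scores(caches, grid, penalty, window.n_lags)
    if np.isnan(scores).all():
        raise DataError("all inner cross-validation scores are NaN")
    return grid[int(np.nanargmax(scores))]


def _inner_scores(caches: Sequence[_TrialCache], grid: Sequence[float],
                  penalty: str, n_lags: int) -> np.ndarray:
    scores = np.zeros((len(caches), len(grid)))
    for j, held in enumerate(caches):
        train = [c for i, c in enumerate(caches) if i != j]
        solver = _FoldSolver(train, penalty, n_lags)
        for g, lam in enumerate(grid):
            pred = solver.predict(held, solver.weights(lam))
            scores[j, g] = _mean_channel_corr(pred, held.Y)
    return np.nanmean(scores, axis=0)


def cross_validated_fit_predict(
    trials: Sequence,
    ground_truth: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    window: LagWindow,
    grid: Sequence[float] = LAMBDA_GRID,
    penalty: str = "identity",
    model: str = "",
    band: str = "",
    participant: str = "",
    session: str = "",
) -> PredictionScore:
    """Leave-one-trial-out TRF evaluation against the ground-truth EEG.

    For each fold the regularisation parameter is tuned on the training
    trials (inner leave-one-out), the model is refit on all training trials,
    the held-out trial is predicted, and each predicted channel is
    correlated with the shared ground-truth trace for that trial.  Returns
    per-channel correlations averaged over folds.
    """
    caches = _as_caches(trials, window)
    if len(caches) < 2:
        raise ValueError("need >= 2 trials for leave-one-out cross-validation")
    grid = sorted(float(g) for g in grid)
    n_ch = caches[0].Y.shape[1]
    r_folds = np.zeros((len(caches), n_ch))
    lambdas: list[float] = []
    for k, held in enumerate(caches):
        train = [c for i, c in enumerate(caches) if i != k]
        if len(train) >= 2:
            scores = _inner_scores(train, grid, penalty, window.n_lags)
            if np.isnan(scores).all():
                raise DataError("all inner cross-validation scores are NaN")
            lam = grid[int(np.nanargmax(scores))]
        else:
            lam = grid[0] if len(grid) == 1 else grid[len(grid) // 2]
        solver = _FoldSolver(train, penalty, window.n_lags)
        pred = solver.predict(held, solver.weights(lam))
        truth = (ground_truth[held.trial_id]
                 if isinstance(ground_truth, Mapping) else ground_truth[k])
        r_folds[k] = prediction_correlation(pred.T, np.asarray(truth, dtype=float))
        lambdas.append(lam)
    return PredictionScore(
        r_per_channel=r_folds.mean(axis=0), model=model, band=band,
        participant=participant, session=session, lambdas=lambdas,
    )


def prediction_correlation(predicted: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pearson r of each predicted channel (channels x time) against one trace."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    truth = np.asarray(truth, dtype=float)
    if predicted.shape[1] != truth.shape[0]:
        raise DataError(
            f"prediction length {predicted.shape[1]} does not match "
            f"ground-truth length {truth.shape[0]}"
        )
    tc = truth - truth.mean()
    tnorm = np.sqrt((tc ** 2).sum())
    pc = predicted - predicted.mean(axis=1, keepdims=True)
    pnorm = np.sqrt((pc ** 2).sum(axis=1))
    if tnorm == 0 or (pnorm == 0).any():
        raise ValueError("zero-variance input to prediction correlation")
    return pc @ tc / (pnorm * tnorm)


def prediction_gain(full: PredictionScore, reduced: PredictionScore) -> GainScore:
    """FS-S gain: mean-over-channels r(full model) minus r(reduced model)."""
    for attr in ("participant", "session", "band"):
        if getattr(full, attr) != getattr(reduced, attr):
            raise DataError(
                f"mismatched {attr}: {getattr(full, attr)!r} vs "
                f"{getattr(reduced, attr)!r}"
            )
    if full.r_per_channel.shape != reduced.r_per_channel.shape:
        raise DataError("mismatched channel sets between models")
    return GainScore(gain=full.mean_r - reduced.mean_r,
                     participant=full.participant, session=full.session,
                     band=full.band)


# ---------------------------------------------------------------------------
# direct fitting (e.g. for weight inspection / parameter recovery)
# ---------------------------------------------------------------------------

def fit_trf(
    trials: Sequence,
    window: LagWindow,
    lam: float,
    penalty: str = "identity",
    feature_names: Sequence[str] | None = None,
) -> TRFModel:
    """Fit a single TRF on all supplied trials at a fixed lambda.

    Data are z-scored internally for numerical stability; the returned
    weights are converted back to input units and reshaped to
    feature x lag x channel.
    """
    caches = _as_caches(trials, window)
    solver = _FoldSolver(caches, penalty, window.n_lags)
    Ws = solver.weights(lam)                       # standardised space
    W = Ws * solver.sigy[None, :] / solver.sigx[:, None]
    bias = solver.my - solver.mx @ W
    L = window.n_lags
    n_feat = W.shape[0] // L
    return TRFModel(
        weights=W.reshape(n_feat, L, -1), bias=bias, lam=float(lam),
        window=window, penalty=penalty,
        feature_names=list(feature_names) if feature_names else [],
    )


def predict_trf(model: TRFModel, features: np.ndarray) -> np.ndarray:
    """Forward prediction (time x channels) from a fitted TRF."""
    X = lag_design_matrix(features, model.window)
    F, L, C = model.weights.shape
    return X @ model.weights.reshape(F * L, C) + model.bias
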