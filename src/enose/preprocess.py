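"""Per-session signal conditioning: smoothing, drift correction, rescaling.

The chain mirrors the edge inference pipeline of the device: a
Savitzky-Golay filter removes frame-to-frame noise, a linear baseline fit
over the leading air-only phase is extrapolated and subtracted to undo the
slow monotone drift of the nanotube resistances, and each odor-feature
column is centre-reduced so classifiers see signal shape rather than scale.

The three stages are scikit-learn transformers operating on one session
matrix of shape ``(T, n_features)`` (rows are time points), so they compose
in an ``sklearn.pipeline.Pipeline``.  The module-level functions
(:func:`smooth_signal`, :func:`estimate_drift`, ...) are thin 1-D wrappers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .frames import OdorSignal


@dataclass(frozen=True)
class SmootherConfig:
    """Savitzky-Golay parameters: odd window length (samples), poly degree."""

    window_length: int = 51
    poly_degree: int = 3

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.window_length % 2 == 0:
            raise ValueError(
                f"window_length must be odd and positive, got "
                f"{self.window_length}"
            )
        if not 0 <= self.poly_degree < self.window_length:
            raise ValueError(
                f"poly_degree must satisfy 0 <= degree < window "
                f"({self.poly_degree} vs {self.window_length})"
            )


@dataclass(frozen=True)
class DriftModel:
    """OLS line (slope per sample, intercept) fit to a leading baseline window."""

    slope: float
    intercept: float
    fit_window: int = 100

    def predict(self, t) -> np.ndarray:
        """Drift-line value at sample index/indices ``t``."""
        return self.intercept + self.slope * np.asarray(t, dtype=float)


class SavitzkyGolaySmoother(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing of each column of a session matrix.

    Each sample is replaced by the value, at its own position, of the
    least-squares polynomial of degree ``poly_degree`` fit over a centred
    window of ``window_length`` samples.  Edges use polynomial extension:
    the first/last window's polynomial is evaluated at the edge positions,
    so output length equals input length.

    Parameters
    ----------
    window_length : int, default 51
        Odd window size in samples.  A signal shorter than this cannot be
        smoothed — the streaming pipeline buffers 51 frames before its first
        prediction for exactly this reason.
    poly_degree : int, default 3
        Degree of the fitted polynomial; must be < ``window_length``.
    """

    def __init__(self, window_length: int = 51, poly_degree: int = 3):
        self.window_length = window_length
        self.poly_degree = poly_degree

    def fit(self, X, y=None):
        SmootherConfig(self.window_length, self.poly_degree)  # validate
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cfg = SmootherConfig(self.window_length, self.poly_degree)
        T = X.shape[0]
        if T < cfg.window_length:
            raise ValueError(
                f"signal length {T} < window {cfg.window_length}: buffer "
                f"more samples before smoothing (warm-up requires "
                f"{cfg.window_length} frames)"
            )
        return savgol_filter(
            X, cfg.window_length, cfg.poly_degree, axis=0, mode="interp"
        )


class DriftCorrector(TransformerMixin, BaseEstimator):
    """Linear baseline-drift removal per column of one session matrix.

    ``fit`` regresses the first ``fit_window`` samples of each column on
    their sample indices (the leading air-only phase); ``transform``
    subtracts the extrapolated line over the whole session and re-adds the
    column's first value, so the corrected signal keeps its physical level:

        corrected[t] = x[t] - (intercept + slope * t) + x[0]

    Fit and transform are meant to run on the same (smoothed) session.
    """

    def __init__(self, fit_window: int = 100):
        self.fit_window = fit_window

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        w = self.fit_window
        if w < 2:
            raise ValueError("fit_window must be >= 2")
        if w > X.shape[0]:
            raise ValueError(
                f"fit_window {w} exceeds signal length {X.shape[0]}"
            )
        t = np.arange(w, dtype=float)
        # OLS per column over the leading window
        coef = np.polyfit(t, X[:w], deg=1)
        self.slopes_ = coef[0]
        self.intercepts_ = coef[1]
        self.first_values_ = X[0].copy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        t = np.arange(X.shape[0], dtype=float)[:, None]
        drift = self.intercepts_ + self.slopes_ * t
        out = X - drift + self.first_values_
        return out[:, 0] if squeeze else out

    def drift_models(self) -> list:
        """Per-column :class:`DriftModel` objects from the last fit."""
        return [
            DriftModel(float(s), float(b), self.fit_window)
            for s, b in zip(np.atleast_1d(self.slopes_),
                            np.atleast_1d(self.intercepts_))
        ]


class SessionNormalizer(TransformerMixin, BaseEstimator):
    """Centre-reduce each column over the full session (population std).

    Equivalent to StandardScaler applied to one session: every column is
    mapped to mean 0 / std 1 over all T samples (all three phases).  A
    zero-variance column raises — a flat chemiresistor trace indicates a
    dead channel, which must not silently become zeros.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to rescale")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)  # ddof=0
        # dead-channel check is relative: smoothing a flat trace leaves
        # O(eps) float residue, still a constant signal for our purposes
        tiny = 1e-12 * np.maximum(1.0, np.abs(self.mean_))
        zero = np.flatnonzero(self.scale_ <= tiny)
        if zero.size:
            raise ValueError(
                f"constant signal cannot be rescaled (column {int(zero[0])})"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        out = (X - self.mean_) / self.scale_
        return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# functional wrappers

def smooth_signal(column, cfg: SmootherConfig = SmootherConfig()) -> np.ndarray:
    """Savitzky-Golay filtrate of a 1-D series (length preserved)."""
    col = np.asarray(column, dtype=float)
    return SavitzkyGolaySmoother(cfg.window_length, cfg.poly_degree).fit(
        col[:, None]
    ).transform(col[:, None])[:, 0]


def estimate_drift(column, fit_window: int = 100) -> DriftModel:
    """OLS baseline line over samples ``0..fit_window-1`` of a 1-D series."""
    dc = DriftCorrector(fit_window).fit(np.asarray(column, dtype=float))
    return dc.drift_models()[0]


def correct_drift(column, drift: DriftModel) -> np.ndarray:
    """Subtract the extrapolated drift line, re-adding the first value."""
    col = np.asarray(column, dtype=float)
    t = np.arange(col.shape[0])
    return col - drift.predict(t) + col[0]


def normalize_signal(column) -> np.ndarray:
    """Centre-reduce a 1-D series to mean 0 / population-std 1."""
    col = np.asarray(column, dtype=float)
    return SessionNormalizer().fit(col).transform(col)


def preprocess_session(
    signal: OdorSignal,
    cfg: SmootherConfig = SmootherConfig(),
    fit_window: int = 100,
    normalize: bool = True,
) -> OdorSignal:
    """Smooth, drift-correct and (optionally) normalize all 15 columns.

    The drift fit window must lie inside phase A so that exposure samples
    never leak into the baseline estimate.  The returned session carries the
    per-column drift models and, when normalized, also the pre-normalization
    corrected matrix (``corrected_values``) from which physically scaled
    indicators are computed.
    """
    if fit_window > signal.phase_bounds[0]:
        raise ValueError(
            f"drift fit_window {fit_window} exceeds phase A length "
            f"{signal.phase_bounds[0]}: exposure samples would leak into "
            f"the baseline fit"
        )
    sm = SavitzkyGolaySmoother(cfg.window_length, cfg.poly_degree)
    try:
        smoothed = sm.fit(signal.values).transform(signal.values)
    except ValueError as exc:
        raise ValueError(f"smoothing failed: {exc}") from exc
    dc = DriftCorrector(fit_window).fit(smoothed)
    corrected = dc.transform(smoothed)
    if not normalize:
        return signal.with_values(
            corrected, drift_models=dc.drift_models(), corrected_values=None
        )
    try:
        norm = SessionNormalizer().fit(corrected).transform(corrected)
    except ValueError as exc:
        raise ValueError(f"normalization failed: {exc}") from exc
    return signal.with_values(
        norm, drift_models=dc.drift_models(), corrected_values=corrected
    )


def tune_smoother(
    training_columns: list,
    references: list | None = None,
    window_grid=range(1, 101),
    degree_grid=range(1, 11),
    time_budget_ms: float = 100.0,
) -> SmootherConfig:
    """Grid-search Savitzky-Golay parameters under a latency budget.

    Scores each (window, degree) candidate by the mean squared error between
    the smoothed training columns and ``references`` — held-out repeat
    measurements of the same signals (when omitted, the columns score
    against themselves, which favours light smoothing and is mainly useful
    for latency-only tuning).  Candidates with even windows, degree >=
    window, or window > signal length are skipped; candidates whose measured
    smoothing cost per signal exceeds ``time_budget_ms`` are infeasible.
    """
    if not training_columns:
        raise ValueError("need at least one training column")
    cols = [np.asarray(c, dtype=float) for c in training_columns]
    refs = cols if references is None else [
        np.asarray(r, dtype=float) for r in references
    ]
    if len(refs) != len(cols):
        raise ValueError("references must pair one-to-one with columns")
    min_len = min(len(c) for c in cols)

    best = None  # (mse, window, degree)
    fastest_infeasible = None  # (ms, window, degree)
    for w in window_grid:
        if w % 2 == 0 or w > min_len:
            continue
        for d in degree_grid:
            if d >= w:
                continue
            t0 = time.perf_counter()
            smoothed = [smooth_signal(c, SmootherConfig(w, d)) for c in cols]
            ms = (time.perf_counter() - t0) * 1e3 / len(cols)
            if ms > time_budget_ms:
                if fastest_infeasible is None or ms < fastest_infeasible[0]:
                    fastest_infeasible = (ms, w, d)
                continue
            mse = float(
                np.mean([np.mean((s - r) ** 2) for s, r in zip(smoothed, refs)])
            )
            if best is None or mse < best[0]:
                best = (mse, w, d)
    if best is None:
        hint = (
            f"; fastest candidate (window={fastest_infeasible[1]}, "
            f"degree={fastest_infeasible[2]}) measured "
            f"{fastest_infeasible[0]:.3f} ms"
            if fastest_infeasible
            else ""
        )
        raise ValueError(
            f"no feasible grid point within {time_budget_ms} ms{hint}"
        )
    return SmootherConfig(best[1], best[2])
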