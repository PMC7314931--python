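"""Minimal per-subject signal conditioning before connectivity analysis.

Four operations, applied per node column: discard of initial volumes (signal
equilibration), least-squares linear detrending, zero-phase band-pass
filtering (0.01-0.08 Hz by default), and ordinary-least-squares nuisance
regression. Global-signal regression is deliberately not performed.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .series import SubjectSeries

logger = logging.getLogger("dfcnet")

__all__ = [
    "discard_initial",
    "linear_detrend",
    "bandpass",
    "regress_nuisance",
    "SeriesPreprocessor",
]


def _as_values(series) -> tuple[np.ndarray, SubjectSeries | None]:
    if isinstance(series, SubjectSeries):
        return series.values, series
    return np.asarray(series, dtype=float), None


def _wrap(values: np.ndarray, template: SubjectSeries | None):
    if template is None:
        return values
    return template.with_values(values)


def discard_initial(series, n_discard: int = 10):
    """Drop the first ``n_discard`` time points (default 10 volumes)."""
    values, tmpl = _as_values(series)
    t = values.shape[0]
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= t:
        raise ValueError(f"cannot discard {n_discard} of {t} time points")
    return _wrap(values[n_discard:], tmpl)


def linear_detrend(series):
    """Remove the per-column least-squares line (intercept + slope)."""
    values, tmpl = _as_values(series)
    if values.shape[0] < 3:
        raise ValueError("detrending needs at least 3 time points")
    out = sps.detrend(values, axis=0, type="linear")
    return _wrap(out, tmpl)


def bandpass(series, low_hz: float = 0.01, high_hz: float = 0.08,
             tr_seconds: float | None = None, order: int = 4):
    """Zero-phase Butterworth band-pass (forward-backward filtfilt).

    The band must sit below the Nyquist frequency ``1/(2 TR)``; with the
    default TR = 3 s that is 0.1667 Hz.
    """
    values, tmpl = _as_values(series)
    if tr_seconds is None:
        tr_seconds = tmpl.tr_seconds if tmpl is not None else 3.0
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"band edge {high_hz} Hz is not below the Nyquist frequency "
            f"{nyquist:.4g} Hz for TR = {tr_seconds} s"
        )
    if low_hz == 0:
        sos = sps.butter(order, high_hz / nyquist, btype="lowpass", output="sos")
    else:
        sos = sps.butter(order, [low_hz / nyquist, high_hz / nyquist],
                         btype="bandpass", output="sos")
    out = sps.sosfiltfilt(sos, values, axis=0)
    return _wrap(out, tmpl)


def regress_nuisance(series, confounds=None):
    """OLS residuals after projecting out confound columns plus an intercept.

    With no confounds this reduces to mean-centering. Rank-deficient
    confound matrices are handled by least-squares projection (dependent
    columns carry no extra information); a warning is logged.
    """
    values, tmpl = _as_values(series)
    t = values.shape[0]
    if confounds is None:
        confounds = np.empty((t, 0))
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != t:
        raise ValueError("confounds must have the same number of rows as the series")
    if confounds.shape[1] >= t:
        raise ValueError("more confounds than time points")
    design = np.column_stack([np.ones(t), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "confound design is rank deficient (rank %d of %d columns); "
            "dependent columns are absorbed by the projection",
            rank, design.shape[1],
        )
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    out = values - design @ beta
    return _wrap(out, tmpl)


class SeriesPreprocessor(BaseEstimator, TransformerMixin):
    """Composable preprocessing transformer for node time series.

    Applies, in ``steps`` order, any of: ``"discard"``, ``"detrend"``,
    ``"bandpass"``, ``"nuisance"``. Stateless (``fit`` is a no-op);
    ``transform`` accepts a SubjectSeries, a T x N array, or a list of
    either and preserves node names and metadata.

    Parameters
    ----------
    n_discard : int, default 10
        Initial volumes dropped.
    low_hz, high_hz : float
        Band-pass edges in Hz (defaults 0.01 and 0.08).
    tr_seconds : float or None
        Sampling interval; taken from the series when None.
    confounds : array or None
        T x C nuisance regressors (after discard), used by the
        ``"nuisance"`` step.
    steps : tuple of str
        Operation order; the default runs discard, detrend, band-pass, then
        nuisance regression.
    """

    def __init__(self, n_discard: int = 10, low_hz: float = 0.01, high_hz: float = 0.08,
                 tr_seconds: float | None = None, confounds=None,
                 steps: tuple = ("discard", "detrend", "bandpass", "nuisance")):
        self.n_discard = n_discard
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.tr_seconds = tr_seconds
        self.confounds = confounds
        self.steps = steps

    def fit(self, X, y=None):
        for step in self.steps:
            if step not in ("discard", "detrend", "bandpass", "nuisance"):
                raise ValueError(f"unknown preprocessing step {step!r}")
        self.n_features_in_ = None
        return self

    def _transform_one(self, series):
        out = series
        logger.info("preprocessing steps: %s", " -> ".join(self.steps))
        for step in self.steps:
            if step == "discard":
                out = discard_initial(out, self.n_discard)
            elif step == "detrend":
                out = linear_detrend(out)
            elif step == "bandpass":
                out = bandpass(out, self.low_hz, self.high_hz, tr_seconds=self.tr_seconds)
            elif step == "nuisance":
                out = regress_nuisance(out, self.confounds)
        return out

    def transform(self, X):
        self.fit(X)
        if isinstance(X, list):
            return [self._transform_one(x) for x in X]
        return self._transform_one(X)
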