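"""Epoch handling and temporal preprocessing of ROI and physiological signals.

BOLD time courses arrive as volumes-by-ROIs matrices sampled at the scanner
repetition time (TR); physiological channels (photoplethysmogram,
respiration belt, electrodermal activity) arrive as high-rate traces.  This
module provides the standard temporal operators used ahead of connectivity
estimation: linear detrending, zero-phase Butterworth band filtering,
nuisance regression against an externally supplied confound matrix, and
second-based window extraction.

All filters are 2nd-order Butterworth applied forward-backward
(``sosfiltfilt``), i.e. zero phase, which is the usual convention for
resting-state connectivity. Windows are half-open ``[start, end)`` in
seconds, a volume belonging to a window iff its onset time falls inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
import numpy as np
from scipy import signal as sps

from .exceptions import (
    InsufficientDataError,
    InvalidBandError,
    WindowRangeError,
)

EPOCH_KINDS = ("task_rest", "music", "intrinsic_rest")
PHYSIO_CHANNELS = ("ppg", "respiration", "eda")


@dataclass(frozen=True)
class RoiTimeSeries:
    """A volumes-by-ROIs signal matrix for one epoch of one trial.

    Parameters
    ----------
    participant_id, trial_id:
        Free-form tokens identifying the unit of observation.
    epoch:
        One of ``task_rest`` (pre-listening rest), ``music`` (listening
        period) or ``intrinsic_rest`` (long task-free rest).
    tr:
        Sampling interval in seconds (repetition time).
    data:
        Array of shape (n_volumes, n_rois); must be finite.
    roi_ids:
        Column labels, one per ROI.
    """

    participant_id: str
    trial_id: str
    epoch: str
    tr: float
    data: np.ndarray
    roi_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "roi_ids", tuple(self.roi_ids))
        if self.epoch not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (volumes x ROIs)")
        if len(self.roi_ids) != self.data.shape[1]:
            raise ValueError("roi_ids length must match data columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def times(self) -> np.ndarray:
        """Onset time of each volume, seconds from epoch start."""
        return np.arange(self.n_volumes) * self.tr

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class PhysioTrace:
    """A single physiological channel sampled at a fixed rate (Hz)."""

    channel: str
    rate: float
    samples: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.channel not in PHYSIO_CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


def detrend_linear(series: RoiTimeSeries) -> RoiTimeSeries:
    """Remove the per-column least-squares line (and hence the mean).

    Raises :class:`InsufficientDataError` with fewer than 3 volumes.
    """
    if series.n_volumes < 3:
        raise InsufficientDataError(
            f"detrending needs >=3 volumes, got {series.n_volumes}"
        )
    return series.with_data(sps.detrend(series.data, axis=0, type="linear"))


def _sos_filtfilt(data: np.ndarray, sos: np.ndarray, axis: int = 0) -> np.ndarray:
    n = data.shape[axis]
    default_pad = 3 * (2 * sos.shape[0] + 1)
    padlen = min(default_pad, n - 1)
    return sps.sosfiltfilt(sos, data, axis=axis, padlen=padlen)


def _band_sos(low: float, high: float | None, fs: float, order: int = 2) -> np.ndarray:
    nyq = fs / 2.0
    if high is not None and high >= nyq:
        raise InvalidBandError(
            f"upper band edge {high} Hz must lie below Nyquist {nyq} Hz"
        )
    if high is None and low >= nyq:
        raise InvalidBandError(
            f"cutoff {low} Hz must lie below Nyquist {nyq} Hz"
        )
    if low < 0:
        raise InvalidBandError("lower band edge must be non-negative")
    if high is not None and low >= high:
        raise InvalidBandError("lower band edge must lie below the upper edge")
    if low == 0 and high is not None:
        return sps.butter(order, high, btype="lowpass", fs=fs, output="sos")
    if high is None:
        return sps.butter(order, low, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(series: RoiTimeSeries, low: float, high: float) -> RoiTimeSeries:
    """Zero-phase band-pass (default RSFC band is 0.008-0.09 Hz)."""
    if series.n_volumes < 3:
        raise InsufficientDataError("band-pass needs >=3 volumes")
    sos = _band_sos(low, high, fs=1.0 / series.tr)
    return series.with_data(_sos_filtfilt(series.data, sos))


def highpass(series: RoiTimeSeries, cutoff: float) -> RoiTimeSeries:
    """Zero-phase high-pass; used for music epochs (0.008 Hz cutoff) where a
    low-pass would remove event-locked responses."""
    if series.n_volumes < 3:
        raise InsufficientDataError("high-pass needs >=3 volumes")
    sos = _band_sos(cutoff, None, fs=1.0 / series.tr)
    return series.with_data(_sos_filtfilt(series.data, sos))


def regress_confounds(series: RoiTimeSeries, confounds: np.ndarray) -> RoiTimeSeries:
    """Project out confound time courses (columns of ``confounds``).

    The confound matrix is an input: its construction (motion, CompCor,
    cardiac/respiratory regressors, ...) is upstream of this package.
    Output columns are orthogonal to every confound column.  A
    rank-deficient confound matrix is handled by least squares with a
    logged warning.
    """
    confounds = np.asarray(confounds, dtype=float)
    if confounds.size == 0:
        return series.with_data(series.data.copy())
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != series.n_volumes:
        raise ValueError(
            f"confound rows ({confounds.shape[0]}) must equal volumes "
            f"({series.n_volumes})"
        )
    if confounds.shape[1] >= series.n_volumes:
        raise ValueError("need fewer confounds than volumes")
    beta, _, rank, _ = np.linalg.lstsq(confounds, series.data, rcond=None)
    if rank < confounds.shape[1]:
        warnings.warn(
            f"confound matrix is rank deficient (rank {rank} < "
            f"{confounds.shape[1]}); using pseudo-inverse projection",
            stacklevel=2,
        )
    return series.with_data(series.data - confounds @ beta)


def extract_window(series: RoiTimeSeries, start: float, end: float) -> RoiTimeSeries:
    """Half-open second-based window ``[start, end)``.

    A volume is included iff its onset time lies inside the window, so an
    aligned window of w seconds at TR t holds w/t volumes.
    """
    if not (0 <= start < end):
        raise WindowRangeError(f"invalid window [{start}, {end})")
    if end > series.duration + 1e-9:
        raise WindowRangeError(
            f"window [{start}, {end}) exceeds epoch duration {series.duration}"
        )
    t = series.times
    mask = (t >= start - 1e-9) & (t < end - 1e-9)
    if not mask.any():
        raise WindowRangeError(f"window [{start}, {end}) contains no volume")
    return series.with_data(series.data[mask])


def filter_physio(trace: PhysioTrace, low: float, high: float | None) -> PhysioTrace:
    """Zero-phase band filtering of a physiological trace.

    ``low`` may be 0 for a pure low-pass; ``high`` may be None for a pure
    high-pass.  Conventional bands: pulse 1-35 Hz, respiration 0.05-1 Hz,
    electrodermal low-pass 1 Hz.
    """
    sos = _band_sos(low, high, fs=trace.rate)
    filtered = _sos_filtfilt(trace.samples, sos)
    return PhysioTrace(channel=trace.channel, rate=trace.rate, samples=filtered)
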