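"""Heart rate, respiration rate, and phasic skin-conductance metrics.

Pulse and respiration traces are reduced to instantaneous rates by peak
detection: successive inter-event intervals give a rate (60000/IBI_ms for
heart rate in bpm) placed at each peak time, then cubic-spline
interpolated onto a uniform 10-Hz grid.

Electrodermal activity is reduced to a nonnegative *phasic driver* by
regularised deconvolution against the biexponential (Bateman) impulse
response — a deliberately simple, deterministic stand-in for continuous
decomposition analysis.  The trace is low-pass filtered at 1 Hz,
downsampled to 10 Hz, split into a slowly varying tonic level and a
phasic remainder, and the driver is recovered by projected-gradient
(FISTA) non-negative least squares with Tikhonov smoothing.  Driver
excursions whose reconstructed skin-conductance response peaks below an
amplitude threshold (default 0.05 microsiemens) are zeroed.

Event-locked quantification follows the convention used for chills
psychophysiology: for each event, the mean of the series in the 1 s
before onset is the baseline, the response is the sum of
(value - baseline) over the event window, events deviating more than 3 SD
from the within-participant mean are excluded, and totals may be
log(1+x)-transformed (skin conductance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .events import EventTrain
from .exceptions import InsufficientDataError, InvalidConfigError
from .preprocess import PhysioTrace, filter_physio
from .simulate import scr_impulse_response

TARGET_RATE = 10.0  # Hz of all derived rate/driver series


@dataclass(frozen=True)
class RateSeries:
    """A uniformly sampled derived measure (bpm, breaths/min, or uS driver)."""

    rate: float
    values: np.ndarray
    measure: str = ""
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass(frozen=True)
class ResponseSummary:
    """Event-locked response scores for one participant and measure.

    ``scores`` holds one baseline-corrected sum per usable event;
    ``outlier_mask`` marks events excluded by the 3-SD screen (they are
    recorded, never silently dropped); ``total`` sums surviving events
    (optionally log(1+x)-transformed).
    """

    scores: np.ndarray
    outlier_mask: np.ndarray
    total: float
    units: str
    n_events: int
    n_skipped: int = 0
    log_transformed: bool = False


def rate_from_peaks(
    trace: PhysioTrace,
    min_interval: float = 0.25,
    prominence: float | None = None,
    target_rate: float = TARGET_RATE,
    scale: float = 60.0,
) -> RateSeries:
    """Instantaneous event rate from a peaked trace on a 10-Hz grid.

    ``scale=60`` yields per-minute rates (bpm for pulse, breaths/min for
    respiration).  Requires at least 3 detected peaks.  The rate value at
    peak k is ``scale / IBI(k-1, k)`` placed at peak k's time; a cubic
    spline interpolates between peaks and the ends are held constant.
    """
    x = trace.samples
    if prominence is None:
        prominence = 0.5 * np.std(x)
    distance = max(1, int(round(min_interval * trace.rate)))
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence)
    if peaks.size < 3:
        raise InsufficientDataError(
            f"found {peaks.size} peaks; need >=3 for a rate series"
        )
    tpk = peaks / trace.rate
    ibi = np.diff(tpk)
    rate_vals = scale / ibi          # value at the *second* peak of each pair
    spline = CubicSpline(tpk[1:], rate_vals)
    grid = np.arange(0.0, trace.duration, 1.0 / target_rate)
    vals = spline(np.clip(grid, tpk[1], tpk[-1]))
    measure = {"ppg": "heart_rate", "respiration": "respiration_rate"}.get(
        trace.channel, trace.channel)
    units = "bpm" if trace.channel == "ppg" else "events/min"
    return RateSeries(rate=target_rate, values=vals, measure=measure,
                      units=units)


def _downsample_to(x: np.ndarray, rate: float, target: float) -> np.ndarray:
    step = rate / target
    idx = np.round(np.arange(0, x.size, step)).astype(int)
    idx = idx[idx < x.size]
    return x[idx]


def _fista_nnls(K_forward, K_adjoint, x, n, alpha, lip, n_iter=400):
    """FISTA for min_d ||K d - x||^2 + alpha ||d||^2 subject to d >= 0."""
    d = np.zeros(n)
    z = d.copy()
    t_k = 1.0
    step = 1.0 / (lip + alpha)
    for _ in range(n_iter):
        grad = K_adjoint(K_forward(z) - x) + alpha * z
        d_new = np.maximum(z - step * grad, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k)) / 2.0
        z = d_new + ((t_k - 1.0) / t_new) * (d_new - d)
        d, t_k = d_new, t_new
    return d


def scr_phasic_driver(
    trace: PhysioTrace,
    tau1: float = 0.75,
    tau2: float = 2.0,
    threshold: float = 0.05,
    smoothing: float = 1e-3,
    n_iter: int = 400,
) -> RateSeries:
    """Thresholded nonnegative phasic driver of an electrodermal trace.

    Deconvolution of the (tonic-removed) signal against the Bateman
    impulse response with an ``smoothing`` Tikhonov penalty; excursions
    whose reconstructed response peak is below ``threshold`` uS are
    zeroed.  Driver units are uS/s: reconvolving the driver with the
    impulse response recovers the phasic signal in uS.
    """
    if trace.channel != "eda":
        raise InvalidConfigError("phasic driver requires an 'eda' trace")
    if not 0 < tau1 < tau2:
        raise InvalidConfigError("need 0 < tau1 < tau2")
    x = trace.samples
    rate = trace.rate
    if rate > 2.5 * TARGET_RATE:
        x = filter_physio(trace, 0.0, 1.0).samples
    if rate != TARGET_RATE:
        x = _downsample_to(x, rate, TARGET_RATE)
    dt = 1.0 / TARGET_RATE
    n = x.size
    # tonic level: smoothed morphological opening (running minimum then
    # maximum over ~20 s).  Phasic responses are positive-going and decay
    # within seconds, so the opening removes them while following slow
    # tonic waves exactly wherever no burst is present — a plain running
    # minimum lags slow oscillations, and a low-pass absorbs response
    # amplitude.
    if n > 30:
        from scipy.ndimage import (
            maximum_filter1d,
            minimum_filter1d,
            uniform_filter1d,
        )

        win = min(n, int(20 * TARGET_RATE) + 1)
        tonic = minimum_filter1d(x, size=win, mode="nearest")
        tonic = maximum_filter1d(tonic, size=win, mode="nearest")
        tonic = uniform_filter1d(tonic, size=min(n, int(5 * TARGET_RATE) + 1),
                                 mode="nearest")
    else:
        tonic = np.full(n, x.min())
    phasic = x - tonic
    h = scr_impulse_response(np.arange(0.0, min(60.0, n * dt), dt), tau1, tau2)

    def forward(d):
        return sps.fftconvolve(d, h)[:n] * dt

    def adjoint(r):
        return sps.fftconvolve(r[::-1], h)[:n][::-1] * dt

    lip = (dt * h.sum()) ** 2
    d = _fista_nnls(forward, adjoint, phasic, n, smoothing, lip, n_iter=n_iter)
    d[d < 1e-6 * max(1.0, d.max(initial=0.0))] = 0.0
    # threshold excursions on their reconstructed response amplitude
    out = d.copy()
    i = 0
    while i < n:
        if out[i] <= 0:
            i += 1
            continue
        j = i
        while j < n and out[j] > 0:
            j += 1
        seg = np.zeros(n)
        seg[i:j] = out[i:j]
        peak = (sps.fftconvolve(seg, h)[:n] * dt).max(initial=0.0)
        if peak < threshold:
            out[i:j] = 0.0
        i = j
    return RateSeries(rate=TARGET_RATE, values=out, measure="scr_driver",
                      units="uS/s")


def _loo_outlier_mask(scores: np.ndarray, sd: float) -> np.ndarray:
    """Leave-one-out 3-SD screen.

    Each score is compared with the mean/SD of the *other* scores: with
    the handful of events a participant contributes, a screen that
    includes the candidate in its own reference statistics can never
    trigger (the largest attainable z is (n-1)/sqrt(n)).
    """
    n = scores.size
    mask = np.zeros(n, dtype=bool)
    if n < 3:
        return mask
    for i in range(n):
        rest = np.delete(scores, i)
        s = rest.std(ddof=1)
        dev = abs(scores[i] - rest.mean())
        if s > 0:
            mask[i] = dev > sd * s
        else:  # identical reference events: any deviation is an outlier
            mask[i] = not np.isclose(scores[i], rest.mean(),
                                     rtol=1e-9, atol=1e-9)
    return mask


def event_locked_sum(
    series: RateSeries,
    events: EventTrain,
    label: str = "chill",
    baseline_window: float = 1.0,
    outlier_sd: float = 3.0,
    log_transform: bool = False,
) -> ResponseSummary:
    """Baseline-corrected event sums with a 3-SD outlier screen.

    Per event: baseline = mean of the ``baseline_window`` seconds before
    onset; score = sum over the event window of (value - baseline).
    Events starting earlier than ``baseline_window`` into the recording
    are skipped with a warning.  Outliers are screened two-sided at
    ``outlier_sd`` SDs across this participant's events.
    """
    r = series.rate
    v = series.values
    scores = []
    n_skipped = 0
    sel = events.events[events.events["trial_type"] == label]
    for row in sel.itertuples(index=False):
        b0 = int(round((row.onset - baseline_window) * r))
        b1 = int(round(row.onset * r))
        e1 = int(round((row.onset + row.duration) * r))
        if b0 < 0:
            warnings.warn(
                f"event at {row.onset:.2f}s starts within the baseline "
                "window; skipped", stacklevel=2)
            n_skipped += 1
            continue
        if e1 > v.size:
            warnings.warn(
                f"event at {row.onset:.2f}s extends past the recording; "
                "skipped", stacklevel=2)
            n_skipped += 1
            continue
        baseline = v[b0:b1].mean() if b1 > b0 else 0.0
        scores.append(float(np.sum(v[b1:e1] - baseline)))
    scores = np.asarray(scores)
    mask = _loo_outlier_mask(scores, outlier_sd)
    total = float(scores[~mask].sum()) if scores.size else 0.0
    if log_transform:
        total = float(np.log1p(max(total, 0.0)))
    unit = series.units + ("·samples" if series.units else "samples")
    return ResponseSummary(scores=scores, outlier_mask=mask, total=total,
                           units=unit, n_events=int(scores.size),
                           n_skipped=n_skipped, log_transformed=log_transform)
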