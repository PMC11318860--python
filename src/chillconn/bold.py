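"""Event-locked BOLD percent-signal-change during chills.

For each chill event, the event window is shifted by +4 s to account for
hemodynamic delay (the signal itself is not resampled).  The per-ROI
baseline is the mean of the two volumes at onset-2 and onset+2 volumes —
skipping the volumes immediately adjacent to the onset volume — and the
percent signal change is 100 * (x - baseline) / baseline.  The per-ROI
response score for an event is the sum of PSC over the event's (shifted)
window; scores deviating more than 3 SD from the across-event mean are
excluded, and surviving scores are totaled.

The alternative reading of the baseline convention (the directly adjacent
onset±1 volumes) is available via ``baseline_volumes="adjacent"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import EventTrain
from .exceptions import UndefinedResponseError
from .preprocess import RoiTimeSeries

HEMODYNAMIC_SHIFT = 4.0  # seconds


@dataclass(frozen=True)
class BoldResponseSummary:
    """Per-ROI event-locked PSC totals for one participant-trial set."""

    roi_ids: tuple
    totals: np.ndarray          # (n_rois,)
    scores: np.ndarray          # (n_events, n_rois)
    outlier_mask: np.ndarray    # (n_events, n_rois) True = excluded
    n_events: int
    n_skipped: int = 0


def percent_signal_change(
    series: RoiTimeSeries,
    onset: float,
    shift: float = HEMODYNAMIC_SHIFT,
    baseline_volumes: str = "skip_adjacent",
) -> np.ndarray | None:
    """Per-ROI PSC of the whole epoch relative to one event's baseline.

    Returns an array shaped like ``series.data`` or ``None`` (with a
    warning) when the onset sits too close to the epoch edge for the
    baseline volumes to exist.  Raises
    :class:`UndefinedResponseError` if a baseline is non-positive.
    """
    if baseline_volumes not in ("skip_adjacent", "adjacent"):
        raise ValueError("baseline_volumes must be 'skip_adjacent' or 'adjacent'")
    off = 2 if baseline_volumes == "skip_adjacent" else 1
    v0 = int(np.floor((onset + shift) / series.tr))
    lo, hi = v0 - off, v0 + off
    if lo < 0 or hi >= series.n_volumes:
        warnings.warn(
            f"event at {onset:.2f}s lacks baseline volumes (onset volume "
            f"{v0}); skipped", stacklevel=2)
        return None
    baseline = (series.data[lo] + series.data[hi]) / 2.0
    bad = baseline <= 0
    if bad.any():
        roi = series.roi_ids[int(np.argmax(bad))]
        raise UndefinedResponseError(
            f"non-positive PSC baseline for ROI {roi!r}")
    return 100.0 * (series.data - baseline) / baseline


def roi_event_response(
    series: RoiTimeSeries,
    events: EventTrain,
    label: str = "chill",
    shift: float = HEMODYNAMIC_SHIFT,
    outlier_sd: float = 3.0,
    baseline_volumes: str = "skip_adjacent",
) -> BoldResponseSummary:
    """Summed event-locked PSC per ROI with a 3-SD across-event screen."""
    scores = []
    n_skipped = 0
    sel = events.events[events.events["trial_type"] == label]
    for row in sel.itertuples(index=False):
        psc = percent_signal_change(series, row.onset, shift=shift,
                                    baseline_volumes=baseline_volumes)
        if psc is None:
            n_skipped += 1
            continue
        t = series.times
        w0, w1 = row.onset + shift, row.onset + row.duration + shift
        mask = (t >= w0 - 1e-9) & (t < w1 - 1e-9)
        if not mask.any() or t[mask][-1] + series.tr > series.duration + 1e-9:
            n_skipped += 1
            warnings.warn(
                f"event at {row.onset:.2f}s extends past the epoch; skipped",
                stacklevel=2)
            continue
        scores.append(psc[mask].sum(axis=0))
    p = len(series.roi_ids)
    if not scores:
        return BoldResponseSummary(
            roi_ids=series.roi_ids, totals=np.zeros(p),
            scores=np.zeros((0, p)), outlier_mask=np.zeros((0, p), bool),
            n_events=0, n_skipped=n_skipped)
    S = np.vstack(scores)
    from .physio import _loo_outlier_mask

    mask = np.zeros_like(S, dtype=bool)
    if S.shape[0] >= 3:
        for j in range(S.shape[1]):
            mask[:, j] = _loo_outlier_mask(S[:, j], outlier_sd)
    totals = np.where(mask, 0.0, S).sum(axis=0)
    return BoldResponseSummary(roi_ids=series.roi_ids, totals=totals,
                               scores=S, outlier_mask=mask,
                               n_events=S.shape[0], n_skipped=n_skipped)
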