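"""Cohort-level feature and target extraction.

Bridges the per-trial operators (preprocessing, partial-correlation
features, behavioral cleaning, physiological and BOLD event metrics) to
the unit-by-feature matrices consumed by the predictive models.

Preprocessing conventions: rest epochs are detrended and band-passed
(0.008-0.09 Hz); music epochs are detrended and high-passed only
(0.008 Hz), preserving event-locked responses.  Windowing always happens
*after* filtering the full epoch.  The per-trial Fisher-z
partial-correlation matrix is computed over the full ROI set, averaged
across a participant's available trials, and edges are selected from the
averaged matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bold import roi_event_response
from .connectivity import edge_list, fisher_z, partial_corr_matrix
from .events import clean_presses, emotion_durations, participant_means
from .physio import event_locked_sum, rate_from_peaks, scr_phasic_driver
from .preprocess import (
    RoiTimeSeries,
    bandpass,
    detrend_linear,
    extract_window,
    filter_physio,
    highpass,
)
from .simulate import CohortDataset

REST_BAND = (0.008, 0.09)
MUSIC_HIGHPASS = 0.008


def preprocess_rest(series: RoiTimeSeries,
                    band: tuple = REST_BAND) -> RoiTimeSeries:
    """Detrend then zero-phase band-pass a rest epoch."""
    return bandpass(detrend_linear(series), *band)


def preprocess_music(series: RoiTimeSeries,
                     cutoff: float = MUSIC_HIGHPASS) -> RoiTimeSeries:
    """Detrend then high-pass a music epoch (no low-pass)."""
    return highpass(detrend_linear(series), cutoff)


def _trial_matrix(series: RoiTimeSeries, window, shrinkage):
    if window is not None:
        series = extract_window(series, window[0], window[1])
    pc, alpha = partial_corr_matrix(series, shrinkage=shrinkage,
                                    return_shrinkage=True)
    pc = pc.copy()
    np.fill_diagonal(pc, 0.0)
    return fisher_z(pc), alpha


def participant_mean_matrices(
    dataset: CohortDataset,
    window: tuple | None = None,
    epoch: str = "task_rest",
    shrinkage: str | float = "auto",
    missing: Mapping[tuple, bool] | None = None,
):
    """Per-participant trial-averaged Fisher-z partial-correlation matrices.

    Returns (participant_ids, matrices, mean_shrinkage).  ``missing`` may
    flag (participant_id, trial_id) pairs to drop (emulating trials lost
    to denoising failures).
    """
    pids = dataset.participant_ids
    mats, alphas = [], []
    for pid in pids:
        acc, n_used, a_acc = None, 0, 0.0
        for tid in dataset.trial_ids(pid):
            if missing and missing.get((pid, tid)):
                continue
            trial = dataset.trials[(pid, tid)]
            series = trial.rest if epoch == "task_rest" else trial.music
            series = (preprocess_rest(series) if epoch == "task_rest"
                      else preprocess_music(series))
            z, alpha = _trial_matrix(series, window, shrinkage)
            acc = z if acc is None else acc + z
            a_acc += alpha
            n_used += 1
        if n_used == 0:
            raise ValueError(f"participant {pid} has no usable trials")
        mats.append(acc / n_used)
        alphas.append(a_acc / n_used)
    return pids, mats, float(np.mean(alphas))


def feature_matrix_from_matrices(
    matrices: Sequence[np.ndarray],
    dataset: CohortDataset,
    mode: str = "network_pair",
    networks: Sequence[str] | None = ("auditory", "reward"),
    side: str | None = None,
):
    """Stack edge vectors from per-unit matrices into (units, edges)."""
    parc = dataset.parcellation
    edges = edge_list(parc, mode=mode, networks=networks, side=side)
    pos = {r: i for i, r in enumerate(parc.roi_ids)}
    ia = np.array([pos[a] for a, _ in edges])
    ib = np.array([pos[b] for _, b in edges])
    X = np.vstack([m[ia, ib] for m in matrices])
    return X, edges


def participant_features(
    dataset: CohortDataset,
    mode: str = "network_pair",
    networks: Sequence[str] | None = ("auditory", "reward"),
    side: str | None = None,
    window: tuple | None = None,
    epoch: str = "task_rest",
    shrinkage: str | float = "auto",
    conditioning: str = "full",
):
    """Participant-by-edge feature matrix (trials averaged).

    ``conditioning="full"`` computes partial correlations over the whole
    ROI set before selecting edges; ``"subset"`` restricts the
    conditioning set to the ROIs spanned by the edge set (e.g. the
    10-ROI single-hemisphere auditory-reward models).  Returns
    (participant_ids, X, edges).
    """
    if conditioning == "full":
        pids, mats, _ = participant_mean_matrices(
            dataset, window=window, epoch=epoch, shrinkage=shrinkage)
        X, edges = feature_matrix_from_matrices(mats, dataset, mode=mode,
                                                networks=networks, side=side)
        return pids, X, edges
    if conditioning != "subset":
        raise ValueError("conditioning must be 'full' or 'subset'")
    parc = dataset.parcellation
    edges = edge_list(parc, mode=mode, networks=networks, side=side)
    keep = sorted({r for e in edges for r in e})
    keep_idx = [parc.roi_ids.index(r) for r in keep]
    from .connectivity import ParcellationSpec

    sub_parc = ParcellationSpec(
        roi_ids=tuple(parc.roi_ids[i] for i in keep_idx),
        network=tuple(parc.network[i] for i in keep_idx),
        hemisphere=tuple(parc.hemisphere[i] for i in keep_idx))
    pos = {r: i for i, r in enumerate(sub_parc.roi_ids)}
    ia = np.array([pos[a] for a, _ in edges])
    ib = np.array([pos[b] for _, b in edges])
    pids = dataset.participant_ids
    rows = []
    for pid in pids:
        acc, n_used = None, 0
        for tid in dataset.trial_ids(pid):
            trial = dataset.trials[(pid, tid)]
            src = trial.rest if epoch == "task_rest" else trial.music
            sub = RoiTimeSeries(
                participant_id=src.participant_id, trial_id=src.trial_id,
                epoch=src.epoch, tr=src.tr, data=src.data[:, keep_idx],
                roi_ids=sub_parc.roi_ids)
            sub = (preprocess_rest(sub) if epoch == "task_rest"
                   else preprocess_music(sub))
            z, _ = _trial_matrix(sub, window, shrinkage)
            acc = z if acc is None else acc + z
            n_used += 1
        rows.append(acc[ia, ib] / n_used)
    return pids, np.vstack(rows), edges


def participant_targets(dataset: CohortDataset, label: str = "chill"):
    """Per-participant mean cleaned emotion duration (seconds).

    Returns (participant_ids, y).
    """
    pids = dataset.participant_ids
    y = []
    for pid in pids:
        summaries = [
            emotion_durations(clean_presses(dataset.trials[(pid, tid)].events))
            for tid in dataset.trial_ids(pid)
        ]
        y.append(participant_means(summaries)[label])
    return pids, np.asarray(y)


def trial_targets(dataset: CohortDataset, label: str = "chill"):
    """Per-trial cleaned emotion duration.  Returns (unit_ids, y)."""
    ids, y = [], []
    for (pid, tid), trial in dataset.trials.items():
        ids.append((pid, tid))
        y.append(emotion_durations(clean_presses(trial.events)).durations[label])
    return ids, np.asarray(y)


def trial_features(
    dataset: CohortDataset,
    variant: str = "preceding",
    mode: str = "network_pair",
    networks: Sequence[str] | None = ("auditory", "reward"),
    window: tuple | None = None,
    shrinkage: str | float = "auto",
):
    """Trial-by-edge features for the three listening-cycle periods.

    ``variant``:
      * ``"preceding"`` — the rest epoch immediately before each song;
      * ``"music"`` — connectivity during the whole listening period;
      * ``"following"`` — the rest epoch of the *next* trial in the same
        session (the rest that follows the song); the last trial of each
        session is dropped.

    Returns (unit_ids, X, edges) with unit_ids aligned to the trials
    that retain a feature.
    """
    if variant not in ("preceding", "music", "following"):
        raise ValueError(f"unknown variant {variant!r}")
    parc = dataset.parcellation
    edges = edge_list(parc, mode=mode, networks=networks)
    pos = {r: i for i, r in enumerate(parc.roi_ids)}
    ia = np.array([pos[a] for a, _ in edges])
    ib = np.array([pos[b] for _, b in edges])
    per_session = dataset.config.trials_per_session
    ids, rows = [], []
    for pid in dataset.participant_ids:
        tids = dataset.trial_ids(pid)
        for k, tid in enumerate(tids):
            if variant == "preceding":
                src = dataset.trials[(pid, tid)].rest
                series = preprocess_rest(src)
            elif variant == "music":
                src = dataset.trials[(pid, tid)].music
                series = preprocess_music(src)
            else:
                if (k + 1) % per_session == 0 or k + 1 >= len(tids):
                    continue  # no post-song rest for the session's last trial
                src = dataset.trials[(pid, tids[k + 1])].rest
                series = preprocess_rest(src)
            z, _ = _trial_matrix(series, window, shrinkage)
            rows.append(z[ia, ib])
            ids.append((pid, tid))
    return ids, np.vstack(rows), edges


def physio_chill_targets(dataset: CohortDataset, measure: str = "scr"):
    """Per-participant summed event-locked physiological chills response.

    ``measure``: ``"scr"`` (log-transformed driver sum), ``"hr"`` or
    ``"rr"``.  Per trial the event-locked baseline-corrected sum is
    computed, trial scores are summed per participant after the outlier
    screen inside each trial.
    """
    if measure not in ("scr", "hr", "rr"):
        raise ValueError("measure must be scr, hr or rr")
    pids = dataset.participant_ids
    out = []
    for pid in pids:
        total = 0.0
        for tid in dataset.trial_ids(pid):
            trial = dataset.trials[(pid, tid)]
            events = clean_presses(trial.events)
            if measure == "scr":
                series = scr_phasic_driver(trial.physio["eda"])
                summary = event_locked_sum(series, events, label="chill")
            elif measure == "hr":
                filtered = filter_physio(trial.physio["ppg"], 1.0,
                                         min(35.0, trial.physio["ppg"].rate
                                             / 2 - 1))
                series = rate_from_peaks(filtered, min_interval=0.3)
                summary = event_locked_sum(series, events, label="chill")
            else:
                filtered = filter_physio(trial.physio["respiration"], 0.05, 1.0)
                series = rate_from_peaks(filtered, min_interval=1.5)
                summary = event_locked_sum(series, events, label="chill")
            total += summary.total
        if measure == "scr":
            total = float(np.log1p(max(total, 0.0)))
        out.append(total)
    return pids, np.asarray(out)


def bold_chill_targets(dataset: CohortDataset, roi_id: str):
    """Per-participant summed event-locked PSC for one ROI."""
    parc = dataset.parcellation
    if roi_id not in parc.roi_ids:
        raise KeyError(f"unknown ROI {roi_id!r}")
    col = parc.roi_ids.index(roi_id)
    pids = dataset.participant_ids
    out = []
    for pid in pids:
        total = 0.0
        for tid in dataset.trial_ids(pid):
            trial = dataset.trials[(pid, tid)]
            events = clean_presses(trial.events)
            music = preprocess_music(trial.music)
            # filtering removes the mean; restore it so PSC baselines are
            # positive raw-signal levels
            music = music.with_data(music.data + trial.music.data.mean(axis=0))
            summary = roi_event_response(music, events, label="chill")
            total += float(summary.totals[col])
        out.append(total)
    return pids, np.asarray(out)
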