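"""Synthetic listening cohorts with a planted auditory-reward coupling.

The generator emulates the data layout of a music-chills fMRI experiment:
per participant and trial, a short pre-listening rest epoch of ROI BOLD
signals, a music-listening epoch with button-press event trains, and
physiological traces (pulse, respiration, electrodermal) sampled at a
fixed rate.  Its central device is a latent per-participant (and
per-trial) *coupling* scalar that simultaneously

* scales the auditory-reward cross-network covariance of the rest epoch
  (the planted connectivity signal),
* sets the trial's total chills duration (the behavioral target),
* scales the amplitude of event-locked hemodynamic responses in reward
  ROIs during music, and
* scales the amplitude of event-locked electrodermal responses,

so the full analysis chain — connectivity features, LASSO decoding,
physiology and BOLD event metrics — can be exercised end-to-end against a
known ground truth.  With ``effect_size = 0`` the behavioral target is
decoupled from the brain signal and the generator provides an exact null.

Default scales follow the study design this package models: 38
participants, 8 trials in 2 sessions, TR = 2 s, 40-s pre-listening rest,
~270-s songs, 288 ROIs in 13 networks (auditory 12, reward 8), mean
chills duration ~50 s with between-participant spread ~30 s.

All randomness flows through one seeded ``numpy`` generator in a fixed
order: identical configurations produce byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .connectivity import ParcellationSpec, edge_list
from .events import EventTrain
from .exceptions import GenerationError, InvalidConfigError
from .preprocess import PhysioTrace, RoiTimeSeries

#: 13 networks, 288 ROIs; auditory and reward sizes follow the modeled
#: study, the remaining 11 networks split the rest of the brain.
DEFAULT_NETWORKS: dict = {
    "auditory": 12,
    "reward": 8,
    "default_mode": 65,
    "visual": 30,
    "frontoparietal": 28,
    "salience": 20,
    "somatomotor": 30,
    "dorsal_attention": 18,
    "ventral_attention": 14,
    "cingulo_opercular": 20,
    "subcortical": 14,
    "cerebellum": 19,
    "medial_temporal": 10,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of a synthetic cohort.

    The planted coupling g ~ N(0, ``coupling_sd``) per participant, plus
    N(0, ``coupling_trial_sd``) trial-to-trial jitter, drives both the
    rest-epoch covariance and the chills target.  The covariance carries
    a *shared component* spanning the auditory and reward ROIs whose
    variance is ``shared_var * exp(fc_gain * g)``: every auditory-reward
    cross covariance (the planted edges) rises monotonically with g while
    the matrix stays positive definite for any g.  The chills target is
    ``baseline_duration + effect_size * g`` seconds (clamped to the song
    length, with trial noise ``obs_noise_sd``).
    """

    n_participants: int = 38
    n_trials: int = 8
    trials_per_session: int = 4
    tr: float = 2.0
    rest_duration: float = 40.0
    music_duration: float = 270.0
    rois_per_network: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NETWORKS)
    )
    effect_size: float = 50.0           # seconds of chills per coupling unit
    coupling_sd: float = 0.7            # between-participant SD of coupling
    coupling_trial_sd: float = 0.2      # within-participant trial jitter SD
    baseline_duration: float = 50.0     # population-mean chills duration (s)
    obs_noise_sd: float = 25.0          # trial-level behavioral noise SD (s)
    fc_gain: float = 1.5                # log-variance gain of the shared
                                        # auditory-reward component per
                                        # coupling unit
    shared_var: float = 0.1             # baseline variance of that component
    base_within_r: float = 0.3          # within-network baseline correlation
    base_cross_r: float = 0.1           # cross-network baseline correlation
    ar_coef: float = 0.25               # lag-1 autocorrelation of BOLD noise
    bold_baseline: float = 1000.0       # raw BOLD units
    bold_noise_sd: float = 10.0         # ~1% signal fluctuation
    bold_response_amp: float = 10.0     # ~1% peak event response
    scr_amp: float = 0.4                # microsiemens driver amplitude scale
    scr_tau1: float = 0.75              # SCR impulse-response rise (s)
    scr_tau2: float = 2.0               # SCR impulse-response decay (s)
    heart_rate_bpm: float = 65.0
    physio_rate: float = 100.0          # Hz
    intrinsic_duration: float = 600.0   # 10-min task-free rest (s)
    include_intrinsic: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_trials < 1:
            raise InvalidConfigError("counts must be >= 1")
        if self.tr <= 0:
            raise InvalidConfigError("tr must be positive")
        if self.rest_duration < self.tr:
            raise InvalidConfigError("rest_duration must cover >= 1 volume")
        if self.music_duration < 20:
            raise InvalidConfigError("music_duration must be >= 20 s")
        nets = dict(self.rois_per_network)
        for required in ("auditory", "reward"):
            if required not in nets or nets[required] < 2:
                raise InvalidConfigError(
                    f"parcellation must contain a {required!r} network (>=2 ROIs)"
                )
        if nets["auditory"] % 2:
            raise InvalidConfigError("auditory ROI count must be even")
        if self.effect_size < 0:
            raise InvalidConfigError("effect_size must be non-negative")
        if not 0 < self.base_cross_r < self.base_within_r < 1:
            raise InvalidConfigError("need 0 < base_cross_r < base_within_r < 1")
        if self.physio_rate <= 0:
            raise InvalidConfigError("physio_rate must be positive")

    def shared_component_var(self, coupling: float) -> float:
        """Variance of the shared auditory-reward component at a coupling.

        ``shared_var * exp(fc_gain * coupling)``, clipped so the
        positive-definiteness slack of the base model is preserved
        (within-network correlation plus the component must stay below
        the unit ROI variance).
        """
        hi = 0.95 * (1.0 - self.base_within_r) - 0.1
        return float(np.clip(self.shared_var * np.exp(self.fc_gain * coupling),
                             0.005, max(hi, 0.01)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rois_per_network"] = dict(d["rois_per_network"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery checks.

    ``true_target`` is the noiseless chills duration
    clamp(baseline + effect_size * coupling, [0, song length]);
    ``planted_edges`` all cross the auditory-reward boundary.
    """

    participant_coupling: np.ndarray          # (n_participants,)
    trial_coupling: np.ndarray                # (n_participants, n_trials)
    planted_edges: tuple
    true_target: np.ndarray                   # (n_participants, n_trials)
    baseline: float
    effect_size: float

    def to_dict(self) -> dict:
        return {
            "participant_coupling": self.participant_coupling.tolist(),
            "trial_coupling": self.trial_coupling.tolist(),
            "planted_edges": [list(e) for e in self.planted_edges],
            "true_target": self.true_target.tolist(),
            "baseline": self.baseline,
            "effect_size": self.effect_size,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            participant_coupling=np.asarray(d["participant_coupling"], float),
            trial_coupling=np.asarray(d["trial_coupling"], float),
            planted_edges=tuple(tuple(e) for e in d["planted_edges"]),
            true_target=np.asarray(d["true_target"], float),
            baseline=float(d["baseline"]),
            effect_size=float(d["effect_size"]),
        )


@dataclass(frozen=True)
class TrialData:
    """All epochs of one participant-trial."""

    rest: RoiTimeSeries
    music: RoiTimeSeries
    events: EventTrain
    physio: Mapping[str, PhysioTrace]


@dataclass(frozen=True)
class CohortDataset:
    """A complete synthetic cohort."""

    parcellation: ParcellationSpec
    config: SimulationConfig
    trials: Mapping[tuple, TrialData]          # (participant_id, trial_id) ->
    ground_truth: GroundTruth
    intrinsic: Mapping[str, RoiTimeSeries] | None = None

    @property
    def participant_ids(self) -> tuple:
        seen = []
        for pid, _ in self.trials:
            if pid not in seen:
                seen.append(pid)
        return tuple(seen)

    def trial_ids(self, participant_id: str) -> tuple:
        return tuple(t for (p, t) in self.trials if p == participant_id)


def simulate_parcellation(
    rois_per_network: Mapping[str, int] | None = None, seed: int = 0
) -> ParcellationSpec:
    """Build a parcellation with hemisphere-balanced networks.

    Each network's ROIs are split half left, half right (an odd remainder
    becomes a midline ROI); the auditory network must have an even count.
    The ROI ordering is a pure function of the map, so a given seed (or
    any seed) reproduces the same spec.
    """
    nets = dict(rois_per_network) if rois_per_network is not None else dict(
        DEFAULT_NETWORKS
    )
    if not nets:
        raise InvalidConfigError("rois_per_network must be non-empty")
    for name, count in nets.items():
        if count < 1:
            raise InvalidConfigError(f"network {name!r} must have >= 1 ROI")
    if "auditory" in nets and nets["auditory"] % 2:
        raise InvalidConfigError("auditory ROI count must be even")
    roi_ids, network, hemisphere = [], [], []
    for name, count in nets.items():
        half = count // 2
        sides = ["L"] * half + ["R"] * half + (["mid"] if count % 2 else [])
        per_side: dict = {}
        for side in sides:
            per_side[side] = per_side.get(side, 0) + 1
            roi_ids.append(f"{name}_{side}_{per_side[side]:02d}")
            network.append(name)
            hemisphere.append(side)
    return ParcellationSpec(roi_ids=tuple(roi_ids), network=tuple(network),
                            hemisphere=tuple(hemisphere))


def canonical_hrf(t) -> np.ndarray | float:
    """Double-gamma hemodynamic response (unit time constants).

    h(t) = g(t; 6) - g(t; 16)/6 with gamma densities g; zero at t = 0,
    peak near 5 s, small late undershoot, ~0 beyond 30 s.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def _gpdf(x, a):
        return np.exp((a - 1) * np.log(x) - x - gammaln(a))

    out[pos] = _gpdf(tp, 6.0) - _gpdf(tp, 16.0) / 6.0
    if out.ndim == 0:
        return float(out)
    return out


def scr_impulse_response(t, tau1: float = 0.75, tau2: float = 2.0):
    """Biexponential (Bateman) skin-conductance impulse response.

    h(t) = exp(-t/tau2) - exp(-t/tau1) with 0 < tau1 < tau2; zero at
    t = 0, peak at ln(tau2/tau1) * tau1 * tau2 / (tau2 - tau1).
    """
    if not 0 < tau1 < tau2:
        raise InvalidConfigError("need 0 < tau1 < tau2")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau2)
                   - np.exp(-np.maximum(t, 0) / tau1), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# internal generation helpers


def _base_correlation(parc: ParcellationSpec, within: float, cross: float):
    p = parc.n_rois
    C = np.full((p, p), cross)
    nets = np.asarray(parc.network)
    for name in parc.networks:
        idx = np.where(nets == name)[0]
        C[np.ix_(idx, idx)] = within
    np.fill_diagonal(C, 1.0)
    return C


def _ar_mvn(rng, chol, n_vol, phi, burn=10):
    """Stationary AR(1) series with cross-sectional covariance chol chol'."""
    p = chol.shape[0]
    z = rng.standard_normal((n_vol + burn, p)) @ chol.T
    x = np.empty_like(z)
    x[0] = z[0]
    a = np.sqrt(1.0 - phi * phi)
    for k in range(1, z.shape[0]):
        x[k] = phi * x[k - 1] + a * z[k]
    return x[burn:]


def _choose_label(rng, exclude):
    options = [l for l in ("neutral", "pleasure", "tear") if l not in exclude]
    weights = {"neutral": 0.35, "pleasure": 0.5, "tear": 0.15}
    w = np.array([weights[l] for l in options])
    return options[int(rng.choice(len(options), p=w / w.sum()))]


def _make_trial_events(rng, y_chill, music_dur):
    """Event train whose *cleaned* chill total equals ``y_chill`` exactly.

    Returns (raw EventTrain, chill (onset, duration) list).  The raw train
    additionally exercises the cleaning rules: occasional contiguous
    same-label double presses, sub-second spurious presses, and chill+tear
    co-occurrence.
    """
    span_lo, span_hi = 2.0, music_dur - 2.0
    span = span_hi - span_lo
    if y_chill < 1.5:
        y_chill = 0.0
    chills = []
    if y_chill > 0:
        k_dur = max(1, int(y_chill // 2.0))
        k_space = max(1, int((span - y_chill) / 2.5) - 1)
        k = int(max(1, min(1 + rng.poisson(2.0), k_dur, k_space)))
        d = rng.lognormal(np.log(10.0), 0.5, size=k)
        d = d / d.sum() * y_chill
        for _ in range(6):
            if d.min() >= 1.8 or k == 1:
                break
            d = np.maximum(d, 1.8)
            d = d / d.sum() * y_chill
        if k > 1 and d.min() < 1.5:
            k = 1
            d = np.array([y_chill])
        free = span - y_chill - 2.0 * (k + 1)
        if free < 0:
            raise GenerationError(
                f"chills duration {y_chill:.1f}s does not fit in "
                f"{music_dur:.0f}-s song"
            )
        gaps = 2.0 + free * rng.dirichlet(np.ones(k + 1))
        onset = span_lo
        for j in range(k):
            onset += gaps[j]
            chills.append((onset, float(d[j])))
            onset += d[j]
    raw: list[tuple] = []
    # chill+tear co-occurrence (decided first: a tear between two merged
    # chill presses would block their re-merge during cleaning)
    cooccur_tear = bool(chills) and rng.random() < 0.25
    # chill presses (possibly split into two contiguous presses)
    split_j = -1
    if chills and not cooccur_tear and rng.random() < 0.3:
        durs = [c[1] for c in chills]
        split_j = int(np.argmax(durs))
        if durs[split_j] < 4.0:
            split_j = -1
    for j, (o, d) in enumerate(chills):
        if j == split_j:
            raw.append((o, d / 2.0, "chill"))
            raw.append((o + d / 2.0, d / 2.0, "chill"))
        else:
            raw.append((o, d, "chill"))
    if cooccur_tear:
        o, d = chills[0]
        raw.append((o, d, "tear"))
    # filler covering the rest of the song
    bounds = [0.0]
    for o, d in chills:
        bounds.extend([o, o + d])
    bounds.append(music_dur)
    fillers = []
    prev_label = "chill" if chills else None
    for si in range(0, len(bounds), 2):
        a, b = bounds[si], bounds[si + 1]
        s = b - a
        if s < 1.0:
            continue
        if s < 8.0:
            m = 1
        else:
            m = int(rng.integers(1, min(4, int(s // 4.0)) + 1))
        parts = 1.5 + (s - 1.5 * m) * rng.dirichlet(np.ones(m)) if m > 1 else [s]
        pos = a
        for dur in parts:
            label = _choose_label(rng, {prev_label})
            fillers.append([pos, float(dur), label])
            prev_label = label
            pos += dur
        prev_label = "chill"
    # sub-second spurious press inside a long filler
    long_idx = [i for i, f in enumerate(fillers) if f[1] >= 3.0]
    if long_idx and rng.random() < 0.5:
        i = int(rng.choice(long_idx))
        onset, dur, label = fillers[i]
        before = fillers[i - 1][2] if i > 0 else "chill"
        spurious = _choose_label(rng, {label, before})
        raw.append((onset, 0.4, spurious))
        fillers[i] = [onset + 0.4, dur - 0.4, label]
    raw.extend((o, d, l) for o, d, l in fillers)
    train = EventTrain.from_records(raw, trial_duration=music_dur)
    return train, chills


def _event_regressor(chills, n_vol, tr):
    """HRF-convolved boxcar of the chill events on the volume grid."""
    fine = 0.1
    n_fine = int(round(n_vol * tr / fine))
    box = np.zeros(n_fine)
    for o, d in chills:
        i0 = int(round(o / fine))
        i1 = min(n_fine, int(round((o + d) / fine)))
        box[i0:i1] = 1.0
    h = canonical_hrf(np.arange(0.0, 30.0, fine))
    reg = np.convolve(box, h)[:n_fine] * fine
    idx = np.round(np.arange(n_vol) * tr / fine).astype(int)
    idx = np.clip(idx, 0, n_fine - 1)
    return reg[idx]


def _simulate_physio(rng, chills, cfg: SimulationConfig, g: float):
    n = int(round(cfg.music_duration * cfg.physio_rate))
    t = np.arange(n) / cfg.physio_rate
    # electrodermal: tonic drift + event-locked phasic responses + noise
    phase = rng.uniform(0, 2 * np.pi)
    tonic = 2.0 + 0.3 * np.sin(2 * np.pi * t / 90.0 + phase) + 5e-4 * t
    driver = np.zeros(n)
    for o, _ in chills:
        amp = cfg.scr_amp * max(0.1, 1.0 + 0.5 * g) * rng.lognormal(0.0, 0.4)
        # sympathetic responses lag the felt onset by a couple of seconds
        latency = max(0.5, 2.0 + rng.normal(0.0, 0.3))
        driver[min(n - 1, int(round((o + latency) * cfg.physio_rate)))] += amp
    h = scr_impulse_response(np.arange(0.0, 40.0, 1.0 / cfg.physio_rate),
                             cfg.scr_tau1, cfg.scr_tau2)
    phasic = np.convolve(driver, h)[:n]
    eda = tonic + phasic + rng.normal(0.0, 0.01, n)
    # photoplethysmogram: bumps at slowly modulated inter-beat intervals
    ibi0 = 60.0 / cfg.heart_rate_bpm
    beats = []
    tb = float(rng.uniform(0, ibi0))
    while tb < cfg.music_duration:
        beats.append(tb)
        tb += ibi0 * (1.0 + 0.05 * np.sin(2 * np.pi * tb / 25.0)
                      + rng.normal(0.0, 0.02))
    ppg = rng.normal(0.0, 0.02, n)
    sig = 0.06
    half = int(4 * sig * cfg.physio_rate)
    for tb in beats:
        c = int(round(tb * cfg.physio_rate))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        tt = t[lo:hi] - tb
        ppg[lo:hi] += np.exp(-0.5 * (tt / sig) ** 2)
    # respiration: ~0.25 Hz oscillation
    resp = 0.5 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    resp = resp + rng.normal(0.0, 0.05, n)
    rate = cfg.physio_rate
    return {
        "ppg": PhysioTrace(channel="ppg", rate=rate, samples=ppg),
        "respiration": PhysioTrace(channel="respiration", rate=rate, samples=resp),
        "eda": PhysioTrace(channel="eda", rate=rate, samples=eda),
    }


def simulate_cohort(config: SimulationConfig | None = None) -> CohortDataset:
    """Generate a complete cohort under ``config`` (defaults if None)."""
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    parc = simulate_parcellation(cfg.rois_per_network, seed=cfg.seed)
    p = parc.n_rois
    nets = np.asarray(parc.network)
    aud_idx = np.where(nets == "auditory")[0]
    rew_idx = np.where(nets == "reward")[0]
    C_base = _base_correlation(parc, cfg.base_within_r, cfg.base_cross_r)
    chol_base = np.linalg.cholesky(C_base)
    planted = edge_list(parc, mode="network_pair", networks=("auditory", "reward"))

    n, T = cfg.n_participants, cfg.n_trials
    g_part = rng.normal(0.0, cfg.coupling_sd, size=n)
    g_trial = g_part[:, None] + rng.normal(0.0, cfg.coupling_trial_sd, size=(n, T))
    obs_noise = rng.normal(0.0, cfg.obs_noise_sd, size=(n, T))
    y_max = cfg.music_duration - 10.0
    true_target = np.clip(cfg.baseline_duration + cfg.effect_size * g_trial,
                          0.0, y_max)
    y_obs = np.clip(cfg.baseline_duration + cfg.effect_size * g_trial + obs_noise,
                    0.0, y_max)

    n_vol_rest = int(round(cfg.rest_duration / cfg.tr))
    n_vol_music = int(round(cfg.music_duration / cfg.tr))
    ar_idx = np.concatenate([aud_idx, rew_idx])

    trials: dict = {}
    for i in range(n):
        pid = f"sub-{i + 1:02d}"
        for tix in range(T):
            tid = f"trial-{tix + 1:02d}"
            g = float(g_trial[i, tix])
            C = C_base.copy()
            # shared auditory-reward component: adds its variance to every
            # pairwise covariance inside the auditory+reward block; ROI
            # variances stay 1 (the idiosyncratic part absorbs it)
            C[np.ix_(ar_idx, ar_idx)] += cfg.shared_component_var(g)
            np.fill_diagonal(C, 1.0)
            chol = np.linalg.cholesky(C)
            rest_data = _ar_mvn(rng, chol, n_vol_rest, cfg.ar_coef)
            drift = rng.uniform(-0.02, 0.02, size=p)
            rest_data = (cfg.bold_baseline + cfg.bold_noise_sd * rest_data
                         + np.arange(n_vol_rest)[:, None] * drift
                         * cfg.bold_noise_sd)
            rest = RoiTimeSeries(participant_id=pid, trial_id=tid,
                                 epoch="task_rest", tr=cfg.tr, data=rest_data,
                                 roi_ids=parc.roi_ids)
            events, chills = _make_trial_events(rng, float(y_obs[i, tix]),
                                                cfg.music_duration)
            music_data = cfg.bold_baseline + cfg.bold_noise_sd * _ar_mvn(
                rng, chol_base, n_vol_music, cfg.ar_coef)
            if chills:
                reg = _event_regressor(chills, n_vol_music, cfg.tr)
                amp = cfg.bold_response_amp * max(0.0, 1.0 + 0.5 * g)
                music_data[:, rew_idx] += amp * reg[:, None]
            music = RoiTimeSeries(participant_id=pid, trial_id=tid,
                                  epoch="music", tr=cfg.tr, data=music_data,
                                  roi_ids=parc.roi_ids)
            physio = _simulate_physio(rng, chills, cfg, g)
            trials[(pid, tid)] = TrialData(rest=rest, music=music,
                                           events=events, physio=physio)

    intrinsic = None
    if cfg.include_intrinsic:
        n_vol_intr = int(round(cfg.intrinsic_duration / cfg.tr))
        intrinsic = {}
        for i in range(n):
            pid = f"sub-{i + 1:02d}"
            data = cfg.bold_baseline + cfg.bold_noise_sd * _ar_mvn(
                rng, chol_base, n_vol_intr, cfg.ar_coef)
            intrinsic[pid] = RoiTimeSeries(
                participant_id=pid, trial_id="intrinsic", epoch="intrinsic_rest",
                tr=cfg.tr, data=data, roi_ids=parc.roi_ids)

    gt = GroundTruth(participant_coupling=g_part, trial_coupling=g_trial,
                     planted_edges=planted, true_target=true_target,
                     baseline=cfg.baseline_duration, effect_size=cfg.effect_size)
    return CohortDataset(parcellation=parc, config=cfg, trials=trials,
                         ground_truth=gt, intrinsic=intrinsic)


def planted_edge_covariance(dataset: CohortDataset) -> np.ndarray:
    """Mean sample covariance over planted edges, per participant x trial.

    Estimated from the raw rest epochs (columns standardised per epoch);
    used to verify that the planted connectivity signal rises with the
    latent coupling.
    """
    parc = dataset.parcellation
    pos = {r: i for i, r in enumerate(parc.roi_ids)}
    ij = np.array([(pos[a], pos[b]) for a, b in dataset.ground_truth.planted_edges])
    pids = dataset.participant_ids
    out = np.zeros((len(pids), dataset.config.n_trials))
    for pi, pid in enumerate(pids):
        for ti, tid in enumerate(dataset.trial_ids(pid)):
            X = dataset.trials[(pid, tid)].rest.data
            Xc = X - X.mean(axis=0)
            Xc = Xc / Xc.std(axis=0)
            n = Xc.shape[0]
            vals = np.einsum("ti,ti->i", Xc[:, ij[:, 0]], Xc[:, ij[:, 1]]) / n
            out[pi, ti] = vals.mean()
    return out


# ---------------------------------------------------------------------------
# cohort directory I/O


def _trial_stub(pid: str, tid: str) -> str:
    return f"{pid}_{tid}"


def save_cohort(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write a cohort directory (TSV/JSON formats).

    Layout: ``parcellation.tsv``, ``cohort.json`` (config),
    ``ground_truth.json``, and per trial
    ``sub-XX_trial-YY_epoch-{taskrest,music}_bold.tsv``,
    ``sub-XX_trial-YY_events.tsv``, ``sub-XX_trial-YY_physio.tsv.gz``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.parcellation.to_frame().to_csv(out / "parcellation.tsv", sep="\t",
                                           index=False)
    (out / "cohort.json").write_text(
        json.dumps(dataset.config.to_dict(), indent=1))
    (out / "ground_truth.json").write_text(
        json.dumps(dataset.ground_truth.to_dict()))
    for (pid, tid), trial in dataset.trials.items():
        stub = _trial_stub(pid, tid)
        for name, series in (("taskrest", trial.rest), ("music", trial.music)):
            pd.DataFrame(series.data, columns=series.roi_ids).to_csv(
                out / f"{stub}_epoch-{name}_bold.tsv", sep="\t", index=False,
                float_format="%.6f")
        trial.events.events.to_csv(out / f"{stub}_events.tsv", sep="\t",
                                   index=False, float_format="%.10g")
        ph = trial.physio
        rate = ph["ppg"].rate
        df = pd.DataFrame({
            "time": np.arange(ph["ppg"].samples.size) / rate,
            "ppg": ph["ppg"].samples,
            "resp": ph["respiration"].samples,
            "eda": ph["eda"].samples,
        })
        with gzip.open(out / f"{stub}_physio.tsv.gz", "wt") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.5f")
    if dataset.intrinsic:
        for pid, series in dataset.intrinsic.items():
            pd.DataFrame(series.data, columns=series.roi_ids).to_csv(
                out / f"{pid}_epoch-intrinsic_bold.tsv", sep="\t", index=False,
                float_format="%.6f")
    return out


def load_cohort(in_dir: str | Path) -> CohortDataset:
    """Read a cohort directory written by :func:`save_cohort`."""
    src = Path(in_dir)
    cfg_path = src / "cohort.json"
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing cohort config: {cfg_path}")
    cfg = SimulationConfig.from_dict(json.loads(cfg_path.read_text()))
    parc = ParcellationSpec.from_frame(
        pd.read_csv(src / "parcellation.tsv", sep="\t", dtype=str))
    gt = GroundTruth.from_dict(json.loads((src / "ground_truth.json").read_text()))
    trials: dict = {}
    for i in range(cfg.n_participants):
        pid = f"sub-{i + 1:02d}"
        for tix in range(cfg.n_trials):
            tid = f"trial-{tix + 1:02d}"
            stub = _trial_stub(pid, tid)
            rest_df = pd.read_csv(src / f"{stub}_epoch-taskrest_bold.tsv", sep="\t")
            music_df = pd.read_csv(src / f"{stub}_epoch-music_bold.tsv", sep="\t")
            rest = RoiTimeSeries(participant_id=pid, trial_id=tid,
                                 epoch="task_rest", tr=cfg.tr,
                                 data=rest_df.to_numpy(),
                                 roi_ids=tuple(rest_df.columns))
            music = RoiTimeSeries(participant_id=pid, trial_id=tid,
                                  epoch="music", tr=cfg.tr,
                                  data=music_df.to_numpy(),
                                  roi_ids=tuple(music_df.columns))
            ev_df = pd.read_csv(src / f"{stub}_events.tsv", sep="\t")
            events = EventTrain(events=ev_df, trial_duration=cfg.music_duration)
            with gzip.open(src / f"{stub}_physio.tsv.gz", "rt") as fh:
                ph_df = pd.read_csv(fh, sep="\t")
            physio = {
                "ppg": PhysioTrace("ppg", cfg.physio_rate,
                                   ph_df["ppg"].to_numpy()),
                "respiration": PhysioTrace("respiration", cfg.physio_rate,
                                           ph_df["resp"].to_numpy()),
                "eda": PhysioTrace("eda", cfg.physio_rate,
                                   ph_df["eda"].to_numpy()),
            }
            trials[(pid, tid)] = TrialData(rest=rest, music=music,
                                           events=events, physio=physio)
    intrinsic = None
    intr_files = sorted(src.glob("sub-*_epoch-intrinsic_bold.tsv"))
    if intr_files:
        intrinsic = {}
        for f in intr_files:
            pid = f.name.split("_")[0]
            df = pd.read_csv(f, sep="\t")
            intrinsic[pid] = RoiTimeSeries(
                participant_id=pid, trial_id="intrinsic", epoch="intrinsic_rest",
                tr=cfg.tr, data=df.to_numpy(), roi_ids=tuple(df.columns))
    return CohortDataset(parcellation=parc, config=cfg, trials=trials,
                         ground_truth=gt, intrinsic=intrinsic)
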