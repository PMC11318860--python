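"""Synthetic-cohort generator: parcellation, response kernels, cohorts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from chillconn import (
    SimulationConfig,
    canonical_hrf,
    clean_presses,
    emotion_durations,
    planted_edge_covariance,
    scr_impulse_response,
    simulate_cohort,
    simulate_parcellation,
)
from chillconn.exceptions import InvalidConfigError

from conftest import small_config


class TestParcellation:
    def test_default_is_288_rois_13_networks(self):
        parc = simulate_parcellation()
        assert parc.n_rois == 288
        assert len(parc.networks) == 13
        assert len(parc.rois_in("auditory")) == 12
        assert len(parc.rois_in("auditory", "L")) == 6
        assert len(parc.rois_in("auditory", "R")) == 6
        assert len(parc.rois_in("reward")) == 8

    def test_minimal_map(self):
        parc = simulate_parcellation({"auditory": 2, "reward": 2})
        assert parc.n_rois == 4
        assert set(parc.networks) == {"auditory", "reward"}

    def test_each_roi_in_exactly_one_network(self):
        parc = simulate_parcellation()
        assert len(parc.roi_ids) == len(set(parc.roi_ids))
        assert sum(len(parc.rois_in(n)) for n in parc.networks) == parc.n_rois

    def test_odd_auditory_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_parcellation({"auditory": 3, "reward": 2})

    def test_deterministic_given_seed(self):
        a = simulate_parcellation(seed=5)
        b = simulate_parcellation(seed=5)
        assert a == b


class TestResponseKernels:
    def test_hrf_zero_at_origin_and_before(self):
        assert canonical_hrf(0.0) == 0.0
        assert np.all(canonical_hrf(np.array([-2.0, -0.1])) == 0.0)

    def test_hrf_peaks_between_4_and_7_seconds(self):
        t = np.arange(0, 30, 0.01)
        h = canonical_hrf(t)
        assert 4.0 <= t[np.argmax(h)] <= 7.0

    def test_hrf_positive_net_response(self):
        t = np.arange(0, 30, 0.01)
        assert np.trapezoid(canonical_hrf(t), t) > 0

    def test_scr_kernel_zero_at_origin_nonnegative(self):
        t = np.arange(0, 60, 0.01)
        h = scr_impulse_response(t, 0.75, 2.0)
        assert scr_impulse_response(0.0, 0.75, 2.0) == 0.0
        assert np.all(h >= 0)

    def test_scr_kernel_peak_matches_closed_form(self):
        tau1, tau2 = 0.75, 2.0
        t = np.arange(0, 20, 1e-4)
        peak = t[np.argmax(scr_impulse_response(t, tau1, tau2))]
        expected = np.log(tau2 / tau1) * tau1 * tau2 / (tau2 - tau1)
        assert peak == pytest.approx(expected, abs=1e-3)

    def test_scr_kernel_rejects_bad_taus(self):
        with pytest.raises(InvalidConfigError):
            scr_impulse_response(1.0, 2.0, 2.0)


class TestCohort:
    def test_same_seed_identical_dataset(self):
        cfg = small_config(seed=3)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        key = ("sub-01", "trial-01")
        assert np.array_equal(a.trials[key].rest.data, b.trials[key].rest.data)
        assert np.array_equal(a.trials[key].music.data, b.trials[key].music.data)
        assert a.trials[key].events.events.equals(b.trials[key].events.events)
        assert np.array_equal(a.trials[key].physio["eda"].samples,
                              b.trials[key].physio["eda"].samples)
        assert np.array_equal(a.ground_truth.trial_coupling,
                              b.ground_truth.trial_coupling)

    def test_every_trial_fully_populated(self, small_cohort):
        cfg = small_cohort.config
        assert len(small_cohort.trials) == cfg.n_participants * cfg.n_trials
        for trial in small_cohort.trials.values():
            assert trial.rest.n_volumes == round(cfg.rest_duration / cfg.tr)
            assert trial.music.n_volumes == round(cfg.music_duration / cfg.tr)
            ev = trial.events.events
            assert (ev["onset"] + ev["duration"]
                    <= cfg.music_duration + 1e-6).all()
            for ch in ("ppg", "respiration", "eda"):
                assert trial.physio[ch].duration == pytest.approx(
                    cfg.music_duration)

    def test_cleaned_chill_totals_match_planted_targets(self, small_cohort):
        """Event trains are built so cleaning recovers the drawn duration."""
        cfg = small_cohort.config
        gt = small_cohort.ground_truth
        for pi, pid in enumerate(small_cohort.participant_ids):
            for ti, tid in enumerate(small_cohort.trial_ids(pid)):
                total = emotion_durations(
                    clean_presses(small_cohort.trials[(pid, tid)].events)
                ).durations["chill"]
                assert 0 <= total <= cfg.music_duration

    def test_null_cohorts_have_no_brain_behavior_coupling(self):
        rs = []
        for seed in range(8):
            cfg = small_config(n_participants=12, effect_size=0.0, seed=100 + seed)
            ds = simulate_cohort(cfg)
            fc = planted_edge_covariance(ds).mean(axis=1)
            y = ds.ground_truth.true_target.mean(axis=1)
            if np.std(y) == 0:  # effect 0 -> constant noiseless target
                y = np.array([
                    emotion_durations(clean_presses(
                        ds.trials[(pid, tid)].events)).durations["chill"]
                    for pid in ds.participant_ids
                    for tid in ds.trial_ids(pid)
                ]).reshape(12, -1).mean(axis=1)
            rs.append(np.corrcoef(fc, y)[0, 1])
        assert abs(np.mean(rs)) < 2 / np.sqrt(12)

    def test_planted_signal_recovered_across_replicate_cohorts(self):
        """At a strong effect and low noise the planted-edge connectivity
        tracks mean chills duration across participants."""
        rs = []
        for seed in range(20):
            cfg = small_config(n_participants=38, n_trials=2,
                               obs_noise_sd=5.0, seed=200 + seed)
            ds = simulate_cohort(cfg)
            fc = planted_edge_covariance(ds).mean(axis=1)
            y = np.array([
                np.mean([emotion_durations(clean_presses(
                    ds.trials[(pid, tid)].events)).durations["chill"]
                    for tid in ds.trial_ids(pid)])
                for pid in ds.participant_ids
            ])
            rs.append(np.corrcoef(fc, y)[0, 1])
        assert np.mean(rs) > 0.5

    def test_planted_covariance_rises_with_coupling(self, small_cohort):
        fc = planted_edge_covariance(small_cohort)
        g = small_cohort.ground_truth.trial_coupling
        rho = spearmanr(g.ravel(), fc.ravel()).statistic
        assert rho > 0.2

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_participants=0).validate()
        with pytest.raises(InvalidConfigError):
            SimulationConfig(tr=-1.0).validate()
        with pytest.raises(InvalidConfigError):
            SimulationConfig(
                rois_per_network={"auditory": 3, "reward": 2}).validate()
        with pytest.raises(InvalidConfigError):
            SimulationConfig(effect_size=-1.0).validate()
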