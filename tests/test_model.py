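"""LASSO decoding: fits, nested CV, transfer, sweeps, learning curves."""

import numpy as np
import pytest

from chillconn import (
    DEFAULT_LAMBDA_GRID,
    fit_transfer_model,
    lasso_fit,
    learning_curve,
    nested_loocv,
    nested_lotocv,
    transfer_predict,
    trial_outlier_filter,
    window_sweep,
)
from chillconn import _solver
from chillconn.exceptions import AlignmentError, InsufficientDataError

from conftest import small_config


def planted_data(n=38, p=96, beta=1.0, noise=0.1, seed=0, latent=True):
    rng = np.random.default_rng(seed)
    if latent:
        g = rng.normal(size=n)
        X = 0.05 * g[:, None] + rng.normal(scale=0.08, size=(n, p))
        y = 50 + 30 * g + rng.normal(scale=3.0, size=n)
    else:
        X = rng.normal(size=(n, p))
        y = beta * X[:, 0] + rng.normal(scale=noise, size=n)
    return X, y


class TestLassoFit:
    def test_huge_penalty_gives_null_model(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        fit = lasso_fit(X, y, lam=1e6)
        assert np.allclose(fit.weights, 0.0)
        assert fit.intercept == pytest.approx(y.mean())

    def test_zero_penalty_is_ols(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        fit = lasso_fit(X, y, lam=0.0)
        Xs = (X - X.mean(0)) / X.std(0)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(50), Xs]), y, rcond=None)
        assert np.allclose(fit.weights, coef[1:], atol=1e-8)

    def test_orthonormal_design_soft_threshold(self):
        rng = np.random.default_rng(1)
        n, p = 64, 8
        Z = rng.normal(size=(n, p))
        Z -= Z.mean(axis=0)
        Q, _ = np.linalg.qr(Z)   # zero-mean orthonormal columns
        X = Q * np.sqrt(n)       # population SD exactly 1
        y = rng.normal(size=n)
        lam = 0.3
        fit = lasso_fit(X, y, lam=lam)
        ols = (X.T @ (y - y.mean())) / n  # X already standardised, X'X/n = I
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        assert np.allclose(fit.weights, expected, atol=1e-4)

    def test_cd_and_homotopy_routes_agree(self, rng):
        """Public coordinate-descent fits match the exact path kernel."""
        X = rng.normal(size=(30, 50))
        y = rng.normal(size=30) * 5
        for lam in (0.01, 0.1, 1.0, 10.0):
            cd = lasso_fit(X, y, lam=lam)
            w, mu, sd, b = _solver.fit_at_lambda(
                np.ascontiguousarray(X), np.ascontiguousarray(y), lam)
            assert np.allclose(cd.weights, w, atol=2e-5)
            assert cd.intercept == pytest.approx(b, abs=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lasso_fit(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]), 1.0)


class TestNestedLoocv:
    def test_recovers_single_informative_feature(self):
        rng = np.random.default_rng(7)
        n = 38
        X = rng.normal(size=(n, 38))
        y = 3.0 * X[:, 0] + rng.normal(scale=0.3, size=n)
        cv = nested_loocv(X, y)
        assert cv.accuracy_r > 0.9

    def test_null_accuracy_centred_on_zero(self):
        accs = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(16, 8))
            y = rng.normal(size=16)
            accs.append(nested_loocv(X, y).accuracy_r)
        mean = np.nanmean(accs)
        assert -0.15 < mean < 0.15

    def test_no_leakage_from_held_out_target(self):
        X, y = planted_data(seed=3)
        cv = nested_loocv(X, y)
        y2 = y.copy()
        y2[5] += 1000.0
        cv2 = nested_loocv(X, y2)
        assert cv2.y_pred[5] == pytest.approx(cv.y_pred[5], abs=1e-9)

    def test_one_prediction_per_unit_and_grid_lambdas(self):
        X, y = planted_data(n=12, p=6, seed=5)
        cv = nested_loocv(X, y)
        assert cv.n_units == 12
        assert cv.y_pred.shape == (12,)
        assert set(np.unique(cv.fold_lambdas)) <= set(DEFAULT_LAMBDA_GRID)

    def test_too_few_units(self):
        with pytest.raises(InsufficientDataError):
            nested_loocv(np.zeros((3, 2)), np.arange(3.0))

    def test_duplicated_trials_predicted_identically(self):
        X, y = planted_data(n=10, p=5, seed=11)
        Xd = np.vstack([X, X[:1]])
        yd = np.append(y, y[0])
        cv = nested_lotocv(Xd, yd)
        assert cv.y_pred[0] == pytest.approx(cv.y_pred[-1], abs=1e-8)


class TestTrialOutlierFilter:
    def test_all_equal_none_removed(self):
        assert trial_outlier_filter(np.full(20, 5.0)).all()

    def test_one_extreme_high_removed_low_kept(self):
        rng = np.random.default_rng(0)
        y = rng.normal(50, 5, 300)
        y[7] = 300.0
        keep = trial_outlier_filter(y)
        assert not keep[7]
        assert keep.sum() == 299
        y2 = rng.normal(50, 5, 300)
        y2[7] = -200.0  # the screen is one-sided: low values stay
        assert trial_outlier_filter(y2).all()


class TestTransfer:
    def test_support_recovery_on_planted_effect(self):
        X, y = planted_data(seed=21, latent=False, beta=5.0, noise=0.2, p=20)
        fit = fit_transfer_model(X, y)
        assert 0 in fit.support
        assert fit.support.size < 10

    def test_null_target_transfers_at_chance(self):
        """With no signal the exported decoder generalises at chance:
        its out-of-cohort predictions are uncorrelated with new targets."""
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(800 + seed)
            Xa, ya = rng.normal(size=(30, 40)), rng.normal(size=30)
            Xb, yb = rng.normal(size=(30, 40)), rng.normal(size=30)
            fit = fit_transfer_model(Xa, ya)
            yhat = transfer_predict(fit, Xb)
            if np.std(yhat) > 0:
                rs.append(np.corrcoef(yhat, yb)[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_in_sample_round_trip(self):
        X, y = planted_data(seed=2)
        fit = fit_transfer_model(X, y)
        assert np.allclose(transfer_predict(fit, X), fit.predict(X))

    def test_edge_alignment_and_mismatch(self):
        X, y = planted_data(n=12, p=4, seed=4)
        edges = (("a", "b"), ("a", "c"), ("b", "c"), ("b", "d"))
        fit = fit_transfer_model(X, y, edges=edges)
        perm = [2, 0, 3, 1]
        out = transfer_predict(fit, X[:, perm],
                               edges_new=[edges[i] for i in perm])
        assert np.allclose(out, fit.predict(X))
        with pytest.raises(AlignmentError):
            transfer_predict(fit, X[:, :3], edges_new=edges[:3])

    def test_zero_weight_model_constant_predictions(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        fit = fit_transfer_model(X, y * 0 + 5.0)
        out = transfer_predict(fit, rng.normal(size=(7, 5)))
        assert np.allclose(out, out[0])

    def test_transfer_to_replicate_cohort_positive(self):
        """A decoder fit on one planted cohort predicts another."""
        Xa, ya = planted_data(seed=31)
        Xb, yb = planted_data(seed=32)
        fit = fit_transfer_model(Xa, ya)
        yhat = transfer_predict(fit, Xb)
        assert np.corrcoef(yhat, yb)[0, 1] > 0.3


@pytest.fixture(scope="module")
def sweep_cohort():
    from chillconn import simulate_cohort
    return simulate_cohort(small_config(n_participants=8, seed=17))


class TestWindowSweep:

    def test_cumulative_window_count_and_geometry(self, sweep_cohort):
        rows = window_sweep(sweep_cohort, mode="cumulative", shrinkage=0.5)
        assert len(rows) == 11  # 20, 22, ..., 40 s
        assert rows[0]["window"] == (20.0, 40.0)
        assert rows[-1]["window"] == (0.0, 40.0)

    def test_sliding_window_count(self, sweep_cohort):
        rows = window_sweep(sweep_cohort, mode="sliding", width=26.0, step=2.0,
                            shrinkage=0.5)
        assert len(rows) == 8  # 0-26 ... 14-40
        assert rows[0]["window"] == (0.0, 26.0)
        assert rows[-1]["window"] == (14.0, 40.0)

    def test_single_full_window_matches_plain_cv(self, sweep_cohort):
        from chillconn.features import participant_features, participant_targets
        rows = window_sweep(sweep_cohort, durations=[40.0], mode="cumulative",
                            shrinkage=0.5)
        _, X, _ = participant_features(sweep_cohort, window=(0.0, 40.0),
                                       shrinkage=0.5)
        _, y = participant_targets(sweep_cohort)
        cv = nested_loocv(X, y)
        assert rows[0]["accuracy_r"] == pytest.approx(cv.accuracy_r, abs=1e-12)

    def test_oversized_window_rejected(self, sweep_cohort):
        with pytest.raises(ValueError):
            window_sweep(sweep_cohort, durations=[60.0], mode="cumulative")


class TestLearningCurve:
    def test_full_fraction_matches_plain_cv_and_reproducible(self):
        X, y = planted_data(n=20, p=10, seed=13)
        out = learning_curve(X, y, fractions=(0.5, 1.0), reps=3, seed=5)
        assert out[-1]["mean_accuracy"] == pytest.approx(
            nested_loocv(X, y).accuracy_r)
        out2 = learning_curve(X, y, fractions=(0.5, 1.0), reps=3, seed=5)
        assert np.array_equal(out[0]["accuracies"], out2[0]["accuracies"])

    def test_accuracy_grows_with_sample_size_on_planted_effect(self):
        """More training units should help, on average, when a real effect
        is present."""
        lo, hi = [], []
        for seed in range(6):
            X, y = planted_data(n=30, p=20, seed=40 + seed)
            out = learning_curve(X, y, fractions=(0.35, 1.0), reps=4,
                                 seed=seed)
            lo.append(out[0]["mean_accuracy"])
            hi.append(out[1]["mean_accuracy"])
        assert np.mean(hi) > np.mean(lo)
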