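"""Partial-correlation features, edge selection, window sampling."""

import numpy as np
import pytest

from chillconn import (
    ConnectivityFeatures,
    average_features,
    connectivity_features,
    edge_list,
    fisher_z,
    list_network_pairs,
    pairs_containing,
    partial_corr_matrix,
    sample_intrinsic_windows,
    select_edges,
    simulate_parcellation,
)
from chillconn.exceptions import EmptyAverageError, SamplingError, UndefinedCorrelationError
from chillconn.preprocess import RoiTimeSeries


def series_from(data, tr=2.0, ids=None, epoch="task_rest"):
    data = np.asarray(data, float)
    ids = ids or tuple(f"r{i}" for i in range(data.shape[1]))
    return RoiTimeSeries("s", "t", epoch, tr, data, ids)


class TestPartialCorr:
    def test_two_rois_equals_plain_pearson(self, rng):
        X = rng.normal(size=(200, 2))
        X[:, 1] += 0.5 * X[:, 0]
        pc = partial_corr_matrix(series_from(X), shrinkage=0.0)
        assert pc[0, 1] == pytest.approx(np.corrcoef(X.T)[0, 1], abs=1e-10)

    def test_trivariate_equicorrelated_limit(self):
        # for Sigma with all off-diagonals 0.5, pcorr(i,j|k) = 1/3 exactly
        rng = np.random.default_rng(42)
        S = np.full((3, 3), 0.5)
        np.fill_diagonal(S, 1.0)
        X = rng.multivariate_normal(np.zeros(3), S, size=5000)
        pc = partial_corr_matrix(series_from(X), shrinkage=0.0)
        assert pc[0, 1] == pytest.approx(1 / 3, abs=0.05)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(9)
        n = 2000
        X = rng.normal(size=(n, 5))
        pc = partial_corr_matrix(series_from(X), shrinkage=0.0)
        off = pc[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 3 / np.sqrt(n)

    def test_constant_column_names_roi(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 4.0
        with pytest.raises(UndefinedCorrelationError, match="r1"):
            partial_corr_matrix(series_from(X))

    def test_auto_shrinkage_reported_and_matrix_valid(self, rng):
        X = rng.normal(size=(15, 40))
        pc, alpha = partial_corr_matrix(series_from(X), return_shrinkage=True)
        assert 0 < alpha <= 1
        assert np.allclose(pc, pc.T)
        assert np.all(np.abs(pc) <= 1.0)
        assert np.allclose(np.diag(pc), 1.0)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(100, 6))
        perm = rng.permutation(6)
        pc = partial_corr_matrix(series_from(X), shrinkage=0.1)
        pc_p = partial_corr_matrix(series_from(X[:, perm]), shrinkage=0.1)
        assert np.allclose(pc_p, pc[np.ix_(perm, perm)], atol=1e-10)


class TestFisherZ:
    def test_values_and_oddness(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        r = np.array([-0.7, -0.2, 0.2, 0.7])
        assert np.allclose(fisher_z(-r), -fisher_z(r))

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            z = fisher_z(np.array([1.0]))
        assert np.isfinite(z).all()


class TestEdgeSelection:
    def test_feature_counts_default_parcellation(self, default_parcellation):
        parc = default_parcellation
        assert len(edge_list(parc, "network_pair",
                             ("auditory", "reward"))) == 96
        assert len(edge_list(parc, "hemispheric",
                             ("auditory", "reward"), side="R")) == 45
        assert len(edge_list(parc, "whole_brain")) == 288 * 287 // 2

    def test_network_pair_edges_all_cross(self, default_parcellation):
        parc = default_parcellation
        net = dict(zip(parc.roi_ids, parc.network))
        for a, b in edge_list(parc, "network_pair", ("auditory", "reward")):
            assert {net[a], net[b]} == {"auditory", "reward"}

    def test_unknown_network_raises(self, default_parcellation):
        with pytest.raises(KeyError):
            edge_list(default_parcellation, "network_pair",
                      ("auditory", "no_such_net"))

    def test_select_edges_reads_matrix_positions(self):
        parc = simulate_parcellation({"auditory": 2, "reward": 2})
        m = np.arange(16, dtype=float).reshape(4, 4)
        m = (m + m.T) / 2
        feats = select_edges(m, parc, "network_pair", ("auditory", "reward"))
        pos = {r: i for i, r in enumerate(parc.roi_ids)}
        for (a, b), v in zip(feats.edges, feats.values):
            assert v == m[pos[a], pos[b]]

    def test_relabeling_invariance(self, rng):
        """Feature values depend on ROI identity, not column order."""
        parc = simulate_parcellation({"auditory": 4, "reward": 2})
        X = rng.normal(size=(120, 6))
        s1 = series_from(X, ids=parc.roi_ids)
        f1 = connectivity_features(s1, parc, shrinkage=0.1)
        perm = rng.permutation(6)
        parc2_ids = tuple(parc.roi_ids[i] for i in perm)
        from chillconn import ParcellationSpec
        parc2 = ParcellationSpec(
            roi_ids=parc2_ids,
            network=tuple(parc.network[i] for i in perm),
            hemisphere=tuple(parc.hemisphere[i] for i in perm))
        f2 = connectivity_features(series_from(X[:, perm], ids=parc2_ids),
                                   parc2, shrinkage=0.1)
        assert f1.edges == f2.edges
        assert np.allclose(f1.values, f2.values, atol=1e-10)


class TestNetworkPairs:
    def test_thirteen_networks_give_78_pairs(self, default_parcellation):
        pairs = list_network_pairs(default_parcellation)
        assert len(pairs) == 78
        aud = pairs_containing(pairs, "auditory")
        assert len(aud) == 12
        assert len(pairs) - len(aud) == 66

    def test_two_networks_one_pair(self):
        parc = simulate_parcellation({"auditory": 2, "reward": 2})
        assert list_network_pairs(parc) == (("auditory", "reward"),)


class TestAveraging:
    def _feats(self, values):
        edges = tuple((f"a{i}", f"b{i}") for i in range(len(values)))
        return ConnectivityFeatures(values=np.asarray(values, float),
                                    edges=edges)

    def test_single_trial_identity(self):
        f = self._feats([0.1, -0.2])
        out = average_features([f])
        assert np.array_equal(out.values, f.values)
        assert out.n_averaged == 1

    def test_opposite_trials_cancel(self):
        out = average_features([self._feats([0.3, -0.1]),
                                self._feats([-0.3, 0.1])])
        assert np.allclose(out.values, 0.0)

    def test_missing_trials_dropped_and_counted(self):
        feats = [self._feats([1.0]) for _ in range(7)] + [None]
        out = average_features(feats)
        assert out.n_averaged == 7
        assert out.values[0] == pytest.approx(1.0)

    def test_all_missing_raises(self):
        with pytest.raises(EmptyAverageError):
            average_features([None, None])


@pytest.fixture(scope="module")
def long_rest():
    rng = np.random.default_rng(5)
    parc = simulate_parcellation({"auditory": 4, "reward": 2})
    S = np.full((6, 6), 0.2)
    np.fill_diagonal(S, 1.0)
    X = rng.multivariate_normal(np.zeros(6), S, size=300)
    return parc, series_from(X, ids=parc.roi_ids, epoch="intrinsic_rest")


class TestIntrinsicSampling:

    def test_seed_reproducibility(self, long_rest):
        parc, s = long_rest
        a = sample_intrinsic_windows(s, k=4, window=18.0, reps=2, seed=3,
                                     parcellation=parc, shrinkage=0.3)
        b = sample_intrinsic_windows(s, k=4, window=18.0, reps=2, seed=3,
                                     parcellation=parc, shrinkage=0.3)
        assert np.array_equal(a.values, b.values)

    def test_infeasible_packing_rejected(self, long_rest):
        parc, s = long_rest
        with pytest.raises(SamplingError):
            sample_intrinsic_windows(s, k=40, window=18.0, reps=1, seed=0,
                                     parcellation=parc)

    def test_rep_averaging_shrinks_sampling_noise(self, long_rest):
        """More repetitions -> less Monte-Carlo spread of the estimate."""
        parc, s = long_rest

        def spread(reps):
            ests = [sample_intrinsic_windows(
                s, k=4, window=18.0, reps=reps, seed=100 + i,
                parcellation=parc, shrinkage=0.3).values
                for i in range(6)]
            return np.mean(np.std(ests, axis=0))

        assert spread(16) < spread(1)
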