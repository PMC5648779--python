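import numpy as np
import pytest
from hypothesis import given, strategies as st

import kinescape as ks
from kinescape.errors import EstimationError
from kinescape.msm import CountMatrix, DiscreteTrajectorySet

from oracles import random_reversible_chain


def feature_matrix_1d(values, tids=None):
    values = np.asarray(values, float)
    tids = np.zeros(len(values), dtype=int) if tids is None else np.asarray(tids, int)
    return ks.FeatureMatrix(["x"], values[:, None], tids, 1.0)


def dtraj_of(labels, n_states=None, tids=None, interval=1.0):
    labels = np.asarray(labels, int)
    if n_states is None:
        n_states = labels.max() + 1
    tids = np.zeros(labels.size, dtype=int) if tids is None else np.asarray(tids, int)
    return DiscreteTrajectorySet(labels, tids, n_states, interval)


class TestKCenters:
    def test_identical_frames_collapse_to_one_state(self):
        fm = feature_matrix_1d([3.0, 3.0, 3.0, 3.0])
        dtraj, centers = ks.kcenters_cluster(fm, radius=1.0)
        assert dtraj.n_states == 1
        assert np.array_equal(dtraj.state_labels, [0, 0, 0, 0])

    def test_hand_executed_example(self):
        fm = feature_matrix_1d([0.0, 0.5, 10.0, 10.2])
        dtraj, centers = ks.kcenters_cluster(fm, radius=2.0)
        assert dtraj.n_states == 2
        assert np.array_equal(dtraj.state_labels, [0, 0, 1, 1])
        assert set(centers.tolist()) == {0, 3}

    def test_tiny_radius_gives_singletons(self):
        vals = np.array([0.0, 4.0, 9.0, 15.0])
        dtraj, _ = ks.kcenters_cluster(feature_matrix_1d(vals), radius=0.5)
        assert dtraj.n_states == 4

    def test_radius_must_be_positive(self):
        with pytest.raises(EstimationError):
            ks.kcenters_cluster(feature_matrix_1d([0.0]), radius=0.0)

    @given(st.integers(0, 2**32 - 1), st.sampled_from([0.5, 1.0, 2.0, 4.0]))
    def test_covering_radius_guarantee(self, seed, radius):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 20, size=40)
        fm = feature_matrix_1d(x)
        dtraj, centers = ks.kcenters_cluster(fm, radius=radius)
        dist = np.abs(x[:, None] - x[centers][None, :]).min(axis=1)
        assert dist.max() <= radius + 1e-12

    def test_state_count_non_increasing_in_radius(self):
        rng = np.random.default_rng(7)
        fm = feature_matrix_1d(rng.uniform(0, 30, size=60))
        counts = [ks.kcenters_cluster(fm, radius=r)[0].n_states for r in (0.5, 1.0, 2.0, 5.0)]
        assert counts == sorted(counts, reverse=True)

    def test_rmsd_metric_clusters_conformations(self):
        # two well-separated conformations of the pseudo-protein
        latent = np.array([[8.0, 11.0]] * 3 + [[15.0, 3.0]] * 3)
        frames = ks.embed_pseudo_atoms(latent)
        dtraj, _ = ks.kcenters_cluster(frames, radius=2.0, metric="backbone_rmsd")
        assert dtraj.n_states == 2
        assert len(set(dtraj.state_labels[:3])) == 1
        assert len(set(dtraj.state_labels[3:])) == 1


class TestCountTransitions:
    def test_constant_trajectory(self):
        cm = ks.count_transitions(dtraj_of([0, 0, 0]), 1)
        assert np.array_equal(cm.counts, [[2.0]])

    def test_alternating_lag_one(self):
        cm = ks.count_transitions(dtraj_of([0, 1, 0, 1]), 1)
        assert np.array_equal(cm.counts, [[0.0, 2.0], [1.0, 0.0]])

    def test_alternating_lag_two(self):
        cm = ks.count_transitions(dtraj_of([0, 1, 0, 1]), 2)
        assert np.array_equal(cm.counts, [[1.0, 0.0], [0.0, 1.0]])

    def test_no_counting_across_trajectory_boundaries(self):
        labels = [0, 0, 1, 1]
        tids = [0, 0, 1, 1]
        cm = ks.count_transitions(dtraj_of(labels, tids=tids), 1)
        assert cm.counts[0, 1] == 0.0
        assert cm.counts[0, 0] == 1.0 and cm.counts[1, 1] == 1.0

    def test_total_count_identity(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=50)
        tids = np.repeat([0, 1, 2], [20, 18, 12])
        for lag in (1, 3, 7):
            cm = ks.count_transitions(dtraj_of(labels, tids=tids), lag)
            expected = sum(max(0, n - lag) for n in (20, 18, 12))
            assert cm.counts.sum() == expected

    def test_strided_mode(self):
        cm = ks.count_transitions(dtraj_of([0, 1, 0, 1, 0]), 2, mode="strided")
        # windows: (0,0) and (0,0) from frames 0->2->4
        assert cm.counts[0, 0] == 2.0
        assert cm.counts.sum() == 2.0

    def test_all_segments_too_short(self):
        with pytest.raises(EstimationError, match="no transitions"):
            ks.count_transitions(dtraj_of([0, 1], tids=[0, 1], n_states=2), 1)


class TestTrimErgodic:
    def test_fully_connected_is_identity(self):
        c = CountMatrix(np.ones((3, 3)), lag_ns=1.0)
        trimmed, mapping = ks.trim_ergodic(c)
        assert np.array_equal(trimmed.counts, c.counts)
        assert np.array_equal(mapping, [0, 1, 2])

    def test_source_only_state_removed(self):
        counts = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [3.0, 0.0, 0.0]])
        trimmed, mapping = ks.trim_ergodic(CountMatrix(counts, lag_ns=1.0))
        assert trimmed.n_states == 2
        assert mapping[2] == -1
        assert np.array_equal(trimmed.counts, counts[:2, :2])

    def test_heavier_component_retained(self):
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = 1.0
        counts[2, 3] = counts[3, 2] = 10.0
        trimmed, mapping = ks.trim_ergodic(CountMatrix(counts, lag_ns=1.0))
        assert np.array_equal(mapping, [-1, -1, 0, 1])

    def test_tie_breaks_to_lowest_index(self):
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = 2.0
        counts[2, 3] = counts[3, 2] = 2.0
        _, mapping = ks.trim_ergodic(CountMatrix(counts, lag_ns=1.0))
        assert np.array_equal(mapping, [0, 1, -1, -1])

    def test_empty_graph_is_an_error(self):
        with pytest.raises(EstimationError, match="empty"):
            ks.trim_ergodic(CountMatrix(np.zeros((2, 2)), lag_ns=1.0))


class TestEstimateModel:
    def test_direct_arithmetic_example(self):
        cm = CountMatrix(np.array([[2.0, 1.0], [3.0, 2.0]]), lag_ns=5.0)
        model = ks.estimate_model(cm)
        assert np.allclose(model.transition_matrix, [[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(model.stationary, [0.5, 0.5])
        assert model.lag_ns == 5.0

    def test_symmetric_counts_are_a_fixed_point(self):
        c = np.array([[4.0, 1.0, 0.5], [1.0, 3.0, 2.0], [0.5, 2.0, 5.0]])
        model = ks.estimate_model(CountMatrix(c, lag_ns=1.0))
        assert np.allclose(model.transition_matrix, c / c.sum(axis=1, keepdims=True))

    @given(st.integers(0, 2**32 - 1))
    def test_estimator_contract_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 8)
        counts = rng.uniform(0.01, 10.0, size=(n, n))
        model = ks.estimate_model(CountMatrix(counts, lag_ns=1.0))
        t, pi = model.transition_matrix, model.stationary
        assert np.allclose(t.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(pi @ t, pi, atol=1e-12)
        flux = pi[:, None] * t
        assert np.max(np.abs(flux - flux.T)) < 1e-14
        # leading left eigenvector oracle
        evals, evecs = np.linalg.eig(t.T)
        lead = np.argmax(np.real(evals))
        v = np.real(evecs[:, lead])
        v = v / v.sum()
        assert np.allclose(pi, v, atol=1e-10)

    def test_zero_row_is_an_error(self):
        counts = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(EstimationError, match="no counts"):
            ks.estimate_model(CountMatrix(counts, lag_ns=1.0))

    def test_representatives_map_states_to_frames(self):
        labels = [0, 1, 0, 1, 1]
        dtraj = dtraj_of(labels)
        model, mapping, relabeled = ks.build_msm(dtraj, 1)
        assert set(model.state_representatives[0].tolist()) == {0, 2}
        assert set(model.state_representatives[1].tolist()) == {1, 3, 4}

    def test_pipeline_determinism(self):
        rng = np.random.default_rng(4)
        fm = feature_matrix_1d(rng.uniform(0, 10, 200))
        out = []
        for _ in range(2):
            dtraj, _ = ks.kcenters_cluster(fm, radius=1.0)
            model, _, _ = ks.build_msm(dtraj, 2)
            out.append(model.transition_matrix)
        assert np.array_equal(out[0], out[1])

    def test_eigenvalues_are_real_and_sorted(self):
        t, pi = random_reversible_chain(6, np.random.default_rng(1))
        model = ks.MarkovModel(transition_matrix=t, lag_ns=1.0, stationary=pi)
        ev = model.eigenvalues()
        assert ev[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(ev) <= 1e-12)
        oracle = np.sort(np.real(np.linalg.eigvals(t)))[::-1]
        assert np.allclose(ev, oracle, atol=1e-10)
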