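import numpy as np
import pandas as pd
import pytest

from cellsort import (
    GeneNetwork,
    build_attractors,
    build_model,
    classify_cluster,
    evolve,
    init_state,
    overlaps,
)
from cellsort.hopfield import SpinState, update_probability
from cellsort.markers import AttractorSet
from cellsort.voting import UNASSIGNED, CentroidMatrix, binarize_zscores

import networkx as nx


def patterns(rows, types=None, genes=None):
    arr = np.asarray(rows, dtype=float)
    types = types or [f"T{i}" for i in range(arr.shape[0])]
    genes = genes or [f"g{i}" for i in range(arr.shape[1])]
    return AttractorSet(pd.DataFrame(arr, index=types, columns=genes))


class TestBuildModel:
    def test_toy_correlation_matrix(self, toy_normalized):
        att = build_attractors(toy_normalized)
        model = build_model(att)
        expected = np.array([[0.104167, 0.041667], [0.041667, 0.083333]])
        np.testing.assert_allclose(model.Q, expected, atol=5e-7)

    def test_single_pattern_coupling_is_half_adjacency(self):
        att = patterns([[1.0, 1.0]])
        model = build_model(att)
        # Q = [1]; J = A/N * xi xi^T = A/2
        np.testing.assert_allclose(model.Q, [[1.0]])
        np.testing.assert_allclose(model.J, model.A / 2.0)

    def test_empty_network_zero_coupling(self):
        att = patterns([[1.0, 1.0], [1.0, 0.5]])
        net = GeneNetwork(nx.empty_graph(["g0", "g1"]))
        model = build_model(att, network=net)
        assert (model.J == 0).all()

    def test_singular_q_uses_pseudoinverse(self):
        att = patterns([[1.0, 1.0], [1.0, 1.0]])  # duplicate patterns
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            model = build_model(att)
        assert np.all(np.isfinite(model.Qinv))


class TestInitState:
    def make_centroids(self, zcol):
        y = pd.DataFrame(
            np.column_stack([np.zeros(len(zcol)), np.ones(len(zcol))]),
            index=[f"g{i}" for i in range(len(zcol))],
        )
        cm = CentroidMatrix(Y=y)
        cm.Z = pd.DataFrame(
            np.column_stack([zcol, -np.asarray(zcol)]), index=y.index
        )
        return cm

    def test_threshold_by_hand(self):
        model = build_model(patterns([[1.0, 1.0, 1.0]]))
        cm = self.make_centroids([0.5, -0.2, 1.1])
        state = init_state(cm, 0, model, zeta=0.3)
        np.testing.assert_array_equal(state.sigma, [1, -1, 1])

    def test_all_below_threshold_all_down(self):
        model = build_model(patterns([[1.0, 1.0, 1.0]]))
        state = init_state(self.make_centroids([-1.0, -2.0, 0.0]), 0, model)
        np.testing.assert_array_equal(state.sigma, [-1, -1, -1])

    def test_minus_infinity_threshold_all_up(self):
        model = build_model(patterns([[1.0, 1.0, 1.0]]))
        state = init_state(self.make_centroids([-9.0, 0.0, 9.0]), 0, model,
                           zeta=-np.inf)
        np.testing.assert_array_equal(state.sigma, [1, 1, 1])

    def test_missing_gene_is_error(self):
        model = build_model(patterns([[1.0, 1.0, 1.0]]))
        cm = self.make_centroids([0.5, 0.5])  # only g0, g1 rows
        with pytest.raises(ValueError, match="missing"):
            init_state(cm, 0, model)


class TestUpdateSchedule:
    def test_ramp_endpoints(self):
        assert update_probability(0) == pytest.approx(0.025)
        assert update_probability(100) == pytest.approx(0.5)
        assert update_probability(500) == pytest.approx(0.5)

    def test_ramp_linear_midpoint(self):
        assert update_probability(50) == pytest.approx(0.2625)


class TestEvolve:
    def test_stored_pattern_is_fixed_point_at_low_temperature(self):
        # single +/-1 memory, complete graph: h_i = xi_i (N-1)/N keeps the
        # sign of every spin, so at tiny temperature the pattern is stable
        xi = np.array([[1.0, 1.0, -1.0, 1.0, -1.0]])
        model = build_model(xi, temperature=1e-3)
        start = SpinState(xi[0].astype(np.int8))
        _, final = evolve(start, model, steps=100, seed=3)
        np.testing.assert_array_equal(final.sigma, xi[0])

    def test_plus_one_never_jumps_directly_to_minus_one(self):
        # J = 0 so every draw is a fair coin at any temperature
        att = patterns([[1.0, 1.0, 1.0, 1.0]])
        net = GeneNetwork(nx.empty_graph(["g0", "g1", "g2", "g3"]))
        model = build_model(att, network=net, temperature=1.0)
        sigma = np.ones(4, dtype=np.int8)
        state = SpinState(sigma)
        seen = set()
        for step in range(60):
            _, state = evolve(state, model, steps=1, seed=step, record=False)
            seen.update(state.sigma.tolist())
        assert -1 not in seen  # +1 parks at 0 and 0 cannot drop to -1

    def test_fixed_seed_bit_identical(self):
        att = patterns([[1.0, 0.5, 0.0], [0.0, 0.5, 1.0]])
        model = build_model(att, temperature=0.5)
        start = SpinState(np.array([1, -1, 1], dtype=np.int8))
        t1, f1 = evolve(start, model, steps=50, seed=9)
        t2, f2 = evolve(start, model, steps=50, seed=9)
        np.testing.assert_array_equal(f1.sigma, f2.sigma)
        np.testing.assert_array_equal(t1.m, t2.m)

    def test_zero_temperature_deterministic_sign(self):
        att = patterns([[1.0, 1.0]])
        model = build_model(att, temperature=0.0)
        start = SpinState(np.array([1, 1], dtype=np.int8))
        _, final = evolve(start, model, steps=50, seed=0)
        np.testing.assert_array_equal(final.sigma, [1, 1])


class TestOverlaps:
    def test_perfect_agreement_is_one(self):
        model = build_model(patterns([[1.0, 1.0]]))
        m = overlaps(SpinState(np.array([1, 1], dtype=np.int8)), model)
        np.testing.assert_allclose(m, [1.0])

    def test_sign_flip_is_minus_one(self):
        model = build_model(patterns([[1.0, 1.0]]))
        m = overlaps(SpinState(np.array([-1, -1], dtype=np.int8)), model)
        np.testing.assert_allclose(m, [-1.0])

    def test_partial_state_half(self):
        model = build_model(patterns([[1.0, 1.0]]))
        m = overlaps(SpinState(np.array([1, 0], dtype=np.int8)), model)
        np.testing.assert_allclose(m, [0.5])

    def test_orthogonal_patterns_exact_unit_overlap(self):
        # +/-1 patterns with zero dot product -> Q = identity and the
        # overlap of a stored pattern with itself is exactly 1
        xi = np.array([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        model = build_model(xi)
        np.testing.assert_allclose(model.Q, np.eye(2))
        m = overlaps(SpinState(xi[0].astype(np.int8)), model)
        np.testing.assert_allclose(m, [1.0, 0.0], atol=1e-12)
        m1 = overlaps(SpinState(xi[1].astype(np.int8)), model)
        np.testing.assert_allclose(m1, [0.0, 1.0], atol=1e-12)

    def test_identity_q_unit_overlap_for_stored_pattern(self):
        xi = np.array([[1.0, 1.0, 1.0, 1.0]])
        model = build_model(patterns(xi))
        m = overlaps(SpinState(np.ones(4, dtype=np.int8)), model)
        np.testing.assert_allclose(m, [1.0])


class TestClassifyCluster:
    def make_model_and_centroids(self, temperature=1e-3):
        table = pd.DataFrame(
            {"A": [0.5, 0.5, 0.0, 0.0], "B": [0.0, 0.0, 0.5, 0.5]},
            index=["g0", "g1", "g2", "g3"],
        )
        from cellsort import MarkerTable

        att = build_attractors(MarkerTable(table, normalized=True))
        model = build_model(att, temperature=temperature)
        y = pd.DataFrame(
            {0: [5.0, 5.0, 0.1, 0.1], 1: [0.1, 0.1, 5.0, 5.0]},
            index=["g0", "g1", "g2", "g3"],
        )
        centroids = binarize_zscores(CentroidMatrix(Y=y), zeta=0.3)
        return model, centroids

    def test_matching_cluster_labeled_with_full_frequency(self):
        model, centroids = self.make_model_and_centroids()
        label, freqs, _ = classify_cluster(centroids, 0, model, reps=10,
                                           steps=100, seed=2)
        assert label == "A"
        assert freqs["A"] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self):
        model, centroids = self.make_model_and_centroids(temperature=5.0)
        _, freqs, _ = classify_cluster(centroids, 0, model, reps=20,
                                       steps=30, seed=4)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_all_negative_overlaps_unassigned(self):
        model, centroids = self.make_model_and_centroids()
        # a state anti-aligned with every attractor
        down = binarize_zscores(
            CentroidMatrix(Y=pd.DataFrame(
                {0: [0.1, 0.1, 0.1, 0.1], 1: [5.0, 5.0, 5.0, 5.0]},
                index=["g0", "g1", "g2", "g3"],
            )),
            zeta=0.3,
        )
        label, freqs, _ = classify_cluster(down, 0, model, reps=5,
                                           steps=50, seed=1)
        assert label == UNASSIGNED

    def test_trajectory_overlaps_finite_and_recorded_every_step(self):
        model, centroids = self.make_model_and_centroids(temperature=0.5)
        _, _, trajectories = classify_cluster(centroids, 0, model, reps=3,
                                              steps=80, seed=6)
        for traj in trajectories:
            assert traj.m.shape == (80, 2)
            assert np.isfinite(traj.m).all()
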