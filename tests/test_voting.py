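import numpy as np
import pandas as pd
import pytest

from cellsort import (
    UNASSIGNED,
    assign_types,
    binarize_zscores,
    cluster_centroids,
    consensus,
    fraction_scores,
    normalize,
    null_significance,
    voting_scores,
)
from cellsort.io import ClusterLabels
from cellsort.voting import CentroidMatrix

from conftest import make_counts


def labels_of(mapping):
    return ClusterLabels.from_mapping(mapping)


class TestClusterCentroids:
    def test_mean_of_single_cluster(self):
        m = make_counts([[1, 3]], genes=["g0"])
        m.is_lognormalized = True
        cm = cluster_centroids(m, labels_of({"c0": 0, "c1": 0}), ["g0"])
        assert cm.Y.iloc[0, 0] == 2.0

    def test_absent_marker_dropped_with_warning(self):
        m = make_counts([[1, 3]], genes=["g0"])
        with pytest.warns(UserWarning, match="absent"):
            cm = cluster_centroids(m, labels_of({"c0": 0, "c1": 0}),
                                   ["g0", "missing"])
        assert list(cm.Y.index) == ["g0"]

    def test_unequal_cluster_sizes(self):
        m = make_counts([[4, 1, 2, 3]], genes=["g0"])
        cm = cluster_centroids(
            m, labels_of({"c0": 0, "c1": 1, "c2": 1, "c3": 1}), ["g0"]
        )
        np.testing.assert_allclose(cm.Y.to_numpy(), [[4.0, 2.0]])

    def test_empty_cluster_is_error(self):
        m = make_counts([[1, 2]], genes=["g0"])
        with pytest.raises(Exception, match="contiguous|empty"):
            cluster_centroids(m, labels_of({"c0": 0, "c1": 2}), ["g0"])


class TestBinarizeZscores:
    def test_two_cluster_hand_zscore(self):
        cm = CentroidMatrix(Y=pd.DataFrame([[1.0, 3.0]], index=["g0"]))
        out = binarize_zscores(cm, zeta=0.3)
        np.testing.assert_allclose(out.Z.to_numpy(), [[-1.0, 1.0]])
        assert out.Zbin.to_numpy().tolist() == [[0, 1]]

    def test_constant_row_all_zero(self):
        cm = CentroidMatrix(Y=pd.DataFrame([[2.0, 2.0, 2.0]], index=["g0"]))
        out = binarize_zscores(cm)
        assert (out.Zbin.to_numpy() == 0).all()

    def test_threshold_below_all_z(self):
        cm = CentroidMatrix(Y=pd.DataFrame([[1.0, 3.0]], index=["g0"]))
        out = binarize_zscores(cm, zeta=-10)
        assert (out.Zbin.to_numpy() == 1).all()

    def test_single_cluster_is_error(self):
        cm = CentroidMatrix(Y=pd.DataFrame([[1.0]], index=["g0"]))
        with pytest.raises(ValueError, match="at least 2 clusters"):
            binarize_zscores(cm)

    def test_strict_flag_excludes_boundary(self):
        cm = CentroidMatrix(Y=pd.DataFrame([[1.0, 3.0]], index=["g0"]))
        at = binarize_zscores(cm, zeta=1.0)
        above = binarize_zscores(cm, zeta=1.0, strict=True)
        assert at.Zbin.iloc[0, 1] == 1
        assert above.Zbin.iloc[0, 1] == 0

    def test_increasing_zeta_thins_support(self):
        rng = np.random.default_rng(0)
        cm = CentroidMatrix(Y=pd.DataFrame(rng.random((20, 6))))
        counts = [
            binarize_zscores(cm, zeta=z).Zbin.to_numpy().sum()
            for z in (0.0, 0.3, 0.6, 1.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestVotingScores:
    def test_toy_hand_products(self, toy_normalized, toy_zbin):
        v, sup, con = voting_scores(toy_normalized, toy_zbin)
        np.testing.assert_allclose(v[0], [0.5, 0.0])
        np.testing.assert_allclose(v[1], [0.25, -0.5])
        assert sup[("A", 0)] == ["G1"]
        assert sup[("A", 1)] == ["G2"]
        assert con[("B", 1)] == ["G3"]

    def test_zero_zbin_zero_scores(self, toy_normalized):
        zbin = pd.DataFrame(0, index=["G1", "G2", "G3"], columns=[0, 1])
        v, _, _ = voting_scores(toy_normalized, zbin)
        assert (v.to_numpy() == 0).all()

    def test_linear_in_zbin(self, toy_normalized):
        z1 = pd.DataFrame({0: [1, 0, 0]}, index=["G1", "G2", "G3"])
        z2 = pd.DataFrame({0: [0, 1, 1]}, index=["G1", "G2", "G3"])
        v1, _, _ = voting_scores(toy_normalized, z1)
        v2, _, _ = voting_scores(toy_normalized, z2)
        v12, _, _ = voting_scores(toy_normalized, z1 + z2)
        np.testing.assert_allclose(v12.to_numpy(),
                                   v1.to_numpy() + v2.to_numpy())

    def test_misaligned_genes_is_error(self, toy_normalized):
        zbin = pd.DataFrame({0: [1]}, index=["nope"])
        with pytest.raises(ValueError, match="misaligned"):
            voting_scores(toy_normalized, zbin)


class TestFractionScores:
    def test_toy_hand_division(self, toy_normalized, toy_zbin):
        v, sup, _ = voting_scores(toy_normalized, toy_zbin)
        lam = fraction_scores(v, toy_normalized)
        np.testing.assert_allclose(lam[0], [2 / 3, 0.0])
        np.testing.assert_allclose(lam[1], [1 / 3, -1.0])

    def test_full_support_reaches_one(self, toy_normalized):
        zbin = pd.DataFrame({0: [1, 1, 0]}, index=["G1", "G2", "G3"])
        v, _, _ = voting_scores(toy_normalized, zbin)
        lam = fraction_scores(v, toy_normalized)
        assert lam.loc["A", 0] == pytest.approx(1.0)

    def test_bounded_above_by_one(self, toy_normalized):
        rng = np.random.default_rng(1)
        zbin = pd.DataFrame(rng.integers(0, 2, size=(3, 8)),
                            index=["G1", "G2", "G3"])
        v, _, _ = voting_scores(toy_normalized, zbin)
        lam = fraction_scores(v, toy_normalized)
        assert (lam.to_numpy() <= 1.0 + 1e-12).all()

    def test_low_support_rule_zeroes_score(self):
        # type with 10 known markers and no supporting marker in cluster 0
        genes = [f"g{i}" for i in range(10)]
        from cellsort import MarkerTable, normalize_and_restrict
        table = MarkerTable(pd.DataFrame({"A": [1.0] * 10}, index=genes))
        nt = normalize_and_restrict(table, genes)
        zbin = pd.DataFrame({0: [0] * 10, 1: [1] * 10}, index=genes)
        v, sup, _ = voting_scores(nt, zbin)
        lam = fraction_scores(v, nt, sup)
        assert lam.loc["A", 0] == 0.0
        assert lam.loc["A", 1] == pytest.approx(1.0)


class TestAssignTypes:
    def test_argmax_label(self):
        lam = pd.DataFrame({0: [2 / 3, 0.0]}, index=["A", "B"])
        labels, _ = assign_types(lam)
        assert labels[0] == "A"

    def test_all_nonpositive_unassigned(self):
        lam = pd.DataFrame({0: [0.0, 0.0], 1: [-1.0, -0.2]},
                           index=["A", "B"])
        labels, _ = assign_types(lam)
        assert labels[0] == UNASSIGNED and labels[1] == UNASSIGNED

    def test_tie_breaks_lexicographically_with_warning(self):
        lam = pd.DataFrame({0: [0.5, 0.5]}, index=["B", "A"])
        with pytest.warns(UserWarning, match="tie"):
            labels, alts = assign_types(lam)
        assert labels[0] == "A"
        assert [t for t, _ in alts[0]] == ["A", "B"]

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            assign_types(pd.DataFrame())


class TestConsensus:
    def test_idempotent_on_identical_inputs(self):
        lam = pd.DataFrame({0: [0.2, 0.8], 1: [0.4, 0.1]}, index=["A", "B"])
        cons, _, _ = consensus([lam, lam])
        rescaled = lam / lam.max(axis=0)
        np.testing.assert_allclose(cons.to_numpy(), rescaled.to_numpy())

    def test_zero_annihilates(self):
        a = pd.DataFrame({0: [1.0, 0.0]}, index=["A", "B"])
        b = pd.DataFrame({0: [0.5, 0.9]}, index=["A", "B"])
        cons, _, _ = consensus([a, b])
        assert cons.loc["B", 0] == 0.0

    def test_geometric_mean_of_rescaled(self):
        a = pd.DataFrame({0: [0.25, 1.0]}, index=["A", "B"])
        b = pd.DataFrame({0: [1.0, 1.0]}, index=["A", "B"])
        cons, _, _ = consensus([a, b])
        assert cons.loc["A", 0] == pytest.approx(0.5)  # sqrt(0.25 * 1.0)

    def test_shape_mismatch_is_error(self):
        a = pd.DataFrame({0: [1.0]}, index=["A"])
        b = pd.DataFrame({0: [1.0, 0.5]}, index=["A", "B"])
        with pytest.raises(ValueError, match="shape"):
            consensus([a, b])

    def test_negative_scores_clipped(self):
        a = pd.DataFrame({0: [-5.0, 2.0]}, index=["A", "B"])
        cons, labels, _ = consensus([a])
        assert cons.loc["A", 0] == 0.0
        assert labels[0] == "B"


class TestNullSignificance:
    def test_planted_types_beat_wrong_types(self, planted_two_type):
        table, lognorm, labels, truth = planted_two_type
        scores = null_significance(
            lognorm,
            labels,
            _normalized(table, lognorm),
            n_rand=300,
            seed=1,
        )
        lam = scores.Lambda
        planted = sorted(set(truth.cell_types))
        for c, t in enumerate(planted):
            other = [x for x in planted if x != t]
            assert lam.loc[t, c] > lam.loc[other, c].max()

    def test_fixed_seed_bit_reproducible(self, planted_two_type):
        table, lognorm, labels, _ = planted_two_type
        nt = _normalized(table, lognorm)
        a = null_significance(lognorm, labels, nt, n_rand=150, seed=42)
        b = null_significance(lognorm, labels, nt, n_rand=150, seed=42)
        np.testing.assert_array_equal(a.Lambda.to_numpy(),
                                      b.Lambda.to_numpy())
        np.testing.assert_array_equal(a.null_mean.to_numpy(),
                                      b.null_mean.to_numpy())

    def test_small_n_rand_warns(self, planted_two_type):
        table, lognorm, labels, _ = planted_two_type
        with pytest.warns(UserWarning, match="unstable"):
            null_significance(lognorm, labels, _normalized(table, lognorm),
                              n_rand=50, seed=0)


def _normalized(table, lognorm):
    from cellsort import normalize_and_restrict

    return normalize_and_restrict(table, lognorm.genes)


class TestPipelineRecovery:
    @pytest.mark.parametrize("method", ["voting", "fraction", "hopfield"])
    def test_pure_type_clusters_recovered(self, planted_two_type, method):
        from cellsort import annotate

        table, lognorm, labels, truth = planted_two_type
        res = annotate(lognorm, labels, table, method=method, n_rand=300,
                       seed=7)
        planted = sorted(set(truth.cell_types))
        assert list(res.cluster_labels[sorted(res.cluster_labels.index)]) == planted
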