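import numpy as np
import pytest

import ectospec as es
from ward_oracle import scipy_merge_sequence, ward_merge_sequence


def fv(sample_id, values):
    values = np.atleast_1d(np.asarray(values, dtype=float))
    return es.FeatureVector(sample_id, values, np.arange(values.size, dtype=float))


def features_from_matrix(X):
    return [fv(f"s{i}", row) for i, row in enumerate(np.atleast_2d(X))]


class TestDistanceMatrix:
    def test_unit_vectors_distance(self):
        dm = es.distance_matrix(features_from_matrix([[1, 0], [0, 1]]))
        assert dm.d[0, 1] == pytest.approx(np.sqrt(2))
        assert dm.d[0, 0] == 0.0

    def test_matches_double_loop_recomputation(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 6))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        dm = es.distance_matrix(features_from_matrix(X))
        for i in range(10):
            for j in range(10):
                brute = np.sqrt(np.sum((X[i] - X[j]) ** 2))
                assert dm.d[i, j] == pytest.approx(brute, abs=1e-12)

    def test_mismatched_supports_rejected(self):
        a = fv("a", [1.0, 2.0])
        b = es.FeatureVector("b", np.array([1.0, 2.0]), np.array([5.0, 6.0]))
        with pytest.raises(ValueError, match="support"):
            es.distance_matrix([a, b])


class TestWardLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        tree = es.ward_linkage(es.distance_matrix(features_from_matrix([[0.0], [3.0]])))
        assert tree.Z[0, 2] == pytest.approx(3.0)

    def test_collinear_three_points(self):
        # {0, 1, 5}: merge (0,1) at height 1, then at sqrt(2 * delta_SSE)
        tree = es.ward_linkage(
            es.distance_matrix(features_from_matrix([[0.0], [1.0], [5.0]]))
        )
        assert tree.Z[0, 2] == pytest.approx(1.0)
        # delta_SSE of {0,1}+{5}: (2*1/3)*(5-0.5)^2 = 13.5 -> height sqrt(27)
        assert tree.Z[1, 2] == pytest.approx(np.sqrt(27.0))

    @pytest.mark.parametrize("trial", range(100))
    def test_equivalent_to_exhaustive_oracle_small_n(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 9))
        d = int(rng.integers(1, 5))
        X = rng.normal(size=(n, d))
        tree = es.ward_linkage(es.distance_matrix(features_from_matrix(X)))
        got = scipy_merge_sequence(tree)
        expected = ward_merge_sequence(X)
        # sample ids are "s{i}" in index order
        for (ga, gb, gh), (ea, eb, eh) in zip(got, expected):
            ga = frozenset(int(tree.leaf_ids[i][1:]) for i in ga)
            gb = frozenset(int(tree.leaf_ids[i][1:]) for i in gb)
            assert {ga, gb} == {ea, eb}
            assert gh == pytest.approx(eh, abs=1e-9)

    def test_heights_monotone_on_default_dataset(self, default_tree):
        assert np.all(np.diff(default_tree.heights) >= -1e-12)

    def test_sample_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        feats = features_from_matrix(X)
        t1 = es.ward_linkage(es.distance_matrix(feats))
        perm = rng.permutation(12)
        t2 = es.ward_linkage(es.distance_matrix([feats[i] for i in perm]))
        assert np.allclose(np.sort(t1.heights), np.sort(t2.heights))
        for k in (2, 3, 5):
            p1 = es.cut_tree(t1, k)
            p2 = es.cut_tree(t2, k)
            part1 = {frozenset(s for s, c in p1.items() if c == i)
                     for i in set(p1.values())}
            part2 = {frozenset(s for s, c in p2.items() if c == i)
                     for i in set(p2.values())}
            assert part1 == part2

    def test_nan_distances_rejected(self):
        dm = es.distance_matrix(features_from_matrix([[0.0], [1.0]]))
        dm.d[0, 1] = dm.d[1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            es.ward_linkage(dm)


class TestCutTree:
    @pytest.fixture()
    def tree015(self):
        return es.ward_linkage(
            es.distance_matrix(features_from_matrix([[0.0], [1.0], [5.0]]))
        )

    def test_k1_single_cluster(self, tree015):
        assert set(es.cut_tree(tree015, 1).values()) == {0}

    def test_kn_singletons(self, tree015):
        assert len(set(es.cut_tree(tree015, 3).values())) == 3

    def test_k2_splits_far_point(self, tree015):
        cut = es.cut_tree(tree015, 2)
        assert cut["s0"] == cut["s1"] != cut["s2"]

    def test_k_out_of_range(self, tree015):
        with pytest.raises(ValueError):
            es.cut_tree(tree015, 0)
        with pytest.raises(ValueError):
            es.cut_tree(tree015, 4)


class TestSpeciesReport:
    @staticmethod
    def _toy(shift=None):
        rng = np.random.default_rng(3)
        centers = np.eye(5) * 10
        X, truth = [], {}
        for ci, center in enumerate(centers):
            for j in range(6):
                X.append(center + rng.normal(0, 0.1, 5))
                truth[f"s{len(X) - 1}"] = f"sp{ci}"
        X = np.asarray(X)
        if shift is not None:
            moved, target = shift
            X[moved] = centers[target]  # drop one sample onto a foreign centroid
        return X, truth

    def test_separated_clusters_score_perfectly(self):
        X, truth = self._toy()
        tree = es.ward_linkage(es.distance_matrix(features_from_matrix(X)))
        rep = es.species_report(tree, truth, 5)
        assert rep.n_misassigned == 0 and rep.accuracy == 1.0

    def test_single_moved_sample_counts_as_misassigned(self):
        X, truth = self._toy(shift=(0, 3))
        tree = es.ward_linkage(es.distance_matrix(features_from_matrix(X)))
        rep = es.species_report(tree, truth, 5)
        assert rep.n_misassigned == 1
        assert rep.accuracy == pytest.approx(1 - 1 / 30)

    def test_accuracy_identity(self, default_tree, default_truth):
        rep = es.species_report(default_tree, default_truth, 5)
        assert rep.accuracy == pytest.approx(
            1.0 - rep.n_misassigned / len(default_truth)
        )

    def test_missing_truth_rejected(self, default_tree, default_truth):
        truth = dict(default_truth)
        truth.pop(next(iter(truth)))
        with pytest.raises(ValueError, match="missing"):
            es.species_report(default_tree, truth, 5)


class TestHeterogeneity:
    def test_ratio_of_group_with_itself_is_one(self, default_tree, default_truth):
        cg = [s for s, sp in default_truth.items()
              if sp == "Cenococcum_geophilum"]
        assert es.heterogeneity_ratio(default_tree, cg, cg) == pytest.approx(1.0)

    def test_direct_quotient(self):
        X = [[0.0], [1.0], [10.0], [12.0]]
        tree = es.ward_linkage(es.distance_matrix(features_from_matrix(X)))
        ratio = es.heterogeneity_ratio(tree, ["s0", "s1"], ["s2", "s3"])
        assert ratio == pytest.approx(1.0 / 2.0)

    def test_non_subtree_group_rejected(self, default_tree):
        leaves = default_tree.leaf_ids
        bad = [leaves[0], leaves[-1]]
        with pytest.raises(ValueError, match="subtree"):
            es.heterogeneity_ratio(default_tree, bad, leaves)

    def test_swabian_subgroup_is_tighter_than_species_cluster(
        self, default_dataset, default_tree
    ):
        meta = {s.meta.sample_id: s.meta for s in default_dataset}
        swabian = {sid for sid, m in meta.items() if m.site == "Swabian"}
        cg = [sid for sid, m in meta.items()
              if m.species == "Cenococcum_geophilum"]
        pure = [fs for fs in default_tree.node_leafsets() if fs <= swabian]
        largest = max(pure, key=len)
        assert len(largest) >= 2
        ratio = es.heterogeneity_ratio(default_tree, sorted(largest), cg)
        assert ratio < 1.0


class TestNewick:
    def test_two_leaf_form(self):
        tree = es.ward_linkage(
            es.distance_matrix(features_from_matrix([[0.0], [4.0]]))
        )
        assert es.export_newick(tree) == "(s0:2,s1:2);"

    def test_round_trip_topology(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(9, 3))
        tree = es.ward_linkage(es.distance_matrix(features_from_matrix(X)))
        path = tmp_path / "t.nwk"
        es.export_newick(tree, path)
        import dendropy

        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        leaves = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert leaves == set(tree.leaf_ids)
        parsed_splits = {
            frozenset(l.taxon.label for l in node.leaf_iter())
            for node in parsed.preorder_node_iter()
            if not node.is_leaf()
        }
        own_splits = {
            fs for fs in tree.node_leafsets() if len(fs) > 1
        }
        assert parsed_splits == own_splits

    def test_full_tree_parses_with_standard_reader(self, default_tree, tmp_path):
        path = tmp_path / "big.nwk"
        es.export_newick(default_tree, path)
        import dendropy

        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert sum(1 for _ in parsed.leaf_node_iter()) == 181
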