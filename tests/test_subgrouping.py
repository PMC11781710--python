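"""k-means atlas subgrouping: Lloyd oracle, determinism, assignment rules."""

import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans

from multiatlas import AtlasSubgrouper, FeatureVector, assign_subgroup, fit_subgroups


def exhaustive_two_partition_optimum(X: np.ndarray) -> float:
    """Brute-force minimum of the k=2 within-cluster sum of squares."""
    n = len(X)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n):
        bits = np.array(bits)
        if bits.sum() in (0, n):
            continue
        obj = 0.0
        for c in (0, 1):
            pts = X[bits == c]
            obj += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, obj)
    return best


@pytest.fixture(scope="module")
def two_clouds():
    rng = np.random.default_rng(42)
    return np.concatenate(
        [rng.normal(0, 0.5, size=(4, 2)), rng.normal(10, 0.5, size=(4, 2))]
    )


class TestLloydOracle:
    def test_attains_exhaustive_minimum_on_two_clouds(self, two_clouds):
        model = AtlasSubgrouper(n_clusters=2, n_restarts=10, random_state=0).fit(
            two_clouds
        )
        assert model.inertia_ == pytest.approx(
            exhaustive_two_partition_optimum(two_clouds), rel=1e-9
        )
        # the two clouds are recovered exactly
        assert len(set(model.labels_[:4])) == 1
        assert len(set(model.labels_[4:])) == 1
        assert model.labels_[0] != model.labels_[-1]

    def test_exhaustive_minimum_on_random_points(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(8, 2))
        model = AtlasSubgrouper(n_clusters=2, n_restarts=20, random_state=1).fit(X)
        assert model.inertia_ == pytest.approx(
            exhaustive_two_partition_optimum(X), rel=1e-9
        )

    def test_sklearn_agrees_with_brute_force(self):
        # independent cross-check of the oracle itself
        rng = np.random.default_rng(10)
        X = rng.uniform(size=(9, 3))
        sk = KMeans(n_clusters=2, n_init=20, random_state=0).fit(X)
        assert sk.inertia_ == pytest.approx(
            exhaustive_two_partition_optimum(X), rel=1e-6
        )

    def test_identical_points_objective_zero(self):
        X = np.ones((6, 3))
        model = AtlasSubgrouper(n_clusters=2, n_restarts=3, random_state=0).fit(X)
        assert model.inertia_ == pytest.approx(0.0)

    def test_k_equals_n_objective_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 2))
        model = AtlasSubgrouper(n_clusters=5, n_restarts=5, random_state=0).fit(X)
        assert model.inertia_ == pytest.approx(0.0, abs=1e-12)
        assert len(set(model.labels_)) == 5

    def test_centroids_are_member_means(self, two_clouds):
        model = AtlasSubgrouper(n_clusters=2, random_state=0).fit(two_clouds)
        for j in range(2):
            np.testing.assert_allclose(
                model.cluster_centers_[j], two_clouds[model.labels_ == j].mean(axis=0)
            )

    def test_k_larger_than_n_is_an_error(self):
        with pytest.raises(ValueError, match="k"):
            AtlasSubgrouper(n_clusters=5).fit(np.zeros((3, 2)))


class TestDeterminismAndInvariance:
    def test_same_inputs_same_model(self, two_clouds):
        m1 = AtlasSubgrouper(n_clusters=2, n_restarts=5, random_state=7).fit(two_clouds)
        m2 = AtlasSubgrouper(n_clusters=2, n_restarts=5, random_state=7).fit(two_clouds)
        np.testing.assert_array_equal(m1.labels_, m2.labels_)
        np.testing.assert_array_equal(m1.cluster_centers_, m2.cluster_centers_)
        assert m1.inertia_ == m2.inertia_

    def test_permuted_input_same_partition_up_to_relabeling(self, two_clouds):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(two_clouds))
        m1 = AtlasSubgrouper(n_clusters=2, n_restarts=10, random_state=3).fit(two_clouds)
        m2 = AtlasSubgrouper(n_clusters=2, n_restarts=10, random_state=3).fit(
            two_clouds[perm]
        )
        # compare partitions as frozensets of member index sets
        part1 = {frozenset(np.nonzero(m1.labels_ == j)[0]) for j in range(2)}
        part2 = {
            frozenset(perm[np.nonzero(m2.labels_ == j)[0]]) for j in range(2)
        }
        assert part1 == part2

    def test_cluster_sizes_sum_to_n(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(17, 3))
        model = AtlasSubgrouper(n_clusters=4, random_state=0).fit(X)
        assert sum((model.labels_ == j).sum() for j in range(4)) == 17


class TestAssignment:
    def test_target_at_centroid_gets_that_cluster(self, two_clouds):
        model = AtlasSubgrouper(n_clusters=2, random_state=0).fit(two_clouds)
        for j in range(2):
            assert model.predict(model.cluster_centers_[j][None, :])[0] == j

    def test_equidistant_tie_goes_to_lowest_index(self):
        model = AtlasSubgrouper(n_clusters=2)
        model.cluster_centers_ = np.array([[0.0, 0.0], [2.0, 0.0]])
        model.n_features_in_ = 2
        model.labels_ = np.array([0, 1])
        model.inertia_ = 0.0
        assert model.predict(np.array([[1.0, 0.0]]))[0] == 0

    def test_matches_exhaustive_distance_scan(self):
        rng = np.random.default_rng(11)
        model = AtlasSubgrouper(n_clusters=4)
        model.cluster_centers_ = rng.normal(size=(4, 6))
        model.n_features_in_ = 6
        for _ in range(25):
            t = rng.normal(size=6)
            expected = int(
                np.argmin(((model.cluster_centers_ - t) ** 2).sum(axis=1))
            )
            assert model.predict(t[None, :])[0] == expected

    def test_dimension_mismatch_raises(self, two_clouds):
        model = AtlasSubgrouper(n_clusters=2, random_state=0).fit(two_clouds)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((1, 5)))


class TestEmptyClusterRepair:
    def test_empty_cluster_reseeded_from_farthest_point(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 0.0]])
        C = np.array([[0.05, 0.0], [100.0, 100.0]])  # second centroid empty
        assign = AtlasSubgrouper._assign(X, C)
        assert not np.any(assign == 1)
        repaired = AtlasSubgrouper._repair_empty(X, C, assign.copy())
        assert np.any(repaired == 1)
        np.testing.assert_allclose(C[1], [5.0, 0.0])  # farthest point adopted


class TestAtlasInterface:
    @staticmethod
    def _vectors():
        rng = np.random.default_rng(8)
        ids = [f"a{i:02d}" for i in range(10)]
        return {
            a: FeatureVector(("bladder", "rectum"), rng.uniform(10, 400, 2))
            for a in ids
        }

    def test_fit_subgroups_covers_all_atlases(self):
        vectors = self._vectors()
        model = fit_subgroups(vectors, k=3, seed=0)
        assert set(model.assignment_) == set(vectors)
        sizes = [len(model.members(j)) for j in range(3)]
        assert sum(sizes) == len(vectors)

    def test_assign_subgroup_uses_nearest_centroid(self):
        vectors = self._vectors()
        model = fit_subgroups(vectors, k=3, seed=0)
        target = FeatureVector(("bladder", "rectum"), [0.0, 0.0])
        target.normalized = model.cluster_centers_[2]
        assert assign_subgroup(target, model) == 2

    def test_json_round_trip(self, tmp_path):
        vectors = self._vectors()
        model = fit_subgroups(vectors, k=3, seed=5)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = AtlasSubgrouper.from_json(path)
        np.testing.assert_array_equal(back.labels_, model.labels_)
        np.testing.assert_allclose(back.cluster_centers_, model.cluster_centers_)
        assert back.assignment_ == model.assignment_
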