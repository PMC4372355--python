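"""Complete-linkage clustering: oracles, monotone heights, gray-row policy."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from rootdge.clustering import (
    Dendrogram,
    ProfileMatrix,
    cluster_profiles,
    complete_linkage,
    euclidean_distance,
)


def brute_force_complete_linkage(D):
    """Independent agglomeration: recompute max-over-members distances from
    the original matrix at every step; same id scheme and tie-break."""
    n = D.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(members) > 1:
        best = None
        for a in sorted(members):
            for b in sorted(members):
                if a >= b:
                    continue
                d = max(D[i, j] for i in members[a] for j in members[b])
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merges.append((a, b, d))
        members[next_id] = members.pop(a) | members.pop(b)
        next_id += 1
    return merges


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    return D


class TestEuclideanDistance:
    def test_hand_example(self):
        assert euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 6))
            assert euclidean_distance(a, a) == 0.0
            assert euclidean_distance(a, b) == pytest.approx(euclidean_distance(b, a))

    def test_pairwise_complete_positions(self):
        a = [1.0, np.nan, 3.0]
        b = [4.0, 5.0, 7.0]
        assert euclidean_distance(a, b) == pytest.approx(5.0)

    def test_no_shared_positions_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            euclidean_distance([np.nan, 1.0], [2.0, np.nan])


class TestCompleteLinkage:
    def test_three_leaf_hand_example(self):
        D = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        dendro = complete_linkage(D)
        assert dendro.merges == ((0, 1, 1.0), (2, 3, 5.0))

    def test_two_leaves_and_duplicates(self):
        assert complete_linkage(np.array([[0.0, 2.5], [2.5, 0.0]])).merges == ((0, 1, 2.5),)
        D = np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]], dtype=float)
        assert complete_linkage(D).merges[0] == (0, 1, 0.0)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            D = random_distance_matrix(rng, n)
            ours = complete_linkage(D).merges
            oracle = brute_force_complete_linkage(D)
            assert len(ours) == len(oracle)
            for (a, b, h), (oa, ob, oh) in zip(ours, oracle):
                assert (a, b) == (oa, ob)
                assert h == pytest.approx(oh)

    def test_heights_match_scipy(self):
        rng = np.random.default_rng(42)
        D = random_distance_matrix(rng, 12)
        ours = np.array([h for _, _, h in complete_linkage(D).merges])
        scipy_heights = linkage(squareform(D, checks=False), method="complete")[:, 2]
        assert ours == pytest.approx(scipy_heights)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        for n in (4, 7, 10):
            D = random_distance_matrix(rng, n)
            heights = [h for _, _, h in complete_linkage(D).merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage(np.array([[0, 1], [2, 0]], dtype=float))

    def test_dendrogram_invariants_enforced(self):
        with pytest.raises(ValueError):
            Dendrogram(n_leaves=3, merges=((0, 1, 1.0),), leaf_order=(0, 1, 2))


class TestClusterProfiles:
    def matrix(self, rows, index=None, cols=("PR", "CR", "SR")):
        idx = index or [f"g{i}" for i in range(len(rows))]
        return ProfileMatrix(values=pd.DataFrame(rows, index=idx, columns=list(cols)))

    def test_identical_rows_adjacent(self):
        m = self.matrix([[1.0, 1.0, 1.0], [9.0, -9.0, 9.0], [1.0, 1.0, 1.0]])
        dendro, ordered, _ = cluster_profiles(m)
        pos = {g: i for i, g in enumerate(ordered.index)}
        assert abs(pos["g0"] - pos["g2"]) == 1

    def test_fully_observed_matches_complete_linkage(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(6, 3))
        m = self.matrix(vals.tolist())
        dendro, _, _ = cluster_profiles(m)
        D = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                D[i, j] = np.sqrt(((vals[i] - vals[j]) ** 2).sum())
        assert dendro.merges == complete_linkage(D).merges

    def test_permuting_rows_same_heights(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(7, 3))
        m1 = self.matrix(vals.tolist())
        perm = rng.permutation(7)
        m2 = ProfileMatrix(values=m1.values.iloc[perm])
        h1 = [h for _, _, h in cluster_profiles(m1)[0].merges]
        h2 = [h for _, _, h in cluster_profiles(m2)[0].merges]
        assert h1 == pytest.approx(h2)

    def test_gray_rows_appended_not_clustered(self):
        m = self.matrix(
            [[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [np.nan, 0.0, 0.0], [3.0, 3.0, 3.0]]
        )
        dendro, ordered, gray = cluster_profiles(m)
        assert dendro.n_leaves == 3
        assert ordered.index[-1] == "g2"
        assert gray.loc["g2"].tolist() == [True, False, False]

    def test_pairwise_policy_clusters_partial_rows(self):
        m = self.matrix(
            [[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [np.nan, 0.0, 0.0], [3.0, 3.0, 3.0]]
        )
        dendro, _, _ = cluster_profiles(m, policy="pairwise")
        assert dendro.n_leaves == 4

    def test_all_missing_rejected(self):
        m = ProfileMatrix(
            values=pd.DataFrame([[np.nan, np.nan]] * 2, columns=["a", "b"])
        )
        with pytest.raises(ValueError):
            cluster_profiles(m)

    def test_duplicate_columns_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ProfileMatrix(values=pd.DataFrame([[1.0, 2.0]], columns=["a", "a"]))
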