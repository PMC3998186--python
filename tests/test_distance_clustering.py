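import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from chemotax.distance_clustering import (
    Dendrogram,
    DistanceMatrix,
    SimilarityMatrix,
    TreeNode,
    cophenetic,
    genetic_distance_matrix,
    read_newick,
    read_phylip_distances,
    simple_matching_matrix,
    to_newick,
    upgma,
    write_phylip_distances,
)
from tests.conftest import random_band_matrix


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    vals = rng.uniform(0.05, 1.0, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(tuple(f"t{i}" for i in range(n)), vals)


def random_ultrametric_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Cophenetic matrix of a random agglomeration with increasing heights."""
    clusters = [[i] for i in range(n)]
    heights = np.sort(rng.uniform(0.05, 0.5, size=n - 1))
    d = np.zeros((n, n))
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for u in clusters[i]:
            for v in clusters[j]:
                d[u, v] = d[v, u] = 2 * h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return DistanceMatrix(tuple(f"t{i}" for i in range(n)), d)


def cophenetic_in_input_order(t: Dendrogram, ids) -> np.ndarray:
    """Cophenetic matrix reindexed to a given id order (trees permute leaves)."""
    c = cophenetic(t)
    idx = [c.ids.index(s) for s in ids]
    return c.values[np.ix_(idx, idx)]


def brute_force_upgma_cophenetic(d: DistanceMatrix) -> np.ndarray:
    """Average-linkage oracle recomputing means from the original matrix."""
    n = d.n
    clusters = [frozenset([i]) for i in range(n)]
    out = np.zeros((n, n))

    def avg(a: frozenset, b: frozenset) -> float:
        return float(np.mean([d.values[u, v] for u in a for v in b]))

    while len(clusters) > 1:
        best = min(
            itertools.combinations(range(len(clusters)), 2),
            key=lambda ij: avg(clusters[ij[0]], clusters[ij[1]]),
        )
        i, j = best
        h = avg(clusters[i], clusters[j])
        for u in clusters[i]:
            for v in clusters[j]:
                out[u, v] = out[v, u] = h
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] | clusters[j]
        ]
    return out


class TestSimpleMatching:
    def test_identical_rows_give_similarity_one(self, small_matrix):
        s = simple_matching_matrix(small_matrix)
        assert s.values[0, 0] == 1.0

    def test_complementary_rows_give_zero(self):
        rng = np.random.default_rng(0)
        m = random_band_matrix(rng, 2, 10)
        presence = np.vstack([m.presence[0], 1 - m.presence[0]])
        comp = type(m)(m.samples, m.bands, presence)
        assert simple_matching_matrix(comp).values[0, 1] == 0.0

    def test_half_matching_rows(self):
        from chemotax.band_matrix import BandMatrix

        m = BandMatrix(
            ("a", "b"),
            tuple(("P1", 100 * (j + 1)) for j in range(4)),
            np.array([[1, 1, 0, 0], [1, 0, 1, 0]], dtype=np.uint8),
        )
        assert simple_matching_matrix(m).values[0, 1] == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_direct_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        m = random_band_matrix(rng, rng.integers(2, 7), rng.integers(1, 15))
        s = simple_matching_matrix(m)
        for i in range(m.n_samples):
            for j in range(m.n_samples):
                matches = int((m.presence[i] == m.presence[j]).sum())
                assert s.values[i, j] == pytest.approx(matches / m.n_bands)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_distance_is_one_minus_similarity(self, seed):
        rng = np.random.default_rng(seed)
        m = random_band_matrix(rng, rng.integers(2, 7), rng.integers(1, 15))
        s = simple_matching_matrix(m)
        d = genetic_distance_matrix(s)
        off = ~np.eye(s.n, dtype=bool)
        assert np.allclose((d.values + s.values)[off], 1.0)
        assert np.allclose(np.diag(d.values), 0.0)


class TestUpgma:
    def test_two_taxa_join_at_half_distance(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        t = upgma(d)
        assert t.height == pytest.approx(0.2)
        assert to_newick(t, precision=1) == "(A:0.2,B:0.2);"

    def test_three_taxon_worked_example(self):
        d = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]]),
        )
        t = upgma(d)
        assert to_newick(t, precision=2) == "((A:0.10,B:0.10):0.25,C:0.35);"
        coph = cophenetic(t)
        idx = {s: i for i, s in enumerate(coph.ids)}
        assert coph.values[idx["A"], idx["B"]] == pytest.approx(0.2)
        assert coph.values[idx["A"], idx["C"]] == pytest.approx(0.7)
        assert coph.values[idx["B"], idx["C"]] == pytest.approx(0.7)

    def test_rejects_negative_distances(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, -0.1], [-0.1, 0.0]]))

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_agrees_with_brute_force_oracle(self, n):
        for seed in range(25):
            d = random_distance_matrix(np.random.default_rng(seed * 10 + n), n)
            assert np.allclose(
                cophenetic_in_input_order(upgma(d), d.ids),
                brute_force_upgma_cophenetic(d),
            )

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_agrees_with_scipy_average_linkage(self, n):
        for seed in range(10):
            d = random_distance_matrix(np.random.default_rng(seed + 100 * n), n)
            ours = squareform(cophenetic_in_input_order(upgma(d), d.ids), checks=False)
            theirs = cophenet(linkage(squareform(d.values, checks=False), "average"))
            assert np.allclose(ours, theirs)

    def test_merge_heights_nondecreasing_and_ultrametric(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            d = random_distance_matrix(rng, int(rng.integers(3, 8)))
            t = upgma(d)  # Dendrogram construction checks child <= parent height
            coph = cophenetic(t).values
            # three-point condition: the two largest of any triple are equal
            for i, j, k in itertools.combinations(range(d.n), 3):
                trio = sorted([coph[i, j], coph[i, k], coph[j, k]])
                assert trio[1] == pytest.approx(trio[2])

    def test_ultrametric_input_is_a_fixed_point(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = random_ultrametric_matrix(rng, 5)
            assert np.allclose(
                cophenetic_in_input_order(upgma(d), d.ids), d.values, atol=1e-12
            )

    def test_sample_order_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(11)
        d = random_distance_matrix(rng, 6)
        perm = rng.permutation(6)
        dp = DistanceMatrix(
            tuple(d.ids[i] for i in perm), d.values[np.ix_(perm, perm)]
        )
        c1, c2 = cophenetic(upgma(d)), cophenetic(upgma(dp))
        back = [c2.ids.index(s) for s in c1.ids]
        assert np.allclose(c1.values, c2.values[np.ix_(back, back)])


class TestTreeIO:
    def test_two_leaf_newick(self):
        t = Dendrogram(
            TreeNode(0.2, children=(TreeNode(0.0, "A"), TreeNode(0.0, "B")))
        )
        assert to_newick(t, precision=1) == "(A:0.2,B:0.2);"
        assert cophenetic(t).values[0, 1] == pytest.approx(0.4)

    def test_newick_round_trip_preserves_cophenetic_distances(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = upgma(random_distance_matrix(rng, int(rng.integers(3, 8))))
            t2 = read_newick(to_newick(t, precision=10))
            c1, c2 = cophenetic(t), cophenetic(t2)
            order = [c2.ids.index(s) for s in c1.ids]
            assert np.allclose(c1.values, c2.values[np.ix_(order, order)], atol=1e-8)

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="malformed|not ultrametric"):
            read_newick("((A:1,B:2);")

    def test_non_ultrametric_newick_rejected(self):
        with pytest.raises(ValueError, match="not ultrametric"):
            read_newick("(A:1.0,B:2.0);")

    def test_phylip_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        d = random_distance_matrix(rng, 5)
        path = tmp_path / "d.phylip"
        write_phylip_distances(d, path, decimals=9)
        d2 = read_phylip_distances(path)
        assert d2.ids == d.ids
        assert np.allclose(d2.values, d.values, atol=1e-8)

    def test_similarity_matrix_requires_unit_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            SimilarityMatrix(("a", "b"), np.array([[0.0, 0.5], [0.5, 0.0]]))
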