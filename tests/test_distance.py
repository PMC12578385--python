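"""Population centroids, distances, agglomeration and similarity ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy

from emdiff import (
    PopulationDistance,
    hierarchical_cluster,
    merges_to_newick,
    pairwise_euclidean,
    population_centroids,
    similarity_rank,
)


def meta(cell_types, groups):
    n = len(cell_types)
    return pd.DataFrame({
        "barcode": [f"c{i}" for i in range(n)],
        "cell_type": cell_types, "group": groups, "sample": groups,
    })


class TestCentroids:
    def test_identical_cells(self):
        coords = np.array([[1.0, 2.0]] * 3)
        labels, cents = population_centroids(
            coords, meta(["n"] * 3, ["g"] * 3))
        np.testing.assert_allclose(cents, [[1.0, 2.0]])
        assert labels == ["n|g"]

    def test_two_cell_mean(self):
        coords = np.array([[0.0, 0.0], [2.0, 2.0]])
        _, cents = population_centroids(coords, meta(["n"] * 2, ["g"] * 2))
        np.testing.assert_allclose(cents, [[1.0, 1.0]])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3))
        md = meta(["n"] * 10, ["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        l1, c1 = population_centroids(coords, md)
        l2, c2 = population_centroids(coords[perm],
                                      md.iloc[perm].reset_index(drop=True))
        assert l1 == l2
        np.testing.assert_allclose(c1, c2, atol=1e-12)


class TestPairwise:
    def test_three_four_five(self):
        d = pairwise_euclidean([[0.0, 0.0], [3.0, 4.0]])
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(6, 4))
        d = pairwise_euclidean(c)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def brute_force_agglomerate(d, linkage):
    """Naive re-implementation over explicit cluster member lists."""
    d = np.asarray(d, float)
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_node = n
    merges = []

    def cluster_dist(a, b):
        vals = [d[i, j] for i in clusters[a] for j in clusters[b]]
        if linkage == "single":
            return min(vals)
        if linkage == "complete":
            return max(vals)
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            key = (cluster_dist(a, b), a, b)
            if best is None or key < best:
                best = key
        h, a, b = best
        merges.append((a, b, h, len(clusters[a]) + len(clusters[b])))
        clusters[next_node] = clusters.pop(a) + clusters.pop(b)
        next_node += 1
    return merges


class TestHierarchicalCluster:
    def test_forced_first_merge(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], float)
        merges = hierarchical_cluster(d, "average")
        assert merges[0][:3] == (0, 1, 1.0)

    def test_equidistant_tie_smallest_pair(self):
        d = np.ones((3, 3)) - np.eye(3)
        merges = hierarchical_cluster(d, "average")
        assert merges[0][:2] == (0, 1)

    def test_single_linkage_equals_mst_heights(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=(6, 3))
        d = pairwise_euclidean(c)
        merges = hierarchical_cluster(d, "single")
        heights = sorted(m[2] for m in merges)
        from scipy.sparse.csgraph import minimum_spanning_tree
        mst = minimum_spanning_tree(d).toarray()
        mst_edges = sorted(mst[mst > 0])
        np.testing.assert_allclose(heights, mst_edges, atol=1e-12)

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_matches_brute_force_oracle_small(self, linkage):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 6))
            c = rng.normal(size=(n, 3))
            d = pairwise_euclidean(c)
            got = hierarchical_cluster(d, linkage)
            want = brute_force_agglomerate(d, linkage)
            for g, w in zip(got, want):
                assert g[:2] == w[:2]
                assert g[2] == pytest.approx(w[2], abs=1e-10)

    @pytest.mark.parametrize("linkage", ["single", "complete", "average", "ward"])
    def test_matches_scipy_heights(self, linkage):
        rng = np.random.default_rng(4)
        c = rng.normal(size=(7, 3))
        d = pairwise_euclidean(c)
        got = hierarchical_cluster(d, linkage)
        from scipy.spatial.distance import squareform
        Z = scipy.cluster.hierarchy.linkage(squareform(d, checks=False),
                                            method=linkage)
        np.testing.assert_allclose(sorted(m[2] for m in got),
                                   sorted(Z[:, 2]), atol=1e-8)

    def test_monotone_heights(self):
        rng = np.random.default_rng(5)
        d = pairwise_euclidean(rng.normal(size=(8, 3)))
        for linkage in ("single", "complete", "average"):
            h = [m[2] for m in hierarchical_cluster(d, linkage)]
            assert (np.diff(h) >= -1e-12).all()

    def test_asymmetric_input_error(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[0, 1], [2, 0]], float))


class TestSimilarityRank:
    def test_ordering(self):
        d = np.array([[0, 1, 2], [1, 0, 5], [2, 5, 0]], float)
        assert similarity_rank(d, ["q", "A", "B"], "q") == ["A", "B"]

    def test_tie_ascending_label(self):
        d = np.array([[0, 1, 1], [1, 0, 5], [1, 5, 0]], float)
        assert similarity_rank(d, ["q", "B", "A"], "q") == ["A", "B"]

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        c = rng.normal(size=(5, 3))
        labels = [f"p{i}" for i in range(5)]
        r1 = similarity_rank(pairwise_euclidean(c), labels, "p0")
        r2 = similarity_rank(pairwise_euclidean(c + 100.0), labels, "p0")
        assert r1 == r2

    def test_unknown_query_error(self):
        with pytest.raises(ValueError):
            similarity_rank(np.zeros((2, 2)), ["a", "b"], "zz")


class TestPopulationDistanceObject:
    def test_from_embedding_and_newick(self):
        rng = np.random.default_rng(7)
        coords = np.vstack([
            rng.normal(0, 0.1, (20, 3)),
            rng.normal(5, 0.1, (20, 3)),
            rng.normal([5, 5, 5], 0.1, (20, 3)),
        ])
        md = meta(["n"] * 60, ["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        emb = type("E", (), {"coords": coords})()
        pop = PopulationDistance.from_embedding(emb, md)
        assert pop.labels == ["n|a", "n|b", "n|c"]
        nwk = pop.to_newick()
        assert nwk.endswith(";") and "n|a" in nwk
        # parseable by a tree library
        from io import StringIO
        from Bio import Phylo
        tree = Phylo.read(StringIO(nwk), "newick")
        assert tree.count_terminals() == 3
        assert "merge tree" in pop.summary()
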