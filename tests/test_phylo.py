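"""Relationship matrix, clustering, NJ and clade-cut checks against oracles."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from gluhap.phylo import (
    CladePartition,
    additive_relationship,
    cut_clades,
    distance_from_A,
    hierarchical_cluster,
    neighbor_joining,
    read_newick,
    roman,
    write_newick,
)
from gluhap.variant_core import ALT, MISSING, REF

from .conftest import make_matrix


def vanraden_oracle(calls):
    """Elementwise brute-force of A = WW'/(2*sum p(1-p)) on -1/+1 coding."""
    n_sites, n_samples = calls.shape
    M = np.zeros((n_samples, n_sites))
    for j in range(n_samples):
        for i in range(n_sites):
            M[j, i] = {REF: -1.0, ALT: 1.0, MISSING: np.nan}[calls[i, j]]
    p = np.zeros(n_sites)
    for i in range(n_sites):
        col = M[:, i]
        mean = np.mean(col[~np.isnan(col)])
        p[i] = (mean + 1) / 2
        M[np.isnan(col), i] = mean
    denom = 2 * sum(pi * (1 - pi) for pi in p)
    A = np.zeros((n_samples, n_samples))
    for a in range(n_samples):
        for b in range(n_samples):
            A[a, b] = sum(
                (M[a, i] - (2 * p[i] - 1)) * (M[b, i] - (2 * p[i] - 1)) for i in range(n_sites)
            ) / denom
    return A


def naive_complete_linkage(D):
    """O(n^3) agglomerative oracle: returns merge heights and merged sets."""
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights, merges = [], []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        heights.append(d)
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights, merges


def random_additive_matrix(rng, n):
    """Distances from a random binary tree with positive branch lengths."""
    nodes = {i: [(i, 0.0)] for i in range(n)}
    D = np.zeros((n, n))
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]  # pop larger index first
        ba, bb = rng.uniform(0.1, 1.0, 2)
        for la, da in nodes[a]:
            for lb, db in nodes[b]:
                D[la, lb] = D[lb, la] = da + ba + db + bb
        nodes[nxt] = [(l, d + ba) for l, d in nodes[a]] + [(l, d + bb) for l, d in nodes[b]]
        active.remove(a)
        active.remove(b)
        active.append(nxt)
        nxt += 1
    return D


class TestAdditiveRelationship:
    def test_hand_example_two_samples_one_marker(self):
        # calls (REF, ALT): p = 0.5, A = [[2, -2], [-2, 2]]
        A = additive_relationship(make_matrix([[REF, ALT]]))
        np.testing.assert_allclose(A.values, [[2, -2], [-2, 2]])

    def test_identical_samples_identical_rows(self):
        calls = np.array([[REF, REF, ALT], [ALT, ALT, REF], [REF, REF, ALT]], dtype=np.int8)
        A = additive_relationship(make_matrix(calls))
        np.testing.assert_allclose(A.values[0], A.values[1])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            calls = rng.choice([REF, ALT, MISSING], size=(20, 6), p=[0.45, 0.45, 0.1]).astype(np.int8)
            # ensure polymorphic among called at every site
            calls[:, 0] = REF
            calls[:, 1] = ALT
            A = additive_relationship(make_matrix(calls))
            np.testing.assert_allclose(A.values, vanraden_oracle(calls), rtol=1e-10, atol=1e-12)

    def test_site_order_invariant(self):
        rng = np.random.default_rng(11)
        calls = rng.choice([REF, ALT], size=(15, 8)).astype(np.int8)
        calls[:, 0], calls[:, 1] = REF, ALT
        A1 = additive_relationship(make_matrix(calls))
        A2 = additive_relationship(make_matrix(calls[::-1]))
        np.testing.assert_allclose(A1.values, A2.values)

    def test_monomorphic_marker_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            additive_relationship(make_matrix([[REF, REF], [REF, ALT]]))


class TestDistanceFromA:
    def test_hand_example_sqrt32(self):
        A = additive_relationship(make_matrix([[REF, ALT]]))
        D = distance_from_A(A)
        assert D[("s0", "s1")] == pytest.approx(np.sqrt(32.0))

    def test_identical_rows_zero(self):
        calls = np.array([[REF, REF, ALT]], dtype=np.int8)
        D = distance_from_A(additive_relationship(make_matrix(calls)))
        assert D[("s0", "s1")] == 0.0

    def test_permutation_consistent(self):
        rng = np.random.default_rng(12)
        calls = rng.choice([REF, ALT], size=(12, 6)).astype(np.int8)
        calls[:, 0], calls[:, 1] = REF, ALT
        D = distance_from_A(additive_relationship(make_matrix(calls)))
        perm = rng.permutation(6)
        names = [f"s{i}" for i in range(6)]
        Dp = distance_from_A(
            additive_relationship(make_matrix(calls[:, perm], samples=[names[i] for i in perm]))
        )
        for a in names:
            for b in names:
                assert D[(a, b)] == pytest.approx(Dp[(a, b)])


class TestHierarchicalCluster:
    def test_closest_pair_merges_first(self):
        D = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        Z = hierarchical_cluster(DistanceMatrix(D, ids=list("abc"))).Z
        assert sorted(Z[0, :2]) == [0, 1] and Z[0, 2] == 1.0

    def test_ultrametric_same_tree_all_linkages(self):
        D = np.array(
            [[0, 1, 3, 3], [1, 0, 3, 3], [3, 3, 0, 1], [3, 3, 1, 0]], dtype=float
        )
        dm = DistanceMatrix(D, ids=list("abcd"))
        heights = {
            m: hierarchical_cluster(dm, m).Z[:, 2].tolist()
            for m in ("complete", "average", "single")
        }
        assert heights["complete"] == heights["average"] == heights["single"]

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            n = 8
            v = rng.uniform(1, 10, n * (n - 1) // 2)
            from scipy.spatial.distance import squareform

            D = squareform(v)
            Z = hierarchical_cluster(DistanceMatrix(D)).Z
            heights, _ = naive_complete_linkage(D)
            np.testing.assert_allclose(sorted(Z[:, 2]), sorted(heights), rtol=1e-10)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(DistanceMatrix(np.zeros((1, 1))))


class TestNeighborJoining:
    def test_known_four_taxon_tree(self):
        # classic additive example; NJ must reproduce the generating distances
        D = DistanceMatrix(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            ids=list("abcd"),
        )
        tree = neighbor_joining(D)
        td = tree.tip_tip_distances()
        for i in "abcd":
            for j in "abcd":
                assert td[(i, j)] == pytest.approx(D[(i, j)], abs=1e-9)

    def test_identical_pair_zero_terminal(self):
        D = DistanceMatrix(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 4], [5, 5, 4, 0]], ids=list("abcd")
        )
        tree = neighbor_joining(D)
        assert tree.find("a").length == pytest.approx(0.0)
        assert tree.find("b").length == pytest.approx(0.0)

    def test_all_quartet_topologies_recovered(self):
        # the three labeled unrooted quartets, each with a positive internal edge
        for cherry in (("a", "b"), ("a", "c"), ("a", "d")):
            rest = [t for t in "abcd" if t not in cherry]
            ext = {t: 1.0 + i * 0.3 for i, t in enumerate("abcd")}
            internal = 2.0
            ids = list("abcd")
            D = np.zeros((4, 4))
            for i, u in enumerate(ids):
                for j, v in enumerate(ids):
                    if i == j:
                        continue
                    same = {u, v} == set(cherry) or {u, v} == set(rest)
                    D[i, j] = ext[u] + ext[v] + (0 if same else internal)
            tree = neighbor_joining(DistanceMatrix(D, ids=ids))
            td = tree.tip_tip_distances()
            for u in ids:
                for v in ids:
                    assert td[(u, v)] == pytest.approx(D[ids.index(u), ids.index(v)], abs=1e-9)

    def test_additivity_on_random_trees(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            D = random_additive_matrix(rng, 6)
            ids = [f"t{i}" for i in range(6)]
            tree = neighbor_joining(DistanceMatrix(D, ids=ids))
            td = tree.tip_tip_distances()
            for i in range(6):
                for j in range(6):
                    if i != j:
                        assert td[(ids[i], ids[j])] == pytest.approx(D[i, j], abs=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ids=list("ab")))


class TestCutClades:
    def _three_group_dendrogram(self, rng, sizes=(5, 4, 3)):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts, labels, lineage = [], [], []
        for g, size in enumerate(sizes):
            for k in range(size):
                pts.append(centers[g] + rng.normal(0, 0.2, 2))
                labels.append(f"g{g}_m{k}")
                lineage.append(g)
        from scipy.spatial.distance import pdist, squareform

        D = DistanceMatrix(squareform(pdist(np.array(pts))), ids=labels)
        return hierarchical_cluster(D), labels, lineage

    def test_major_equals_sub_when_k_equal(self):
        rng = np.random.default_rng(15)
        dendro, labels, _ = self._three_group_dendrogram(rng)
        part = cut_clades(dendro, 3, 3)
        groups_major = {l: part.major[l] for l in labels}
        groups_sub = {l: part.sub[l] for l in labels}
        assert len(set(groups_major.values())) == len(set(groups_sub.values())) == 3

    def test_recovers_planted_groups(self):
        rng = np.random.default_rng(16)
        dendro, labels, lineage = self._three_group_dendrogram(rng)
        part = cut_clades(dendro, 3, 3)
        for a, la in zip(labels, lineage):
            for b, lb in zip(labels, lineage):
                assert (part.major[a] == part.major[b]) == (la == lb)

    def test_major_labels_ordered_by_size(self):
        rng = np.random.default_rng(17)
        dendro, labels, lineage = self._three_group_dendrogram(rng, sizes=(6, 4, 2))
        part = cut_clades(dendro, 3, 3)
        sizes = {}
        for l, lin in zip(labels, lineage):
            sizes.setdefault(part.major[l], set()).add(lin)
        count = {m: sum(1 for l in labels if part.major[l] == m) for m in ("I", "II", "III")}
        assert count["I"] >= count["II"] >= count["III"]

    def test_singleton_subclades(self):
        rng = np.random.default_rng(18)
        dendro, labels, _ = self._three_group_dendrogram(rng)
        part = cut_clades(dendro, 3, len(labels))
        assert sorted(part.sub[l] for l in labels) == list(range(1, len(labels) + 1))

    def test_non_nested_request_rejected(self):
        rng = np.random.default_rng(19)
        dendro, _, _ = self._three_group_dendrogram(rng)
        with pytest.raises(ValueError):
            cut_clades(dendro, 3, 2)

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(20)
        centers = np.array([[0.0], [8.0], [20.0]])
        pts = np.concatenate([c + rng.normal(0, 0.1, (4, 1)) for c in centers])
        labels = [f"m{i:02d}" for i in range(12)]
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        p1 = cut_clades(hierarchical_cluster(DistanceMatrix(D, ids=labels)), 3, 3)
        perm = rng.permutation(12)
        Dp = D[np.ix_(perm, perm)]
        p2 = cut_clades(
            hierarchical_cluster(DistanceMatrix(Dp, ids=[labels[i] for i in perm])), 3, 3
        )
        assert {l: p1.major[l] for l in labels} == {l: p2.major[l] for l in labels}
        assert {l: p1.sub[l] for l in labels} == {l: p2.sub[l] for l in labels}

    def test_nesting_enforced_in_partition_type(self):
        with pytest.raises(ValueError, match="spans"):
            CladePartition(["a", "b"], {"a": "I", "b": "II"}, {"a": 1, "b": 1})


class TestNewick:
    def test_simple_roundtrip(self):
        text = "(A:1.0,B:2.0);\n"
        assert write_newick(read_newick(text)) == text

    def test_topology_preserved(self):
        tree = read_newick("((A,B),(C,D));")
        names = {frozenset(t.name for t in ch.tips()) for ch in tree.children}
        assert frozenset("AB") in names and frozenset("CD") in names

    def test_random_tree_roundtrip(self):
        rng = np.random.default_rng(21)
        D = random_additive_matrix(rng, 10)
        ids = [f"t{i}" for i in range(10)]
        tree = neighbor_joining(DistanceMatrix(D, ids=ids))
        again = read_newick(write_newick(tree))
        td1, td2 = tree.tip_tip_distances(), again.tip_tip_distances()
        for i in ids:
            for j in ids:
                assert td1[(i, j)] == pytest.approx(td2[(i, j)], abs=1e-9)

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(Exception):
            read_newick("((A:1,B:2;")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("(A:1,(A:1,B:2):1);")


def test_roman_numerals():
    assert [roman(i) for i in (1, 2, 3, 4, 9, 14)] == ["I", "II", "III", "IV", "IX", "XIV"]
    with pytest.raises(ValueError):
        roman(0)
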