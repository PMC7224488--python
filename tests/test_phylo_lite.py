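"""Distance/NJ tests, including an independent brute-force topology oracle.

The oracle enumerates every unrooted leaf-labeled topology (3 for n=4,
15 for n=5, 105 for n=6) and selects the one whose induced quartet splits
all satisfy the four-point condition on the distance matrix — no part of
the package's NJ code is involved in that selection.
"""

import itertools
import math
import random

import dendropy
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitoarch.phylo_lite import (
    DistanceMatrix,
    Supermatrix,
    build_supermatrix,
    distance_matrix,
    k2p_distance,
    nj_tree,
    rf_distance,
)

# ---------------------------------------------------------------------------
# oracle machinery: topology enumeration + four-point quartet inference
# ---------------------------------------------------------------------------


def enumerate_topologies(taxa):
    """All unrooted binary topologies as frozensets of bipartitions,
    built by attaching each new leaf to every edge in turn
    (3, 15, 105, ... trees for 4, 5, 6, ... taxa)."""
    trees = [[(taxa[0], "i0"), (taxa[1], "i0"), (taxa[2], "i0")]]
    counter = 1
    for leaf in taxa[3:]:
        mid = f"i{counter}"
        counter += 1
        trees = [
            edges[:i] + edges[i + 1 :] + [(u, mid), (mid, v), (mid, leaf)]
            for edges in trees
            for i, (u, v) in enumerate(edges)
        ]
    return [topology_bipartitions(edges, taxa) for edges in trees]


def topology_bipartitions(edges, taxa):
    """Non-trivial bipartitions of an edge-list tree, as frozensets of
    frozenset leaf sides."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    taxa_set = set(taxa)
    bips = set()
    for u, v in edges:
        # leaves reachable from u without crossing (u, v)
        seen, stack = {u, v}, [u]
        side = set()
        while stack:
            x = stack.pop()
            if x in taxa_set:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < len(taxa) - 1:
            bips.add(frozenset({frozenset(side), frozenset(taxa_set - side)}))
    return frozenset(bips)


def quartet_split(bips, quartet):
    """Which pairing a topology induces on a 4-taxon subset."""
    a, b, c, d = quartet
    for bip in bips:
        s1, s2 = bip
        for x, y in ((a, b), (a, c), (a, d)):
            rest = [t for t in quartet if t not in (x, y)]
            if ({x, y} <= s1 and set(rest) <= s2) or ({x, y} <= s2 and set(rest) <= s1):
                return frozenset({frozenset({x, y}), frozenset(rest)})
    return None  # unresolved (cannot happen for binary trees, n>=5 internal)


def four_point_split(dist: DistanceMatrix, quartet):
    """Quartet pairing minimizing the sum of within-pair path lengths."""
    a, b, c, d = quartet
    sums = {
        frozenset({frozenset({a, b}), frozenset({c, d})}): dist.get(a, b) + dist.get(c, d),
        frozenset({frozenset({a, c}), frozenset({b, d})}): dist.get(a, c) + dist.get(b, d),
        frozenset({frozenset({a, d}), frozenset({b, c})}): dist.get(a, d) + dist.get(b, c),
    }
    return min(sums, key=sums.get)


def oracle_topology(dist: DistanceMatrix):
    """The unique enumerated topology consistent with every quartet."""
    taxa = list(dist.taxa)
    consistent = []
    for bips in enumerate_topologies(taxa):
        ok = all(
            quartet_split(bips, q) in (None, four_point_split(dist, q))
            for q in itertools.combinations(taxa, 4)
        )
        if ok:
            consistent.append(bips)
    assert len(consistent) == 1, "additive matrix must determine one topology"
    return consistent[0]


def newick_bipartitions(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa_set = set(taxa)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 1 < len(side) < len(taxa) - 1:
            bips.add(frozenset({frozenset(side), frozenset(taxa_set - side)}))
    return frozenset(bips)


def random_additive_matrix(taxa, rng):
    """Path-length distances on a random binary tree with positive lengths."""
    edges = [(taxa[0], "i0"), (taxa[1], "i0"), (taxa[2], "i0")]
    nid = 1
    for leaf in taxa[3:]:
        u, v = edges.pop(rng.randrange(len(edges)))
        mid = f"i{nid}"
        nid += 1
        edges += [(u, mid), (mid, v), (mid, leaf)]
    weights = {e: rng.uniform(0.05, 1.0) for e in edges}
    adj = {}
    for (u, v), w in weights.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    n = len(taxa)
    m = np.zeros((n, n))
    for i, t in enumerate(taxa):
        dist = {t: 0.0}
        stack = [t]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, u in enumerate(taxa):
            m[i, j] = dist[u]
    return DistanceMatrix(taxa=tuple(taxa), matrix=m), topology_bipartitions(edges, taxa)


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------


class TestSupermatrix:
    def test_widths_and_partitions(self):
        blocks = {
            "ND2": {"a": "A" * 9, "b": "C" * 9},
            "COI": {"a": "G" * 12, "b": "T" * 12},
            "COII": {"a": "A" * 6, "b": "G" * 6},
        }
        sm = build_supermatrix(blocks)
        assert sm.n_columns == 27
        assert sm.partitions == (("ND2", 1, 9), ("COI", 10, 21), ("COII", 22, 27))

    def test_partitions_tile_columns(self):
        blocks = {"ND2": {"a": "ACGT", "b": "ACGT"}, "COI": {"a": "GG", "b": "TT"}}
        sm = build_supermatrix(blocks)
        cols = [c for _, a, b in sm.partitions for c in range(a, b + 1)]
        assert cols == list(range(1, sm.n_columns + 1))

    def test_missing_taxon_named(self):
        blocks = {"ND2": {"a": "AAA", "b": "AAA"}, "COI": {"a": "AAA"}}
        with pytest.raises(ValueError, match="COI"):
            build_supermatrix(blocks)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            build_supermatrix({"ND2": {"a": "AAA", "b": "AAAA"}})

    def test_complete_deletion_identity_on_gap_free(self):
        blocks = {"ND2": {"a": "ACGTAC", "b": "TTTTTT"}}
        assert build_supermatrix(blocks, drop_gapped=True).sequences == \
            build_supermatrix(blocks, drop_gapped=False).sequences

    def test_complete_deletion_drops_gapped_columns(self):
        blocks = {"ND2": {"a": "A-GT", "b": "CCG-"}}
        sm = build_supermatrix(blocks, drop_gapped=True)
        assert sm.sequences == {"a": "AG", "b": "CG"}
        assert sm.partitions == (("ND2", 1, 2),)

    def test_phylip_and_nexus_serialization(self):
        sm = build_supermatrix({"ND2": {"a": "ACG", "b": "TTT"}})
        assert sm.to_phylip().splitlines()[0].split() == ["2", "3"]
        assert "CHARSET ND2 = 1-3;" in sm.to_nexus()


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_one_transition_in_100(self):
        a = "A" * 100
        b = "G" + "A" * 99
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.98))

    def test_gapped_sites_skipped(self):
        assert k2p_distance("AC-T", "ACGT") == 0.0

    def test_saturation_inf(self):
        with pytest.warns(UserWarning, match="saturated"):
            assert k2p_distance("ACAC", "GTGT") == math.inf

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            k2p_distance("ACG", "ACGT")

    @given(st.lists(st.sampled_from("ACGT"), min_size=20, max_size=200),
           st.lists(st.sampled_from("ACGT"), min_size=20, max_size=200))
    def test_symmetry(self, xs, ys):
        n = min(len(xs), len(ys))
        a, b = "".join(xs[:n]), "".join(ys[:n])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert k2p_distance(a, b) == k2p_distance(b, a)


# ---------------------------------------------------------------------------
# NJ + RF
# ---------------------------------------------------------------------------


class TestNJ:
    def test_three_taxa_three_point_formula(self):
        d = DistanceMatrix(
            taxa=("a", "b", "c"),
            matrix=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = dendropy.Tree.get(data=nj_tree(d), schema="newick")
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_four_taxon_additive_recovery_vs_bruteforce(self):
        rng = random.Random(11)
        taxa = ["a", "b", "c", "d"]
        for _ in range(20):
            dist, true_bips = random_additive_matrix(taxa, rng)
            nj_bips = newick_bipartitions(nj_tree(dist), taxa)
            assert nj_bips == oracle_topology(dist) == true_bips

    @pytest.mark.parametrize("n", [5, 6])
    def test_consistency_on_additive_matrices(self, n):
        rng = random.Random(100 + n)
        taxa = [f"t{i}" for i in range(n)]
        for _ in range(10):
            dist, true_bips = random_additive_matrix(taxa, rng)
            assert newick_bipartitions(nj_tree(dist), taxa) == oracle_topology(dist)
            assert oracle_topology(dist) == true_bips

    def test_consistency_n8_against_generating_tree(self):
        rng = random.Random(8)
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(5):
            dist, true_bips = random_additive_matrix(taxa, rng)
            assert newick_bipartitions(nj_tree(dist), taxa) == true_bips

    def test_branch_lengths_recovered_on_additive_input(self):
        rng = random.Random(3)
        dist, _ = random_additive_matrix(["a", "b", "c", "d", "e"], rng)
        tree = dendropy.Tree.get(data=nj_tree(dist), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        for t1 in pdm.taxon_iter():
            for t2 in pdm.taxon_iter():
                if t1.label < t2.label:
                    assert pdm.distance(t1, t2) == pytest.approx(dist.get(t1.label, t2.label))

    def test_requires_three_taxa(self):
        d = DistanceMatrix(taxa=("a", "b"), matrix=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            nj_tree(d)

    def test_nonfinite_rejected(self):
        m = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=("a", "b", "c"), matrix=m))

    def test_deterministic(self):
        rng = random.Random(5)
        dist, _ = random_additive_matrix([f"t{i}" for i in range(6)], rng)
        assert nj_tree(dist) == nj_tree(dist)


class TestRF:
    def test_identical_trees(self):
        t = "((a:1,b:1):1,(c:1,d:1):1);"
        assert rf_distance(t, t) == 0

    def test_alternative_quartets(self):
        t1 = "((a:1,b:1):1,(c:1,d:1):1);"
        t2 = "((a:1,c:1):1,(b:1,d:1):1);"
        # each tree has one non-trivial bipartition, neither shared
        assert rf_distance(t1, t2) == 2

    def test_symmetry(self):
        t1 = "(((a:1,b:1):1,c:1):1,(d:1,e:1):1);"
        t2 = "(((a:1,d:1):1,c:1):1,(b:1,e:1):1);"
        assert rf_distance(t1, t2) == rf_distance(t2, t1)

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValueError):
            rf_distance("((a:1,b:1):1,c:1);", "((a:1,b:1):1,d:1);")


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=("a", "b"), matrix=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(taxa=("a", "b"), matrix=np.array([[1, 1], [1, 0]]))

    def test_from_sequences(self):
        dm = distance_matrix({"a": "AAAA", "b": "AAAA", "c": "GAAA"})
        assert dm.get("a", "b") == 0.0
        assert dm.get("a", "c") > 0
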