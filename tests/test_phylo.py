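"""K2P distances, neighbour joining, bootstrap, haplotypes, newick."""

import math

import dendropy
import numpy as np
import pytest

from _tree_oracles import (
    random_unrooted_tree,
    tree_bipartitions,
    tree_distances,
)
from taxamark.phylo import (
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    count_haplotypes,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    to_newick,
)
from taxamark.seqio import SequenceRecord


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_value(self):
        # 100 columns, 10 transitions (A->G), 5 transversions (A->C):
        # d = -1/2 ln(0.75 * sqrt(0.90))
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expected = -0.5 * math.log(0.75 * math.sqrt(0.90))
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert k2p_distance(a, b) == pytest.approx(0.1702, abs=1e-4)

    def test_saturation_boundary_raises(self):
        # P=0.45, Q=0.10 -> 1-2P-Q = 0
        a = "A" * 100
        b = "G" * 45 + "C" * 10 + "A" * 45
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_pairwise_deletion_drops_gapped_columns(self):
        a = "ACGT-ACGTN"
        b = "ACGTTACCT-"
        # retained columns: 8 (positions with gap or N in either dropped);
        # one transversion G->C at position 7
        d = k2p_distance(a, b)
        P, Q = 0.0, 1 / 8
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert d == pytest.approx(expected)

    def test_no_shared_columns_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance("A---", "-CGT")

    def test_approaches_p_distance_at_low_divergence(self):
        # with 1 difference in 1000 sites the correction is negligible
        a = "ACGT" * 250
        b = "CCGT" + "ACGT" * 249
        assert k2p_distance(a, b) == pytest.approx(0.001, rel=0.01)


class TestNJ:
    def test_two_taxa_single_edge_split_at_midpoint(self):
        t = nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 0.5], [0.5, 0]])))
        assert to_newick(t) == "(A:0.25,B:0.25);"

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = nj_tree(DistanceMatrix(labels, D))
        assert t.bipartitions() == {frozenset({"C", "D"})}
        lengths = {}

        def walk(node):
            for c in node.children:
                if c.is_leaf:
                    lengths[c.name] = c.length
                walk(c)

        walk(t.root)
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})

    def test_random_additive_matrices_recover_topology(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            adj, labels = random_unrooted_tree(n, rng)
            D = tree_distances(adj, n)
            t = nj_tree(DistanceMatrix(labels, D))
            assert t.bipartitions() == tree_bipartitions(adj, n, labels)

    def test_non_finite_distances_rejected(self):
        D = np.array([[0, np.inf], [np.inf, 0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], D))


def _group_alignment(seed=0, ncols=600):
    """Two clearly separated 2-leaf groups: ~1% within, ~30% between."""
    rng = np.random.default_rng(seed)

    def noise(arr, p):
        flip = rng.random(arr.size) < p
        return np.where(flip, (arr + rng.integers(1, 4, arr.size)) % 4, arr)

    def s(arr):
        return "".join("ACGT"[c] for c in arr)

    base = rng.integers(0, 4, ncols)
    far = noise(base, 0.30)
    seqs = (base, noise(base, 0.01), far, noise(far, 0.01))
    return [
        SequenceRecord(n, s(x), alphabet="dna-aligned")
        for n, x in zip("abcd", seqs)
    ]


class TestBootstrap:
    def test_unambiguous_signal_gives_full_support(self):
        recs = _group_alignment()
        t = bootstrap_support(recs, replicates=100, seed=4)
        supports = [v for v in t.edge_supports().values() if v is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        recs = _group_alignment(seed=1)
        t = bootstrap_support(recs, replicates=1, seed=0)
        for v in t.edge_supports().values():
            assert v in (0.0, 100.0)

    def test_same_seed_reproduces_supports(self):
        recs = _group_alignment(seed=2)
        t1 = bootstrap_support(recs, replicates=50, seed=7)
        t2 = bootstrap_support(recs, replicates=50, seed=7)
        assert to_newick(t1) == to_newick(t2)


class TestHaplotypes:
    def _recs(self, seqs):
        return [
            SequenceRecord(f"s{i}", s, alphabet="dna-aligned")
            for i, s in enumerate(seqs)
        ]

    def test_identical_records_one_haplotype(self):
        h = count_haplotypes(self._recs(["ACGT", "ACGT", "ACGT"]))
        assert h.n_haplotypes == 1

    def test_distinct_records_distinct_haplotypes(self):
        h = count_haplotypes(self._recs(["ACGT", "ACGA", "ACGC"]))
        assert h.n_haplotypes == 3

    def test_gap_and_ambiguity_columns_removed(self):
        # the distinguishing column carries a gap in one record, so it is
        # deleted in all and the records collapse to one haplotype
        h = count_haplotypes(self._recs(["ACGT", "ACG-", "ACGN"]))
        assert h.n_haplotypes == 1
        assert h.used_sites == 3

    def test_reordering_preserves_class_count(self):
        seqs = ["ACGT", "ACGA", "ACGT", "TCGA"]
        a = count_haplotypes(self._recs(seqs))
        b = count_haplotypes(self._recs(list(reversed(seqs))))
        assert a.n_haplotypes == b.n_haplotypes == 3

    def test_all_columns_removed_rejected(self):
        with pytest.raises(ValueError):
            count_haplotypes(self._recs(["-A", "A-"]))


class TestNewick:
    def test_support_appears_as_internal_label(self):
        recs = _group_alignment()
        t = bootstrap_support(recs, replicates=10, seed=0)
        assert ")100:" in to_newick(t)

    def test_round_trip_preserves_bipartitions_and_lengths(self):
        rng = np.random.default_rng(21)
        adj, labels = random_unrooted_tree(10, rng)
        D = tree_distances(adj, 10)
        tree = nj_tree(DistanceMatrix(labels, D))
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        parsed.encode_bipartitions()
        ref = min(labels)
        taxa = {t.label for t in parsed.taxon_namespace}
        got = set()
        for edge in parsed.preorder_edge_iter():
            if edge.head_node and not edge.head_node.is_leaf() and edge.tail_node:
                side = {
                    lf.taxon.label for lf in edge.head_node.leaf_iter()
                }
                if 1 < len(side) < len(taxa) - 1:
                    if ref in side:
                        side = taxa - side
                    got.add(frozenset(side))
        assert got == tree.bipartitions()
        assert parsed.length() == pytest.approx(
            sum(adj[a][b] for a in adj for b in adj[a] if a < b), rel=1e-6
        )
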