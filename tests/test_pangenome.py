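"""Locus clustering, pan/core classification, exact-match allele calling."""

import numpy as np
import pytest

from taxamark.pangenome import (
    ABSENT,
    AlleleTable,
    CandidateLocus,
    GenomeCdsSet,
    LocusCluster,
    call_alleles,
    classify_pan_core,
    cluster_loci,
    pan_core_counts,
    select_candidates,
)
from taxamark.seqio import SequenceRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _gene(cds_id, aa_seq, rng=None):
    """A (nucleotide, protein) record pair with consistent lengths."""
    rng = rng or np.random.default_rng(abs(hash(aa_seq)) % 2**31)
    nt = "".join(rng.choice(list("ACGT"), 3 * len(aa_seq)))
    return (
        SequenceRecord(cds_id, nt, alphabet="dna"),
        SequenceRecord(cds_id, aa_seq, alphabet="protein"),
    )


def _random_protein(rng, n=80):
    return "".join(rng.choice(list(_AA), n))


@pytest.fixture
def toy_genomes():
    """Three genomes sharing one identical gene, each adding a unique one."""
    rng = np.random.default_rng(42)
    shared_aa = _random_protein(rng)
    shared = _gene("shared", shared_aa, np.random.default_rng(7))
    genomes = []
    for i in range(3):
        unique = _gene(f"uniq{i}", _random_protein(rng))
        genomes.append(
            GenomeCdsSet(f"g{i}", f"sp{i}", [shared, unique])
        )
    return genomes


class TestClustering:
    def test_shared_plus_unique_gives_four_clusters(self, toy_genomes):
        clusters = cluster_loci(toy_genomes)
        assert len(clusters) == 4
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 1, 1, 3]

    def test_pan_core_counts_on_toy(self, toy_genomes):
        clusters = cluster_loci(toy_genomes)
        assert pan_core_counts(clusters, 3) == (4, 1)

    def test_identical_genomes_cluster_pairwise(self):
        rng = np.random.default_rng(1)
        genes = [_gene(f"c{i}", _random_protein(rng)) for i in range(3)]
        g1 = GenomeCdsSet("g1", "sp", list(genes))
        g2 = GenomeCdsSet("g2", "sp", list(genes))
        clusters = cluster_loci([g1, g2])
        assert all(c.size == 2 for c in clusters)
        assert pan_core_counts(clusters, 2) == (3, 3)

    def test_dissimilar_genes_each_found_a_cluster(self):
        rng = np.random.default_rng(2)
        genes = [_gene(f"c{i}", _random_protein(rng)) for i in range(5)]
        clusters = cluster_loci([GenomeCdsSet("g", "sp", genes)])
        assert len(clusters) == 5

    def test_every_cds_in_exactly_one_cluster(self, toy_genomes):
        clusters = cluster_loci(toy_genomes)
        total = sum(len(g.cds) for g in toy_genomes)
        assert sum(c.size for c in clusters) == total

    def test_order_independent(self, toy_genomes):
        a = cluster_loci(toy_genomes)
        b = cluster_loci(list(reversed(toy_genomes)))
        key = lambda cs: sorted(frozenset(c.members.items()) for c in cs)
        assert key(a) == key(b)

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ValueError):
            cluster_loci([])

    def test_classify_requires_positive_n(self, toy_genomes):
        with pytest.raises(ValueError):
            classify_pan_core(cluster_loci(toy_genomes), 0)


class TestAlleleCalling:
    def _cluster_of(self, genomes, cds_id="locus"):
        members = {g.genome_id: cds_id for g in genomes}
        rep = max(
            genomes, key=lambda g: (len(g.nucleotide(cds_id)), g.genome_id)
        )
        return LocusCluster("locus_00001", members, rep.genome_id, cds_id)

    def _genomes_with_locus(self, seqs):
        out = []
        for i, nt in enumerate(seqs):
            aa = "M" * (len(nt) // 3)
            out.append(
                GenomeCdsSet(
                    f"g{i}",
                    "sp",
                    [(SequenceRecord("locus", nt), SequenceRecord("locus", aa))],
                )
            )
        return out

    def test_identical_members_share_one_allele(self):
        nt = "ATGGCTGACGCTAAAGCTGGT" * 6
        genomes = self._genomes_with_locus([nt, nt, nt])
        table = call_alleles(self._cluster_of(genomes), genomes)
        assert table.n_alleles == 1
        assert set(table.assignment.values()) == {1}

    def test_single_substitution_is_a_new_allele(self):
        nt = "ATGGCTGACGCTAAAGCTGGT" * 6
        variant = nt[:30] + ("A" if nt[30] != "A" else "G") + nt[31:]
        genomes = self._genomes_with_locus([nt, nt, variant])
        table = call_alleles(self._cluster_of(genomes), genomes)
        assert table.n_alleles == 2
        assert table.assignment["g0"] == table.assignment["g1"] == 1
        assert table.assignment["g2"] == 2

    def test_low_identity_member_called_absent(self):
        rng = np.random.default_rng(0)
        nt = "".join(rng.choice(list("ACGT"), 300))
        # ~15% substitutions: below the 90% presence-identity floor
        far = list(nt)
        for pos in rng.choice(300, size=45, replace=False):
            far[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[far[pos]]
        genomes = self._genomes_with_locus([nt, "".join(far)])
        cluster = LocusCluster(
            "locus_00001", {"g0": "locus", "g1": "locus"}, "g0", "locus"
        )
        table = call_alleles(cluster, genomes)
        assert table.assignment["g1"] == ABSENT
        assert table.n_alleles == 1

    def test_allele_count_bounded_by_present_genomes(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), 120))
        variants = [base]
        for i in range(3):
            v = list(base)
            v[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[v[i]]
            variants.append("".join(v))
        genomes = self._genomes_with_locus(variants)
        table = call_alleles(self._cluster_of(genomes), genomes)
        present = sum(1 for a in table.assignment.values() if a != ABSENT)
        assert table.n_alleles == present == 4  # all distinct


class TestCandidateSelection:
    def _candidates(self, lengths):
        out = []
        for i, L in enumerate(lengths):
            cluster = LocusCluster(
                f"locus_{i:05d}", {"g0": "c"}, "g0", "c"
            )
            table = AlleleTable(cluster.locus_id, ["A" * L], {"g0": 1})
            out.append(CandidateLocus(cluster, table, L))
        return out

    def test_sorted_by_length_descending(self):
        cands = self._candidates([1902, 600, 1200])
        top = select_candidates(cands, 2)
        assert [c.representative_length for c in top] == [1902, 1200]

    def test_k_beyond_count_returns_all(self):
        cands = self._candidates([100, 200])
        assert len(select_candidates(cands, 10)) == 2

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            select_candidates(self._candidates([100]), 0)

    def test_allele_count_key(self):
        cands = self._candidates([100, 200])
        cands[0].table = AlleleTable(
            cands[0].cluster.locus_id, ["AA", "AC", "AG"], {"g0": 1}
        )
        top = select_candidates(cands, 1, key="allele_count")
        assert top[0].cluster.locus_id == cands[0].cluster.locus_id
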