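"""Consensus calling, conserved-window search, degenerate and
species-specific primer design."""

import numpy as np
import pytest

from taxamark import insilico_pcr, synth
from taxamark.primer_design import (
    Msa,
    column_consensus,
    design_degenerate_pair,
    design_species_specific,
    find_conserved_windows,
    melting_temperature,
)
from taxamark.seqio import IUPAC_DNA, SequenceRecord


def _msa(rows, species=None):
    recs = [
        SequenceRecord(f"r{i}", s, alphabet="dna-aligned")
        for i, s in enumerate(rows)
    ]
    species = species or {r.id: r.id for r in recs}
    return Msa(recs, species)


class TestConsensus:
    @pytest.mark.parametrize(
        "column,expected",
        [
            (["A", "A", "A"], "A"),
            (["A", "G"], "R"),
            (["A", "C", "G", "T"], "N"),
            (["C", "T", "Y"], "Y"),
            (["A", "-", "A"], "-"),
        ],
    )
    def test_union_consensus(self, column, expected):
        assert column_consensus(column) == expected

    @pytest.mark.parametrize("code", sorted(IUPAC_DNA))
    def test_idempotence(self, code):
        assert column_consensus([code]) == code


class TestConservedWindows:
    def test_identical_rows_give_degeneracy_one_everywhere(self):
        rng = np.random.default_rng(0)
        row = "".join(rng.choice(list("ACGT"), 60))
        windows = find_conserved_windows(_msa([row, row, row]), (18, 20))
        assert windows
        assert all(w.degeneracy == 1 for w in windows)
        starts = {(w.start, len(w)) for w in windows}
        expected = {
            (s, L) for L in (18, 19, 20) for s in range(60 - L + 1)
        }
        assert starts == expected

    def test_single_variable_column_doubles_degeneracy(self):
        rng = np.random.default_rng(1)
        row = list("".join(rng.choice(list("ACGT"), 40)))
        other = row.copy()
        row[20], other[20] = "A", "G"
        windows = find_conserved_windows(
            _msa(["".join(row), "".join(other)]), (18, 18)
        )
        for w in windows:
            covers = w.start <= 20 < w.start + 18
            assert w.degeneracy == (2 if covers else 1)

    def test_gap_column_excludes_windows(self):
        row = "ACGTACGTACGTACGTACGTACGT"
        gapped = row[:10] + "-" + row[11:]
        windows = find_conserved_windows(_msa([row, gapped]), (18, 18))
        assert all(not (w.start <= 10 < w.start + 18) for w in windows)

    def test_lower_cap_is_a_subset_of_higher(self):
        rng = np.random.default_rng(2)
        rows = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(3)]
        msa = _msa(rows)
        low = {(w.start, w.consensus) for w in find_conserved_windows(msa, (18, 20), 8)}
        high = {(w.start, w.consensus) for w in find_conserved_windows(msa, (18, 20), 64)}
        assert low <= high


@pytest.fixture(scope="module")
def planted_group():
    spec = synth.GroupSpec(
        4, 3,
        (synth.LocusSpec("locA", 500, 0.30, 0.004, planted_primer_sites=True),),
        seed=9,
    )
    truth = synth.generate_species_group(spec)
    msa = Msa(truth.locus_records("locA"), truth.labels)
    return truth, msa


class TestDegenerateDesign:
    def test_planted_conserved_flanks_recovered(self, planted_group):
        truth, msa = planted_group
        length = len(msa.records[0].residues)
        pairs = design_degenerate_pair(
            msa, (length - 100, length), max_degeneracy=16
        )
        assert pairs
        top = pairs[0]
        cf, cr = truth.planted.conserved_forward, truth.planted.conserved_reverse
        # top pair anchors inside the planted conserved regions
        assert cf[0] - 5 <= top.forward.msa_start <= cf[1]
        assert cr[0] - 22 <= top.reverse.msa_start <= cr[1]
        assert top.expected_product >= length - 100

    def test_infeasible_product_range_is_empty(self, planted_group):
        _, msa = planted_group
        assert design_degenerate_pair(msa, (10, 20)) == []

    def test_fully_conserved_msa_top_pair_degeneracy_two(self):
        rng = np.random.default_rng(5)
        row = "".join(rng.choice(list("ACGT"), 200))
        msa = _msa([row, row])
        pairs = design_degenerate_pair(msa, (150, 200))
        assert pairs and pairs[0].total_degeneracy == 2  # 1 + 1


class TestSpeciesSpecificDesign:
    def test_planted_unique_windows_yield_validated_pairs(self, planted_group):
        truth, msa = planted_group
        pairs = design_species_specific(msa, "sp01", max_pairs=2)
        assert pairs
        for p in pairs:
            assert p.target == "sp01"
            # internal cross-check: every returned pair passes in-silico
            # specificity on its own input
            templates = [r.degapped() for r in msa.records]
            mat = insilico_pcr.specificity_matrix([p], templates, msa.species)
            for t in templates:
                assert mat.is_positive(t.id, p.name) == (
                    msa.species[t.id] == "sp01"
                )

    def test_indistinguishable_target_gives_empty_list(self):
        rng = np.random.default_rng(6)
        row_a = "".join(rng.choice(list("ACGT"), 300))
        row_b = "".join(rng.choice(list("ACGT"), 300))
        msa = _msa(
            [row_a, row_a, row_b],
            species={"r0": "target", "r1": "other", "r2": "third"},
        )
        # target's sequence is identical to a non-target's: no site can
        # discriminate, so design must return nothing
        assert design_species_specific(msa, "target") == []

    def test_unknown_target_rejected(self, planted_group):
        _, msa = planted_group
        with pytest.raises(ValueError):
            design_species_specific(msa, "nope")


class TestMeltingTemperature:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AATT", (8, 8)),
            ("GGCC", (16, 16)),
            ("S", (4, 4)),
            ("W", (2, 2)),
            ("R", (2, 4)),
        ],
    )
    def test_wallace_rule_ranges(self, seq, expected):
        assert melting_temperature(seq) == expected

    def test_long_primer_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("A" * 31)
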