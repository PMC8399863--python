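"""Pairwise global alignment with free end gaps, shared by clustering and
identity-matrix stages.

Scoring for DNA is match +1 / mismatch −1 / gap open −5 / gap extend −1 with
zero-cost terminal gaps; proteins use BLOSUM62 with open −11 / extend −1.
Identity and coverage definitions are spelled out per function because BLAST
identities, MSA-column identities and presence-call identities all differ and
the distinction matters for threshold rules (75% clustering, 90/90 presence).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def _aligner(protein: bool) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    if protein:
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
    else:
        al.match_score = 1.0
        al.mismatch_score = -1.0
        al.open_gap_score = -5.0
        al.extend_gap_score = -1.0
    # free end gaps: global alignment, terminal gaps unpenalised
    al.open_end_gap_score = 0.0
    al.extend_end_gap_score = 0.0
    return al


def align_pair(a: str, b: str, protein: bool = False) -> tuple[str, str]:
    """Return the two gapped rows of the best global free-end-gap alignment."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(protein).align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def percent_identity(a: str, b: str, protein: bool = False) -> float:
    """Percent identity over columns where neither row has a gap.

    100 × (identical column pairs) / (columns with a residue in both rows),
    the convention used for the marker identity matrices.
    """
    ra, rb = align_pair(a, b, protein=protein)
    matches = cols = 0
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            cols += 1
            if x == y:
                matches += 1
    if cols == 0:
        raise ValueError("alignment has no residue-residue columns")
    return 100.0 * matches / cols


@dataclass(frozen=True)
class LocalStats:
    """Identity/coverage of the end-gap-trimmed core of an alignment."""

    identity: float      # matches / core columns (gaps count as mismatch)
    coverage_a: float    # fraction of sequence a inside the core
    coverage_b: float


def core_stats(a: str, b: str, protein: bool = False) -> LocalStats:
    """Alignment statistics over the core region (terminal overhangs trimmed).

    The core runs from the first to the last column where both rows carry a
    residue.  Identity counts internal gap columns as mismatches (BLAST-like);
    coverage is the fraction of each full sequence falling inside the core.
    """
    ra, rb = align_pair(a, b, protein=protein)
    both = [i for i, (x, y) in enumerate(zip(ra, rb)) if x != "-" and y != "-"]
    if not both:
        return LocalStats(0.0, 0.0, 0.0)
    lo, hi = both[0], both[-1] + 1
    matches = sum(1 for x, y in zip(ra[lo:hi], rb[lo:hi]) if x == y and x != "-")
    cols = hi - lo
    res_a = sum(1 for x in ra[lo:hi] if x != "-")
    res_b = sum(1 for y in rb[lo:hi] if y != "-")
    return LocalStats(
        identity=matches / cols,
        coverage_a=res_a / len(a),
        coverage_b=res_b / len(b),
    )


def presence_stats(representative: str, member: str) -> tuple[float, float]:
    """(identity, coverage) of a member against a locus representative.

    Used by the 90% identity / 90% coverage presence rule: identity is
    matches over core columns where the representative has a residue (member
    gaps against those residues count as mismatch); coverage is the fraction
    of the representative's residues inside the core.
    """
    ra, rb = align_pair(representative, member, protein=False)
    both = [i for i, (x, y) in enumerate(zip(ra, rb)) if x != "-" and y != "-"]
    if not both:
        return 0.0, 0.0
    lo, hi = both[0], both[-1] + 1
    rep_cols = matches = 0
    for x, y in zip(ra[lo:hi], rb[lo:hi]):
        if x != "-":
            rep_cols += 1
            if x == y:
                matches += 1
    return matches / rep_cols, rep_cols / len(representative)
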