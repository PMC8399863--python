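"""Sequence records, IUPAC nucleotide semantics, and FASTA I/O.

Everything downstream — locus clustering, identity matrices, degenerate
primer design, in-silico PCR, tree building — moves sequences through the
:class:`SequenceRecord` container defined here.  The IUPAC ambiguity table
is the single source of truth for interpreting degenerate codes such as
``S``/``Y``/``K`` in primers like ``TSGAYGTSAAYGTKCAYCC``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IUPAC_DNA",
    "IUPAC_COMPLEMENT",
    "SequenceRecord",
    "SeqFormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "degeneracy",
    "expand_degenerate",
]

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: base set -> code.  Exact (every non-empty subset of ACGT
#: has exactly one code, so consensus calling is total).
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_DNA.items()}

_BASE_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: code -> complement code; complement(set(code)) == set(complement(code)).
IUPAC_COMPLEMENT: dict[str, str] = {
    code: CODE_FOR_SET[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_DNA.items()
}

DNA_ALPHABET = frozenset(IUPAC_DNA)
DNA_ALIGNED_ALPHABET = DNA_ALPHABET | {"-"}
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBJXZUO*")
PROTEIN_ALIGNED_ALPHABET = PROTEIN_ALPHABET | {"-"}

_ALPHABETS = {
    "dna": DNA_ALPHABET,
    "dna-aligned": DNA_ALIGNED_ALPHABET,
    "protein": PROTEIN_ALPHABET,
    "protein-aligned": PROTEIN_ALIGNED_ALPHABET,
}


class SeqFormatError(ValueError):
    """Raised for malformed FASTA input or residues outside the alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence over a declared alphabet.

    Residues are stored upper-case.  ``alphabet`` is one of ``dna``,
    ``dna-aligned``, ``protein``, ``protein-aligned``; the gap character
    ``-`` is legal only in the aligned alphabets.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("sequence record has an empty id")
        if not self.residues:
            raise SeqFormatError(f"record {self.id!r} has an empty sequence")
        try:
            allowed = _ALPHABETS[self.alphabet]
        except KeyError:
            raise SeqFormatError(f"unknown alphabet {self.alphabet!r}") from None
        object.__setattr__(self, "residues", self.residues.upper().replace(".", "-"))
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise SeqFormatError(
                    f"record {self.id!r}: illegal character {ch!r} at position "
                    f"{pos + 1} for alphabet {self.alphabet!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> "SequenceRecord":
        """Return a copy with gap characters removed (ungapped alphabet)."""
        base = self.alphabet.replace("-aligned", "")
        return SequenceRecord(
            self.id, self.residues.replace("-", ""), self.description, base
        )


def read_fasta(path: str | Path, alphabet: str = "dna") -> List[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Residues are upper-cased; ``.`` is normalised to ``-`` (only legal for
    aligned alphabets).  Duplicate ids and characters outside the alphabet
    raise :class:`SeqFormatError` naming the offending record.
    """
    path = Path(path)
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq),
                description=rec.description[len(rec.id):].strip(),
                alphabet=alphabet,
            )
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _check_iupac(seq: str, what: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch == "-":
            raise SeqFormatError(f"{what}: gap character at position {pos + 1}")
        if ch not in IUPAC_DNA:
            raise SeqFormatError(
                f"{what}: non-IUPAC character {ch!r} at position {pos + 1}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an (optionally degenerate) IUPAC-DNA string."""
    seq = _check_iupac(seq, "reverse_complement")
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate IUPAC string encodes.

    The product over positions of the size of each code's base set; 1 iff
    the sequence is fully concrete.
    """
    seq = _check_iupac(seq, "degeneracy")
    return math.prod(len(IUPAC_DNA[c]) for c in seq)


def expand_degenerate(seq: str, cap: int = 4096) -> Iterator[str]:
    """Yield every concrete expansion of a degenerate string.

    Refuses (ValueError) when the expansion count exceeds ``cap``; intended
    for oracles and small primer sets, not genome-scale strings.
    """
    seq = _check_iupac(seq, "expand_degenerate")
    total = degeneracy(seq)
    if total > cap:
        raise ValueError(f"degeneracy {total} exceeds cap {cap}")

    def _rec(prefix: str, rest: str) -> Iterator[str]:
        if not rest:
            yield prefix
            return
        for b in sorted(IUPAC_DNA[rest[0]]):
            yield from _rec(prefix + b, rest[1:])

    yield from _rec("", seq)


def translate(nt: str) -> str:
    """Translate a nucleotide CDS to protein (standard code, ``*`` = stop)."""
    if len(nt) % 3:
        raise SeqFormatError("CDS length is not a multiple of 3")
    return str(Seq(nt).translate())
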