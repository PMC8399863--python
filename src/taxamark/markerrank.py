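"""Pairwise percent-identity matrices and interspecific discriminability
ranking of candidate marker loci.

A good taxonomic marker shows *low* identity between strains of different
species (wide gaps to cross) while staying amplifiable; the classic contrast
is a protein-coding marker such as *mutL* (interspecific identities in the
60–85% range within a tight species group) against the 16S rRNA gene
(96–100%, useless at this depth).  Ranking is by ascending mean
interspecific identity, the summary the min/max values are reported beside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import percent_identity
from .seqio import SequenceRecord

__all__ = [
    "IdentityMatrix",
    "MarkerDiscriminability",
    "pairwise_identity",
    "identity_matrix",
    "discriminability",
    "rank_markers",
]


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over labelled strains."""

    labels: List[str]
    species: Dict[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("identity matrix is not symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        if v.min() < 0 or v.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")
        missing = [l for l in self.labels if l not in self.species]
        if missing:
            raise ValueError(f"labels without species assignment: {missing}")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe().copy()
        df.insert(0, "species", [self.species[l] for l in self.labels])
        df.to_csv(path, sep="\t", index_label="label")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdentityMatrix":
        """Read a labelled matrix TSV (columns: label, species, then labels)."""
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        species = df["species"].to_dict()
        vals = df.drop(columns="species")
        labels = list(vals.index)
        if list(vals.columns) != labels:
            raise ValueError("matrix rows and columns disagree")
        return cls(labels=labels, species=species, values=vals.to_numpy(float))


@dataclass(frozen=True)
class MarkerDiscriminability:
    """Interspecific identity summary (min/max/mean) for one locus."""

    locus_id: str
    n_interspecific_pairs: int
    min_id: float
    max_id: float
    mean_id: float

    def __post_init__(self) -> None:
        if not (self.min_id <= self.mean_id <= self.max_id):
            raise ValueError("min <= mean <= max violated")


def pairwise_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Percent identity between two DNA sequences after global alignment.

    Alignment is internal (free end gaps); identity counts identical pairs
    over columns where neither sequence has a gap.  The pair is aligned in a
    canonical order, so f(a, b) == f(b, a) even when co-optimal alignments
    with different gap placements exist.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    if sb < sa:
        sa, sb = sb, sa
    return percent_identity(sa, sb)


def identity_matrix(
    seqs: Sequence[SequenceRecord], species: Mapping[str, str]
) -> IdentityMatrix:
    """All-vs-all identity matrix; every unordered pair aligned once."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    missing = [s.id for s in seqs if s.id not in species]
    if missing:
        raise ValueError(f"labels missing from species map: {missing}")
    n = len(seqs)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pairwise_identity(seqs[i], seqs[j])
    return IdentityMatrix(
        labels=[s.id for s in seqs],
        species={s.id: species[s.id] for s in seqs},
        values=vals,
    )


def discriminability(
    matrix: IdentityMatrix, locus_id: str = ""
) -> MarkerDiscriminability:
    """Min/max/mean identity over strictly interspecific strain pairs."""
    pairs: List[float] = []
    labels = matrix.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if matrix.species[labels[i]] != matrix.species[labels[j]]:
                pairs.append(float(matrix.values[i, j]))
    if not pairs:
        raise ValueError("need at least two distinct species")
    arr = np.asarray(pairs)
    return MarkerDiscriminability(
        locus_id=locus_id,
        n_interspecific_pairs=len(pairs),
        min_id=float(arr.min()),
        max_id=float(arr.max()),
        mean_id=float(arr.mean()),
    )


def rank_markers(
    stats: Sequence[MarkerDiscriminability],
) -> List[MarkerDiscriminability]:
    """Most discriminative first: ascending mean, then max, then locus id."""
    if not stats:
        raise ValueError("no marker statistics supplied")
    return sorted(stats, key=lambda s: (s.mean_id, s.max_id, s.locus_id))
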