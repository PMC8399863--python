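"""In-silico PCR: degenerate primer binding, amplicon prediction, and
specificity matrices.

A primer binds where every position is compatible under IUPAC set
intersection, with an exact-match seed enforced at the 3' terminus (the
positions the polymerase extends from).  The default is the strictest
reproducible rule — zero mismatches anywhere — since the effective wet-lab
stringency of a given annealing temperature cannot be known in silico; both
the mismatch budget and the 3' seed width are configurable.

Product sizes include both primer footprints, the standard PCR convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import IUPAC_DNA, SequenceRecord, reverse_complement

#: 4-bit base-set masks (A=1, C=2, G=4, T=8); codes match iff masks intersect
_MASK = {
    code: sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases)
    for code, bases in IUPAC_DNA.items()
}


def _mask_array(seq: str, what: str, strict_n: bool = False) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, c in enumerate(seq):
        try:
            out[i] = _MASK[c]
        except KeyError:
            raise ValueError(
                f"{what}: invalid character {c!r} at position {i + 1}"
            ) from None
        if strict_n and c == "N":
            out[i] = 0
    return out

__all__ = [
    "BindingSite",
    "AmpliconPrediction",
    "SpecificityMatrix",
    "iupac_match",
    "find_binding_sites",
    "predict_amplicons",
    "specificity_matrix",
]


def iupac_match(primer_code: str, template_code: str, strict_n: bool = False) -> bool:
    """True iff the two codes share at least one concrete base.

    With ``strict_n`` an ambiguous template ``N`` (e.g. an unresolved
    sequencing call) counts as a mismatch instead of matching everything.
    """
    if primer_code == "-" or template_code == "-":
        raise ValueError("gap character in iupac_match")
    try:
        p = IUPAC_DNA[primer_code.upper()]
        t = IUPAC_DNA[template_code.upper()]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC code {exc.args[0]!r}") from None
    if strict_n and template_code.upper() == "N":
        return False
    return bool(p & t)


@dataclass(frozen=True)
class BindingSite:
    """One primer annealing position on a template strand."""

    template_id: str
    start: int                  # 0-based, plus-strand coordinate of the window
    strand: str                 # "+" or "-"
    mismatches: int
    three_prime_mismatches: int  # within the 3 bases nearest the primer 3' end


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product (plus-strand half-open coordinates)."""

    pair_name: str
    template_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan(
    window_seq: str,
    template: str,
    three_prime_idx: Sequence[int],
    max_mismatch: int,
    strict_n: bool,
) -> List[Tuple[int, int, int]]:
    """(start, mismatches, three_prime_mismatches) for admissible windows."""
    L = len(window_seq)
    if L > len(template):
        return []
    pmask = _mask_array(window_seq.upper(), "primer")
    tmask = _mask_array(template.upper(), "template", strict_n=strict_n)
    windows = np.lib.stride_tricks.sliding_window_view(tmask, L)
    mismatch = (windows & pmask) == 0          # (n_starts, L) boolean
    totals = mismatch.sum(axis=1)
    tp = np.asarray(list(three_prime_idx), dtype=int)
    tp_clean = ~mismatch[:, tp].any(axis=1)
    hits = np.nonzero((totals <= max_mismatch) & tp_clean)[0]
    return [(int(s), int(totals[s]), 0) for s in hits]


def find_binding_sites(
    primer: str,
    template: SequenceRecord,
    max_mismatch: int = 0,
    seed_3prime: int = 3,
    strict_n: bool = False,
) -> List[BindingSite]:
    """All annealing sites of a degenerate primer on both template strands.

    Sites require total mismatches ≤ ``max_mismatch`` and *zero* mismatches
    in the ``seed_3prime`` positions at the primer's 3' end.  Plus-strand
    sites come first, each strand scanned left to right.
    """
    seq = primer.upper()
    tmpl = template.residues.upper()
    if "-" in tmpl:
        raise ValueError(f"template {template.id!r} contains gaps")
    if len(seq) > len(tmpl):
        return []
    L = len(seq)
    sites: List[BindingSite] = []
    # plus strand: primer 3' end is the window's right end
    tp_plus = range(max(0, L - seed_3prime), L)
    for s, m, t in _scan(seq, tmpl, tp_plus, max_mismatch, strict_n):
        sites.append(BindingSite(template.id, s, "+", m, t))
    # minus strand: match reverse complement; primer 3' end maps to the
    # window's left end on the plus strand
    rc = reverse_complement(seq)
    tp_minus = range(0, min(seed_3prime, L))
    for s, m, t in _scan(rc, tmpl, tp_minus, max_mismatch, strict_n):
        sites.append(BindingSite(template.id, s, "-", m, t))
    return sites


def predict_amplicons(
    pair: "PrimerPairLike",
    template: SequenceRecord,
    max_product: int = 3000,
    max_mismatch: int = 0,
    seed_3prime: int = 3,
    strict_n: bool = False,
) -> List[AmpliconPrediction]:
    """All products a primer pair can amplify from a template.

    A product forms when one primer anneals on the plus strand and the other
    on the minus strand downstream of it (3' ends facing); both orientations
    (forward/plus with reverse/minus and the swap) are considered.  Sorted by
    ascending length, then start.
    """
    fwd, rev = _pair_sequences(pair)
    name = _pair_name(pair)
    f_sites = find_binding_sites(fwd, template, max_mismatch, seed_3prime, strict_n)
    r_sites = find_binding_sites(rev, template, max_mismatch, seed_3prime, strict_n)
    out: List[AmpliconPrediction] = []
    for left_sites, left_len, right_sites, right_len in (
        (f_sites, len(fwd), r_sites, len(rev)),
        (r_sites, len(rev), f_sites, len(fwd)),
    ):
        for ls in left_sites:
            if ls.strand != "+":
                continue
            for rs in right_sites:
                if rs.strand != "-":
                    continue
                end = rs.start + right_len
                if end <= ls.start + left_len:
                    continue  # reverse 3' end not downstream
                if end - ls.start > max_product:
                    continue
                out.append(AmpliconPrediction(name, template.id, ls.start, end))
    out = sorted(set(out), key=lambda a: (a.length, a.start))
    return out


@dataclass
class SpecificityMatrix:
    """Strains × assays table of +/− amplification calls."""

    rows: List[str]
    species: Dict[str, str]
    assays: List[str]
    cells: pd.DataFrame  # index rows, columns assays, values "+"/"−"

    def to_dataframe(self) -> pd.DataFrame:
        df = self.cells.copy()
        df.insert(0, "species", [self.species[r] for r in self.rows])
        return df

    def is_positive(self, row: str, assay: str) -> bool:
        return self.cells.loc[row, assay] == "+"


def specificity_matrix(
    pairs: Sequence["PrimerPairLike"],
    templates: Sequence[SequenceRecord],
    species: Mapping[str, str],
    size_tolerance: float = 0.20,
    max_mismatch: int = 0,
    seed_3prime: int = 3,
) -> SpecificityMatrix:
    """Evaluate every assay against every template.

    A cell is "+" iff the pair yields at least one amplicon within
    ``size_tolerance`` (fractional) of its expected product size; assays are
    independent.
    """
    if not pairs or not templates:
        raise ValueError("need at least one primer pair and one template")
    names = [_pair_name(p) for p in pairs]
    data: Dict[str, List[str]] = {n: [] for n in names}
    for tmpl in templates:
        for p, name in zip(pairs, names):
            expected = _expected_product(p)
            hits = predict_amplicons(
                p, tmpl, max_product=int(expected * (1 + size_tolerance)) + 1,
                max_mismatch=max_mismatch, seed_3prime=seed_3prime,
            )
            lo = expected * (1 - size_tolerance)
            hi = expected * (1 + size_tolerance)
            data[name].append("+" if any(lo <= a.length <= hi for a in hits) else "−")
    rows = [t.id for t in templates]
    cells = pd.DataFrame(data, index=rows)[names]
    return SpecificityMatrix(
        rows=rows,
        species={t.id: species[t.id] for t in templates},
        assays=names,
        cells=cells,
    )


# -- duck-typed access to primer pairs --------------------------------------
# Accepts either primer_design.PrimerPair or a plain (name, fwd, rev,
# expected_product) tuple, so this module has no import cycle.

PrimerPairLike = object


def _pair_sequences(pair) -> Tuple[str, str]:
    if hasattr(pair, "forward"):
        return pair.forward.residues, pair.reverse.residues
    _, fwd, rev, _ = pair
    return fwd, rev


def _pair_name(pair) -> str:
    if hasattr(pair, "name"):
        return pair.name
    return pair[0]


def _expected_product(pair) -> int:
    if hasattr(pair, "expected_product"):
        return pair.expected_product
    return pair[3]
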