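"""Degenerate consensus primers from conserved alignment windows, and
species-specific primer pairs from variable regions.

Two design modes mirror the two assay styles of a marker-based typing scheme:

* *degenerate* — a single pair that amplifies the marker from **every**
  species in the group, built from windows whose IUPAC union consensus stays
  below a degeneracy cap (the printed group-level primers for *mutL*-style
  markers carry degeneracies of 32–64);
* *species-specific* — pairs whose consensus over the target species carries
  enough mismatches against every non-target sequence (with a 3'-terminal
  mismatch preferred, where extension is most sensitive) that only the
  target amplifies.  Candidates are cross-validated with the in-silico PCR
  engine before being returned.

Consensus uses union semantics — every observed base is encoded — because a
degenerate primer must anneal to every known variant, not just the majority.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import insilico_pcr
from .seqio import (
    CODE_FOR_SET,
    IUPAC_DNA,
    SequenceRecord,
    degeneracy,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Msa",
    "DegeneratePrimer",
    "PrimerPair",
    "column_consensus",
    "find_conserved_windows",
    "design_degenerate_pair",
    "design_species_specific",
    "melting_temperature",
]

GAP = "-"


@dataclass
class Msa:
    """A species-labelled multiple sequence alignment (equal-length rows)."""

    records: List[SequenceRecord]
    species: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        n = len(self.records[0].residues)
        for r in self.records:
            if len(r.residues) != n:
                raise ValueError(f"record {r.id!r} breaks equal-length invariant")
        missing = [r.id for r in self.records if r.id not in self.species]
        if missing:
            raise ValueError(f"records without species label: {missing}")

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues)

    def column(self, i: int, rows: Optional[Sequence[int]] = None) -> List[str]:
        idx = range(len(self.records)) if rows is None else rows
        return [self.records[r].residues[i] for r in idx]

    def rows_for_species(self, species: str) -> List[int]:
        return [
            i for i, r in enumerate(self.records) if self.species[r.id] == species
        ]


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC primer anchored to an alignment window."""

    name: str
    residues: str
    msa_start: int
    strand: str  # "+" or "-"
    degeneracy: int = 0
    tm_range: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "degeneracy", degeneracy(self.residues))
        object.__setattr__(self, "tm_range", melting_temperature(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its expected product size."""

    name: str
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    target: str
    expected_product: int

    def __post_init__(self) -> None:
        if self.expected_product <= 0:
            raise ValueError(f"{self.name}: non-positive expected product")

    @property
    def total_degeneracy(self) -> int:
        return self.forward.degeneracy + self.reverse.degeneracy


def column_consensus(column: Iterable[str]) -> str:
    """Smallest IUPAC code covering every base observed in the column.

    Returns ``-`` when any record carries a gap there (the column cannot sit
    inside a primer).
    """
    bases: set[str] = set()
    for c in column:
        c = c.upper()
        if c == GAP:
            return GAP
        bases |= IUPAC_DNA[c]
    if not bases:
        raise ValueError("empty column")
    return CODE_FOR_SET[frozenset(bases)]


@dataclass(frozen=True)
class ConservedWindow:
    start: int
    consensus: str
    degeneracy: int

    def __len__(self) -> int:
        return len(self.consensus)


def find_conserved_windows(
    msa: Msa,
    length_range: Tuple[int, int] = (18, 25),
    max_degeneracy: int = 64,
    rows: Optional[Sequence[int]] = None,
) -> List[ConservedWindow]:
    """All gap-free windows whose union consensus stays within the cap.

    Windows of every length in ``length_range`` (inclusive) are scanned;
    the result is sorted by ascending degeneracy, then start, then length.
    """
    if len(msa.records) < 2 and rows is None:
        raise ValueError("alignment needs at least 2 records")
    lo, hi = length_range
    cons = [column_consensus(msa.column(i, rows)) for i in range(msa.n_cols)]
    out: List[ConservedWindow] = []
    for L in range(lo, hi + 1):
        if L > msa.n_cols:
            continue
        for s in range(msa.n_cols - L + 1):
            window = cons[s : s + L]
            if GAP in window:
                continue
            d = degeneracy("".join(window))
            if d <= max_degeneracy:
                out.append(ConservedWindow(s, "".join(window), d))
    out.sort(key=lambda w: (w.degeneracy, w.start, len(w)))
    return out


def _residue_cumsum(reference: str) -> List[int]:
    """cum[i] = number of reference residues in columns [0, i)."""
    cum = [0]
    for c in reference:
        cum.append(cum[-1] + (c != GAP))
    return cum


def _degapped_length(reference: str, col_start: int, col_end: int) -> int:
    """Number of reference residues in alignment columns [col_start, col_end)."""
    return sum(1 for c in reference[col_start:col_end] if c != GAP)


def design_degenerate_pair(
    msa: Msa,
    product_range: Tuple[int, int],
    length_range: Tuple[int, int] = (18, 25),
    max_degeneracy: int = 64,
    reference_id: Optional[str] = None,
    max_pairs: int = 50,
) -> List[PrimerPair]:
    """Group-level degenerate pairs from conserved flanking windows.

    Forward primers take the window consensus as-is; reverse primers are the
    reverse complement of a downstream window.  The expected product is
    measured on the degapped reference record (the first record unless
    ``reference_id`` names another) and must fall inside ``product_range``.
    For every forward window the single best admissible reverse window
    (lowest degeneracy, then largest product) is paired with it; pairs rank
    by ascending total degeneracy, then descending product size.
    """
    windows = find_conserved_windows(msa, length_range, max_degeneracy)
    if not windows:
        logger.info("no conserved windows under degeneracy cap %d", max_degeneracy)
        return []
    ref = next(
        (r for r in msa.records if reference_id in (None, r.id)), msa.records[0]
    )
    cum = _residue_cumsum(ref.residues)
    lo, hi = product_range
    by_end = sorted(windows, key=lambda w: w.start + len(w))
    end_cums = [cum[w.start + len(w)] for w in by_end]
    pairs: List[PrimerPair] = []
    for wf in windows:
        f_end = wf.start + len(wf)
        lo_cum, hi_cum = cum[wf.start] + lo, cum[wf.start] + hi
        i = bisect_left(end_cums, lo_cum)
        j = bisect_right(end_cums, hi_cum)
        best = None
        for wr in by_end[i:j]:
            if wr.start < f_end:
                continue
            key = (wr.degeneracy, -(cum[wr.start + len(wr)] - cum[wf.start]))
            if best is None or key < best[0]:
                best = (key, wr)
        if best is None:
            continue
        wr = best[1]
        product = cum[wr.start + len(wr)] - cum[wf.start]
        k = len(pairs) + 1
        pairs.append(
            PrimerPair(
                name=f"deg{k}",
                forward=DegeneratePrimer(f"deg{k}-F", wf.consensus, wf.start, "+"),
                reverse=DegeneratePrimer(
                    f"deg{k}-R", reverse_complement(wr.consensus), wr.start, "-"
                ),
                target="group",
                expected_product=product,
            )
        )
    if not pairs:
        logger.info(
            "no window pair yields a product in %s on reference %r",
            product_range, ref.id,
        )
    pairs.sort(key=lambda p: (p.total_degeneracy, -p.expected_product, p.name))
    return pairs[:max_pairs]


def _window_mismatches(
    consensus: str, record_row: str, col_start: int
) -> Tuple[int, List[int]]:
    """Total mismatches and mismatch offsets of a consensus window against a
    record's alignment row (gap in the record counts as mismatch)."""
    total = 0
    offsets: List[int] = []
    for j, code in enumerate(consensus):
        ch = record_row[col_start + j]
        if ch == GAP or not insilico_pcr.iupac_match(code, ch):
            total += 1
            offsets.append(j)
    return total, offsets


def design_species_specific(
    msa: Msa,
    target_species: str,
    primer_length: Tuple[int, int] = (18, 22),
    min_total_mismatch: int = 2,
    require_3prime_mismatch: bool = True,
    product_range: Tuple[int, int] = (80, 500),
    max_degeneracy: int = 8,
    max_pairs: int = 10,
    max_validations: int = 500,
) -> List[PrimerPair]:
    """Primer pairs that amplify only the target species.

    Each primer is the union consensus over the target-species rows of a
    gap-free window, required to carry at least ``min_total_mismatch``
    mismatches against **every** non-target record — with at least one in
    the three 3'-terminal positions when ``require_3prime_mismatch`` — in
    the orientation it will anneal.  Surviving pairs are validated by
    in-silico PCR on the degapped records: positive on all target strains,
    negative on all others.  Returns an empty list (with logged failure
    counts) when the constraints cannot be met.
    """
    t_rows = msa.rows_for_species(target_species)
    if not t_rows:
        raise ValueError(f"no records of species {target_species!r} in alignment")
    nt_rows = [i for i in range(len(msa.records)) if i not in t_rows]
    if not nt_rows:
        raise ValueError("alignment has no non-target species")

    windows = find_conserved_windows(
        msa, primer_length, max_degeneracy, rows=t_rows
    )
    fails = {"total_mismatch": 0, "three_prime": 0}
    fwd_cands: List[ConservedWindow] = []
    rev_cands: List[ConservedWindow] = []
    for w in windows:
        ok_f = ok_r = True
        for r in nt_rows:
            row = msa.records[r].residues
            total, offs = _window_mismatches(w.consensus, row, w.start)
            if total < min_total_mismatch:
                fails["total_mismatch"] += 1
                ok_f = ok_r = False
                break
            if require_3prime_mismatch:
                # forward 3' end = window right end; reverse primer is the
                # reverse complement, so its 3' end = window left end
                if not any(o >= len(w) - 3 for o in offs):
                    ok_f = False
                if not any(o < 3 for o in offs):
                    ok_r = False
                if not (ok_f or ok_r):
                    fails["three_prime"] += 1
                    break
        if ok_f:
            fwd_cands.append(w)
        if ok_r:
            rev_cands.append(w)

    ref = msa.records[t_rows[0]]
    cum = _residue_cumsum(ref.residues)
    lo, hi = product_range
    # admissible combinations, best (lowest-degeneracy, largest-product) first
    combos: List[Tuple[int, int, int, ConservedWindow, ConservedWindow]] = []
    for wf in fwd_cands:
        for wr in rev_cands:
            if wr.start < wf.start + len(wf):
                continue
            product = cum[wr.start + len(wr)] - cum[wf.start]
            if lo <= product <= hi:
                combos.append(
                    (wf.degeneracy + wr.degeneracy, -product, product, wf, wr)
                )
    combos.sort(key=lambda c: (c[0], c[1], c[3].start, c[4].start))

    templates = [r.degapped() for r in msa.records]
    validated: List[PrimerPair] = []
    n_pairs_tried = 0
    tag = target_species.replace(" ", "_")
    for _, _, product, wf, wr in combos[:max_validations]:
        n_pairs_tried += 1
        name = f"sp_{tag}_{len(validated) + 1}"
        pair = PrimerPair(
            name=name,
            forward=DegeneratePrimer(f"{name}-F", wf.consensus, wf.start, "+"),
            reverse=DegeneratePrimer(
                f"{name}-R", reverse_complement(wr.consensus), wr.start, "-"
            ),
            target=target_species,
            expected_product=product,
        )
        if _pair_is_specific(pair, templates, msa.species, target_species):
            validated.append(pair)
            if len(validated) >= max_pairs:
                break
    if not validated:
        logger.info(
            "no specific pair for %r: %d window rejections by total-mismatch, "
            "%d by 3'-rule, %d candidate pairs failed in-silico validation",
            target_species, fails["total_mismatch"], fails["three_prime"],
            n_pairs_tried,
        )
    return validated


def _pair_is_specific(
    pair: PrimerPair,
    templates: Sequence[SequenceRecord],
    species: Mapping[str, str],
    target: str,
) -> bool:
    matrix = insilico_pcr.specificity_matrix([pair], templates, species)
    for t in templates:
        positive = matrix.is_positive(t.id, pair.name)
        if (species[t.id] == target) != positive:
            return False
    return True


def melting_temperature(seq: str) -> Tuple[float, float]:
    """Wallace-rule Tm range of a (possibly degenerate) primer, in °C.

    Tm = 2·(A+T) + 4·(G+C); for degenerate codes the minimum and maximum are
    reached by the least- and most-GC expansion, evaluated per position.
    """
    seq = seq.upper()
    if len(seq) > 30:
        raise ValueError(
            "Wallace rule is unreliable beyond 30 nt; use a thermodynamic "
            "model (override length limit via a custom Tm callable)"
        )
    tmin = tmax = 0.0
    for c in seq:
        if c == GAP:
            raise ValueError("gap character in primer")
        bases = IUPAC_DNA[c]
        contrib = [4.0 if b in "GC" else 2.0 for b in sorted(bases)]
        tmin += min(contrib)
        tmax += max(contrib)
    return tmin, tmax
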