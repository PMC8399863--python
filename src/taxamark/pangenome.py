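"""Pan-genome locus clustering, wgMLST-style allele calling, and candidate
marker selection.

The pipeline mirrors the standard comparative-genomics route to taxonomic
markers: CDS sets from several genomes are clustered into loci at a protein
identity floor (default 75%), presence/absence of each locus is called per
genome at 90% nucleotide identity over 90% coverage of the representative,
alleles are assigned by *exact* sequence match (any single substitution is a
new allele), and core loci are ranked by representative length to pick long,
information-rich candidate markers.

Clustering is a deterministic greedy centroid pass over proteins sorted by
decreasing length — a deliberate simplification of graph-based orthology
tools that reproduces the identity-threshold semantics without external
binaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Literal, Sequence, Tuple

from .alignment import core_stats, presence_stats
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

ABSENT = 0  #: allele id used for genomes in which the locus is not present

__all__ = [
    "GenomeCdsSet",
    "LocusCluster",
    "AlleleTable",
    "cluster_loci",
    "classify_pan_core",
    "pan_core_counts",
    "call_alleles",
    "select_candidates",
    "ABSENT",
]


@dataclass
class GenomeCdsSet:
    """All coding sequences of one genome: paired (nucleotide, protein) records.

    The nucleotide CDS must be 3× the protein length (+3 if it retains the
    stop codon) unless flagged partial.
    """

    genome_id: str
    species: str
    cds: List[Tuple[SequenceRecord, SequenceRecord]]
    partial_ok: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for nt, aa in self.cds:
            if nt.id != aa.id:
                raise ValueError(
                    f"{self.genome_id}: CDS ids differ ({nt.id!r} vs {aa.id!r})"
                )
            if nt.id in seen:
                raise ValueError(f"{self.genome_id}: duplicate CDS id {nt.id!r}")
            seen.add(nt.id)
            if not self.partial_ok and len(nt) not in (3 * len(aa), 3 * len(aa) + 3):
                raise ValueError(
                    f"{self.genome_id}/{nt.id}: nucleotide length {len(nt)} does "
                    f"not match protein length {len(aa)}"
                )

    def nucleotide(self, cds_id: str) -> SequenceRecord:
        for nt, _ in self.cds:
            if nt.id == cds_id:
                return nt
        raise KeyError(f"{self.genome_id}: no CDS {cds_id!r}")


@dataclass
class LocusCluster:
    """A pan-genome locus: at most one member CDS per genome."""

    locus_id: str
    members: Dict[str, str]            # genome_id -> cds id
    representative_genome: str
    representative_id: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.locus_id}: cluster has no members")
        if self.members.get(self.representative_genome) != self.representative_id:
            raise ValueError(f"{self.locus_id}: representative is not a member")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AlleleTable:
    """Exact-match allele assignments for one locus.

    ``alleles`` holds the distinct nucleotide sequences, ids starting at 1 in
    order of first occurrence over lexicographically sorted genomes;
    ``assignment`` maps genome_id to an allele id, or :data:`ABSENT` (0) for
    genomes failing the presence thresholds.
    """

    locus_id: str
    alleles: List[str]
    assignment: Dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.locus_id}: allele sequences not distinct")
        for g, a in self.assignment.items():
            if a != ABSENT and not (1 <= a <= len(self.alleles)):
                raise ValueError(f"{self.locus_id}: genome {g} has unknown allele {a}")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def _canonical_cds_order(
    genomes: Sequence[GenomeCdsSet],
) -> List[Tuple[str, SequenceRecord, SequenceRecord]]:
    """Input-order-independent processing order: protein length desc, then ids."""
    entries = [
        (g.genome_id, nt, aa) for g in genomes for nt, aa in g.cds
    ]
    entries.sort(key=lambda e: (-len(e[2]), e[0], e[1].id))
    return entries


def cluster_loci(
    genomes: Sequence[GenomeCdsSet],
    min_protein_identity: float = 0.75,
    min_mutual_coverage: float = 0.80,
) -> List[LocusCluster]:
    """Greedy centroid clustering of proteins into pan-genome loci.

    Proteins are processed in canonical order (length descending); each joins
    the first existing cluster whose founding centroid it matches at
    ``min_protein_identity`` over ``min_mutual_coverage`` of both sequences,
    otherwise it founds a new cluster.  If a genome would contribute a second
    member to a cluster, the member with the better centroid identity stays
    and the other founds a paralog cluster.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")

    # cluster state: centroid protein, members {genome: (cds_id, identity)}
    centroids: List[SequenceRecord] = []
    centroid_genome: List[str] = []
    memberships: List[Dict[str, Tuple[str, float]]] = []

    def _found(genome_id: str, nt_id: str, aa: SequenceRecord) -> None:
        centroids.append(aa)
        centroid_genome.append(genome_id)
        memberships.append({genome_id: (nt_id, 1.0)})

    queue = _canonical_cds_order(genomes)
    while queue:
        genome_id, nt, aa = queue.pop(0)
        placed = False
        for ci, centroid in enumerate(centroids):
            stats = core_stats(centroid.residues, aa.residues, protein=True)
            if (
                stats.identity >= min_protein_identity
                and stats.coverage_a >= min_mutual_coverage
                and stats.coverage_b >= min_mutual_coverage
            ):
                existing = memberships[ci].get(genome_id)
                if existing is None:
                    memberships[ci][genome_id] = (nt.id, stats.identity)
                elif stats.identity > existing[1]:
                    # better paralog displaces; the old member founds a new cluster
                    memberships[ci][genome_id] = (nt.id, stats.identity)
                    old_nt = next(
                        g.nucleotide(existing[0])
                        for g in genomes
                        if g.genome_id == genome_id
                    )
                    old_aa = next(
                        p for g in genomes if g.genome_id == genome_id
                        for n, p in g.cds if n.id == existing[0]
                    )
                    _found(genome_id, old_nt.id, old_aa)
                else:
                    _found(genome_id, nt.id, aa)
                placed = True
                break
        if not placed:
            _found(genome_id, nt.id, aa)

    by_genome = {g.genome_id: g for g in genomes}
    clusters: List[LocusCluster] = []
    for ci, members in enumerate(memberships):
        # representative = longest nucleotide member, ties by (genome, cds) id
        rep_genome, (rep_id, _) = max(
            members.items(),
            key=lambda kv: (
                len(by_genome[kv[0]].nucleotide(kv[1][0])),
                kv[0],
                kv[1][0],
            ),
        )
        clusters.append(
            LocusCluster(
                locus_id=f"locus_{ci + 1:05d}",
                members={g: cid for g, (cid, _) in sorted(members.items())},
                representative_genome=rep_genome,
                representative_id=rep_id,
            )
        )
    return clusters


def classify_pan_core(
    clusters: Sequence[LocusCluster], n_genomes: int
) -> Dict[str, Literal["core", "accessory"]]:
    """Label each locus core (present in every genome) or accessory."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    return {
        c.locus_id: "core" if c.size == n_genomes else "accessory" for c in clusters
    }


def pan_core_counts(
    clusters: Sequence[LocusCluster], n_genomes: int
) -> Tuple[int, int]:
    """(pan, core) locus counts over a genome set."""
    labels = classify_pan_core(clusters, n_genomes)
    return len(clusters), sum(1 for v in labels.values() if v == "core")


def call_alleles(
    cluster: LocusCluster,
    genomes: Sequence[GenomeCdsSet],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> AlleleTable:
    """Presence calls at identity/coverage thresholds, alleles by exact match.

    A genome is present iff its member aligns to the cluster representative at
    ``min_identity`` over ``min_coverage`` of the representative length.
    Among present members, identical nucleotide strings share an allele id;
    any difference — even one substitution — yields a new id.  Ids follow
    first occurrence over genomes sorted lexicographically.
    """
    by_genome = {g.genome_id: g for g in genomes}
    rep = by_genome[cluster.representative_genome].nucleotide(
        cluster.representative_id
    )
    alleles: List[str] = []
    assignment: Dict[str, int] = {}
    for genome_id in sorted(cluster.members):
        seq = by_genome[genome_id].nucleotide(cluster.members[genome_id]).residues
        if genome_id == cluster.representative_genome:
            identity, coverage = 1.0, 1.0
        else:
            identity, coverage = presence_stats(rep.residues, seq)
        if identity < min_identity or coverage < min_coverage:
            assignment[genome_id] = ABSENT
            continue
        try:
            allele_id = alleles.index(seq) + 1
        except ValueError:
            alleles.append(seq)
            allele_id = len(alleles)
        assignment[genome_id] = allele_id
    return AlleleTable(cluster.locus_id, alleles, assignment)


@dataclass
class CandidateLocus:
    """A core locus with its allele table, ready for marker ranking."""

    cluster: LocusCluster
    table: AlleleTable
    representative_length: int


def select_candidates(
    candidates: Sequence[CandidateLocus],
    k: int,
    key: Literal["length", "allele_count"] = "length",
) -> List[CandidateLocus]:
    """Top-``k`` candidate marker loci.

    Default ranking is by decreasing representative nucleotide length (long
    loci carry more discriminating sites); ``allele_count`` ranks by number
    of distinct alleles instead.  Ties break by locus id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if key == "length":
        order = sorted(
            candidates,
            key=lambda c: (-c.representative_length, c.cluster.locus_id),
        )
    elif key == "allele_count":
        order = sorted(
            candidates,
            key=lambda c: (-c.table.n_alleles, c.cluster.locus_id),
        )
    else:
        raise ValueError(f"unknown sort key {key!r}")
    if k > len(order):
        logger.warning(
            "requested %d candidates but only %d loci available", k, len(order)
        )
    return order[:k]
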