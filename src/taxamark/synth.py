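"""Synthetic species groups with controlled divergence structure.

The generator emulates the situation the toolkit is built for: a tight
bacterial species group (several species, a few strains each) genotyped at
loci whose interspecific divergence spans the useful range — from an
rRNA-like locus at ~1.6% divergence (identities 96–100%, no resolution) to a
protein-coding marker at ~33% (identities in the 60s, clean species
separation).  Sequences evolve under the exact Kimura two-parameter
continuous-time process, the same model the distance estimator inverts, so
parameter recovery is a clean end-to-end check.

Branch lengths are calibrated numerically: the requested interspecific
divergence is the *mean pairwise* p-distance between species, realised on a
random coalescent-style bifurcating species tree.  One locus can carry
planted features for the primer stages — conserved flanking windows shared
by every genome and a species-unique window in between.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .pangenome import GenomeCdsSet
from .phylo import Tree, TreeNode, to_newick
from .seqio import SequenceRecord, translate, write_fasta

__all__ = [
    "LocusSpec",
    "GroupSpec",
    "GroupTruth",
    "mutate_sequence",
    "generate_species_group",
    "plantarum_like_preset",
    "divergence_to_time",
    "expected_p_distance",
]

_BASES = "ACGT"


# -- K2P process -------------------------------------------------------------

def _rates(kappa: float) -> Tuple[float, float]:
    """(alpha, beta) normalised to one expected substitution per site per
    unit time: alpha + 2*beta = 1 with alpha/beta = kappa."""
    beta = 1.0 / (kappa + 2.0)
    return kappa * beta, beta


def expected_p_distance(t: float, kappa: float) -> float:
    """Expected proportion of differing sites after time t under K2P."""
    alpha, beta = _rates(kappa)
    p_ts = 0.25 + 0.25 * np.exp(-4 * beta * t) - 0.5 * np.exp(-2 * (alpha + beta) * t)
    q_tv = 0.5 - 0.5 * np.exp(-4 * beta * t)
    return float(p_ts + q_tv)


def divergence_to_time(divergence: float, kappa: float) -> float:
    """Branch time (substitutions/site) whose expected p-distance is given."""
    if not (0.0 <= divergence < 0.75):
        raise ValueError("divergence must lie in [0, 0.75)")
    if divergence == 0.0:
        return 0.0
    return brentq(lambda t: expected_p_distance(t, kappa) - divergence, 0.0, 50.0)


def _transition_matrix(t: float, kappa: float) -> np.ndarray:
    """4x4 K2P transition probabilities, base order A,C,G,T."""
    alpha, beta = _rates(kappa)
    p_ts = 0.25 + 0.25 * np.exp(-4 * beta * t) - 0.5 * np.exp(-2 * (alpha + beta) * t)
    q_half = 0.25 - 0.25 * np.exp(-4 * beta * t)  # each transversion target
    same = 1.0 - p_ts - 2 * q_half
    P = np.empty((4, 4))
    transition_partner = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T
    for x in range(4):
        for y in range(4):
            if x == y:
                P[x, y] = same
            elif y == transition_partner[x]:
                P[x, y] = p_ts
            else:
                P[x, y] = q_half
    return P


def _evolve(enc: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    if t == 0.0:
        return enc.copy()
    P = _transition_matrix(t, kappa)
    cum = P.cumsum(axis=1)
    u = rng.random(enc.shape[0])
    out = np.empty_like(enc)
    for x in range(4):
        mask = enc == x
        out[mask] = np.searchsorted(cum[x], u[mask], side="right")
    return np.clip(out, 0, 3)


def _decode(enc: np.ndarray) -> str:
    return "".join(_BASES[c] for c in enc)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASES.index(c) for c in seq.upper()], dtype=np.int8)


def mutate_sequence(
    seq: str, expected_divergence: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a concrete DNA sequence so E[p-distance] equals the request.

    Substitutions follow the K2P process (transitions favoured by kappa);
    the branch time is solved from the requested expected divergence, so the
    distance estimator applied to (input, output) recovers that time.
    """
    if any(c not in _BASES for c in seq.upper()):
        raise ValueError("mutate_sequence needs a concrete A/C/G/T sequence")
    t = divergence_to_time(expected_divergence, kappa)
    return _decode(_evolve(_encode(seq), t, kappa, rng))


# -- group specification -----------------------------------------------------

@dataclass(frozen=True)
class LocusSpec:
    """One locus: length and its target inter-/intraspecific divergence."""

    name: str
    length: int
    interspecific_divergence: float
    intraspecific_divergence: float
    planted_primer_sites: bool = False

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError(f"{self.name}: locus length must be >= 100")
        for d in (self.interspecific_divergence, self.intraspecific_divergence):
            if not (0.0 <= d < 0.75):
                raise ValueError(f"{self.name}: divergence must lie in [0, 0.75)")


@dataclass(frozen=True)
class GroupSpec:
    """A synthetic species group: sizes, loci, substitution model, seed."""

    n_species: int
    strains_per_species: int
    loci: Tuple[LocusSpec, ...]
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.strains_per_species < 1:
            raise ValueError("need at least one species and one strain")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not self.loci:
            raise ValueError("need at least one locus")


@dataclass
class PlantedSites:
    """Coordinates (0-based, on the locus) of engineered primer features."""

    locus: str
    conserved_forward: Tuple[int, int]       # identical across all genomes
    conserved_reverse: Tuple[int, int]
    #: per-species pair of distinct windows (forward site, reverse site) —
    #: a species-specific assay needs two discriminating anneal sites
    species_unique: Dict[str, List[Tuple[int, int]]]


@dataclass
class GroupTruth:
    """Everything needed to score downstream stages without re-simulation."""

    spec: GroupSpec
    genomes: List[GenomeCdsSet]
    species_tree_newick: str
    realized_interspecific_divergence: Dict[str, float]
    planted: Optional[PlantedSites]

    @property
    def labels(self) -> Dict[str, str]:
        return {g.genome_id: g.species for g in self.genomes}

    def locus_records(self, locus: str) -> List[SequenceRecord]:
        out = []
        for g in self.genomes:
            nt = g.nucleotide(locus)
            out.append(SequenceRecord(g.genome_id, nt.residues, alphabet="dna"))
        return out


#: Coalescence heights are compressed into this fraction band of the tree
#: depth so every species pair is clearly (and comparably) diverged — the
#: situation in a recognised species group — and no pair drifts into the
#: divergence regime where alignment identity becomes unreliable.
_HEIGHT_BAND = (0.7, 1.0)


def _random_species_tree(
    n: int, rng: np.random.Generator
) -> Tuple[Tree, np.ndarray, List[str]]:
    """Random coalescent-topology ultrametric tree; returns (tree, pairwise
    path-length matrix normalised to max path 1, species names)."""
    names = [f"sp{i + 1:02d}" for i in range(n)]
    if n == 1:
        return Tree(TreeNode(names[0])), np.zeros((1, 1)), names
    # phase 1: coalescent joins with raw exponential waiting times
    events: List[Tuple[int, int, float]] = []
    active = list(range(n))
    next_id = n
    h = 0.0
    k = n
    while len(active) > 1:
        h += float(rng.exponential(1.0 / (k * (k - 1) / 2.0)))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        events.append((a, b, h))
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
        k -= 1
    # phase 2: compress node heights into the band (order preserved)
    hmax = events[-1][2]
    lo, hi = _HEIGHT_BAND
    events = [
        (a, b, hmax * (lo + (hi - lo) * (hh / hmax))) for a, b, hh in events
    ]
    hmax = events[-1][2]
    # phase 3: build nodes and the tip-tip path matrix (tips at depth hmax)
    nodes = [TreeNode(nm) for nm in names]
    heights = [0.0] * n
    members: List[List[int]] = [[i] for i in range(n)]
    paths = np.zeros((n, n))
    for a, b, hh in events:
        for x in members[a]:
            for y in members[b]:
                paths[x, y] = paths[y, x] = 2 * hh
        nodes[a].length = hh - heights[a]
        nodes[b].length = hh - heights[b]
        nodes.append(TreeNode(children=[nodes[a], nodes[b]]))
        heights.append(hh)
        members.append(members[a] + members[b])
    paths /= 2 * hmax
    root = nodes[-1]

    def _rescale(node: TreeNode) -> None:
        node.length /= 2 * hmax
        for c in node.children:
            _rescale(c)

    _rescale(root)
    root.length = 0.0
    return Tree(root), paths, names


def _calibrate_scale(
    paths: np.ndarray, target_divergence: float, kappa: float
) -> float:
    """Tree scale s such that mean over pairs of p(s * path) = target."""
    iu = np.triu_indices(paths.shape[0], 1)
    lengths = paths[iu]
    if target_divergence == 0.0 or lengths.size == 0:
        return 0.0

    def mean_p(s: float) -> float:
        return float(
            np.mean([expected_p_distance(s * L, kappa) for L in lengths])
        )

    return brentq(lambda s: mean_p(s) - target_divergence, 0.0, 200.0)


def _random_cds_root(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random sequence (length rounded up to a codon multiple upstream)."""
    return rng.integers(0, 4, size=length).astype(np.int8)


def _evolve_along_tree(
    node: TreeNode,
    enc: np.ndarray,
    scale: float,
    kappa: float,
    rng: np.random.Generator,
    out: Dict[str, np.ndarray],
) -> None:
    here = _evolve(enc, node.length * scale, kappa, rng)
    if node.is_leaf:
        out[node.name or ""] = here
        return
    for c in node.children:
        _evolve_along_tree(c, here, scale, kappa, rng, out)


def _plant_window(
    seqs: Dict[str, np.ndarray], start: int, window: np.ndarray
) -> None:
    for arr in seqs.values():
        arr[start : start + window.size] = window


def generate_species_group(spec: GroupSpec) -> GroupTruth:
    """Simulate a full species group with per-genome CDS sets.

    Reproducible from the spec's seed: one random species tree is shared by
    all loci, each locus scaled to its own interspecific target; strains are
    independent draws around their species sequence at the intraspecific
    divergence.  A locus flagged ``planted_primer_sites`` gets identical
    20-nt flanks across all genomes (degenerate-primer substrate) and a
    species-unique 20-nt window in between (species-specific substrate).
    """
    rng = np.random.default_rng(spec.seed)
    tree, paths, species_names = _random_species_tree(spec.n_species, rng)

    per_species_locus: Dict[str, Dict[str, np.ndarray]] = {
        nm: {} for nm in species_names
    }
    realized: Dict[str, float] = {}
    planted: Optional[PlantedSites] = None

    for locus in spec.loci:
        length = 3 * ((locus.length + 2) // 3)  # codon multiple for CDS pairing
        root = _random_cds_root(length, rng)
        scale = _calibrate_scale(paths, locus.interspecific_divergence, spec.kappa)
        species_seqs: Dict[str, np.ndarray] = {}
        if spec.n_species == 1:
            species_seqs[species_names[0]] = root.copy()
        else:
            _evolve_along_tree(
                tree.root, root, scale, spec.kappa, rng, species_seqs
            )
        if locus.planted_primer_sites:
            if length < 300:
                raise ValueError(
                    f"{locus.name}: planted primer sites need length >= 300"
                )
            # fixed windows: [30,50) and [length-50, length-30) conserved;
            # unique windows around the centre, distinct across species
            f_win = rng.integers(0, 4, size=20).astype(np.int8)
            r_win = rng.integers(0, 4, size=20).astype(np.int8)
            _plant_window(species_seqs, 30, f_win)
            _plant_window(species_seqs, length - 50, r_win)
            # two unique windows per species, far enough apart for a product
            starts = (length // 2 - 75, length // 2 + 75)
            unique: Dict[str, List[Tuple[int, int]]] = {nm: [] for nm in species_names}
            for start in starts:
                used: List[np.ndarray] = []
                for nm in species_names:
                    while True:
                        w = rng.integers(0, 4, size=20).astype(np.int8)
                        if all(int((w != u).sum()) >= 8 for u in used):
                            break
                    used.append(w)
                    species_seqs[nm][start : start + 20] = w
                    unique[nm].append((start, start + 20))
            planted = PlantedSites(
                locus=locus.name,
                conserved_forward=(30, 50),
                conserved_reverse=(length - 50, length - 30),
                species_unique=unique,
            )
        # realized mean interspecific p-distance (before strain noise)
        if spec.n_species > 1:
            ps = []
            for i in range(spec.n_species):
                for j in range(i + 1, spec.n_species):
                    a = species_seqs[species_names[i]]
                    b = species_seqs[species_names[j]]
                    ps.append(float((a != b).mean()))
            realized[locus.name] = float(np.mean(ps))
        else:
            realized[locus.name] = 0.0
        t_intra = divergence_to_time(locus.intraspecific_divergence, spec.kappa)
        for nm in species_names:
            for s in range(spec.strains_per_species):
                strain_seq = _evolve(species_seqs[nm], t_intra, spec.kappa, rng)
                per_species_locus[nm].setdefault(f"s{s + 1}", {})
                per_species_locus[nm][f"s{s + 1}"][locus.name] = strain_seq  # type: ignore[index]

    genomes: List[GenomeCdsSet] = []
    for nm in species_names:
        for s in range(spec.strains_per_species):
            gid = f"{nm}_s{s + 1}"
            cds = []
            for locus in spec.loci:
                nt_seq = _decode(per_species_locus[nm][f"s{s + 1}"][locus.name])
                nt = SequenceRecord(locus.name, nt_seq, alphabet="dna")
                aa = SequenceRecord(locus.name, translate(nt_seq), alphabet="protein")
                cds.append((nt, aa))
            genomes.append(GenomeCdsSet(gid, nm, cds))
    return GroupTruth(
        spec=spec,
        genomes=genomes,
        species_tree_newick=to_newick(tree) if spec.n_species > 1 else f"({species_names[0]});",
        realized_interspecific_divergence=realized,
        planted=planted,
    )


def plantarum_like_preset(seed: int = 0) -> GroupSpec:
    """A 17-species, one-strain-per-species group with the canonical marker
    contrast: one locus at 33% mean interspecific divergence (protein-coding
    marker-like) and one at 1.6% (rRNA-like).  500-nt loci keep all-vs-all
    alignment affordable while leaving divergence estimates tight."""
    return GroupSpec(
        n_species=17,
        strains_per_species=1,
        loci=(
            LocusSpec("marker_like", 500, 0.33, 0.0),
            LocusSpec("rrna_like", 500, 0.016, 0.0),
        ),
        kappa=2.0,
        seed=seed,
    )


def write_group(truth: GroupTruth, outdir: str | Path) -> None:
    """Emit per-genome CDS FASTA, a labels TSV, and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in truth.genomes:
        write_fasta([nt for nt, _ in g.cds], outdir / f"{g.genome_id}.cds.fasta")
        write_fasta(
            [
                SequenceRecord(aa.id, aa.residues, alphabet="protein")
                for _, aa in g.cds
            ],
            outdir / f"{g.genome_id}.faa",
        )
    with (outdir / "labels.tsv").open("w") as fh:
        fh.write("genome_id\tspecies\n")
        for g in truth.genomes:
            fh.write(f"{g.genome_id}\t{g.species}\n")
    meta = {
        "seed": truth.spec.seed,
        "kappa": truth.spec.kappa,
        "species_tree": truth.species_tree_newick,
        "realized_interspecific_divergence": truth.realized_interspecific_divergence,
        "planted": asdict(truth.planted) if truth.planted else None,
        "loci": [asdict(l) for l in truth.spec.loci],
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=2))
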