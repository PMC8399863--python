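"""Kimura two-parameter distances, neighbour joining with bootstrap, newick
output, and haplotype counting.

The K2P model corrects observed divergence separately for transitions (P)
and transversions (Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

estimated over pairwise-deleted columns (positions with a gap or ambiguity
in either sequence are dropped for that pair).  Trees are built with the
Saitou–Nei neighbour-joining algorithm; ties in the Q-criterion break on the
lexicographically smallest label pair and negative branch lengths are
clamped to zero with the deficit moved to the sister edge, so the
reconstruction is fully deterministic.  Bootstrap supports come from
column resampling with replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "HaplotypeAssignment",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "bootstrap_support",
    "count_haplotypes",
    "to_newick",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class SaturationError(ValueError):
    """Raised when divergence exceeds the K2P model's invertible range."""


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; gaps and ambiguity codes -> -1 (dropped pairwise)."""
    arr = np.full(len(seq), -1, dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        arr[i] = _CODE.get(c, -1)
    return arr


def _k2p_from_counts(n: int, transitions: int, transversions: int, label: str) -> float:
    if n == 0:
        raise ValueError(f"{label}: no shared ungapped, unambiguous columns")
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"{label}: saturated (P={P:.3f}, Q={Q:.3f}); K2P distance undefined"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(a: str | SequenceRecord, b: str | SequenceRecord) -> float:
    """K2P distance between two aligned sequences (pairwise deletion)."""
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError("aligned sequences must have equal length")
    ea, eb = _encode(sa), _encode(sb)
    valid = (ea >= 0) & (eb >= 0)
    n = int(valid.sum())
    diff = valid & (ea != eb)
    # purines A,G encode to even; pyrimidines C,T to odd: a substitution is a
    # transition iff the two codes share parity
    transitions = int((diff & ((ea % 2) == (eb % 2))).sum())
    transversions = int(diff.sum()) - transitions
    label = f"pair ({getattr(a, 'id', 'a')}, {getattr(b, 'id', 'b')})"
    return _k2p_from_counts(n, transitions, transversions, label)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site)."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if (v < 0).any():
            raise ValueError("negative distances")
        self.values = v


def k2p_matrix(
    records: Sequence[SequenceRecord], deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs K2P matrix from an alignment.

    ``deletion="complete"`` first removes every column holding a gap or
    ambiguity in *any* record, matching the stricter MEGA configuration.
    """
    seqs = [r.residues for r in records]
    if deletion == "complete":
        enc = np.stack([_encode(s) for s in seqs])
        keep = (enc >= 0).all(axis=0)
        enc = enc[:, keep]
        seqs = ["".join("ACGT"[c] for c in row) for row in enc]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = len(records)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(seqs[i], seqs[j])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix([r.id for r in records], vals)


@dataclass
class TreeNode:
    name: Optional[str] = None          # leaf label
    length: float = 0.0                 # branch length to parent
    support: Optional[float] = None     # bootstrap %, internal edges only
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """An unrooted tree stored with an arbitrary internal traversal root."""

    root: TreeNode

    @property
    def leaf_names(self) -> List[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Non-trivial splits, canonicalised to the side *excluding* the
        lexicographically smallest leaf."""
        all_leaves = set(self.root.leaves())
        ref = min(all_leaves)
        out: Set[FrozenSet[str]] = set()

        def _walk(node: TreeNode) -> Set[str]:
            if node.is_leaf:
                return {node.name or ""}
            below: Set[str] = set()
            for c in node.children:
                below |= _walk(c)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                out.add(frozenset(side))
            return below

        _walk(self.root)
        return out

    def edge_supports(self) -> Dict[FrozenSet[str], Optional[float]]:
        all_leaves = set(self.root.leaves())
        ref = min(all_leaves)
        out: Dict[FrozenSet[str], Optional[float]] = {}

        def _walk(node: TreeNode) -> Set[str]:
            if node.is_leaf:
                return {node.name or ""}
            below: Set[str] = set()
            for c in node.children:
                below |= _walk(c)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                out[frozenset(side)] = node.support
            return below

        _walk(self.root)
        return out


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Joins minimise the Q-criterion; ties go to the lexicographically
    smallest (label_i, label_j) pair, where an internal node carries the
    smallest leaf label beneath it.  Negative branch lengths are clamped to
    zero and the deficit moved to the sister branch.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances")
    if n == 2:
        half = d.values[0, 1] / 2.0
        a = TreeNode(d.labels[0], half)
        b = TreeNode(d.labels[1], half)
        return Tree(TreeNode(children=[a, b]))

    nodes: List[TreeNode] = [TreeNode(lbl) for lbl in d.labels]
    tags: List[str] = list(d.labels)  # tie-break label per active node
    D = d.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best: Tuple[float, Tuple[str, str], int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((tags[i], tags[j])))
                cand = (q, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        assert best is not None
        _, _, i, j = best
        dij = D[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        nodes[i].length = bi
        nodes[j].length = bj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # grow matrix with the new node's distances
        new = len(nodes)
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = sorted(active, key=lambda x: tags[x])
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, b in ((i, bi), (j, bj), (k, bk)):
        nodes[idx].length = max(b, 0.0)
    return Tree(TreeNode(children=[nodes[i], nodes[j], nodes[k]]))


def bootstrap_support(
    records: Sequence[SequenceRecord],
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> Tree:
    """NJ tree with bootstrap supports from column resampling.

    Each replicate resamples alignment columns with replacement, rebuilds the
    K2P+NJ tree, and scores every internal bipartition; support is the
    percentage of successful replicates containing the same split.
    Replicates hitting K2P saturation are dropped; more than 10% dropped is
    an error.  Deterministic for a fixed seed.
    """
    if len(records) < 4:
        raise ValueError("bootstrap needs at least 4 records")
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    labels = [r.id for r in records]
    ncols = len(records[0].residues)
    enc = np.stack([_encode(r.residues) for r in records])
    if deletion == "complete":
        enc = enc[:, (enc >= 0).all(axis=0)]
        ncols = enc.shape[1]

    def _matrix(cols: np.ndarray) -> DistanceMatrix:
        sub = enc[:, cols]
        nrec = len(records)
        vals = np.zeros((nrec, nrec))
        for i in range(nrec):
            for j in range(i + 1, nrec):
                ea, eb = sub[i], sub[j]
                valid = (ea >= 0) & (eb >= 0)
                nn = int(valid.sum())
                diff = valid & (ea != eb)
                ts = int((diff & ((ea % 2) == (eb % 2))).sum())
                tv = int(diff.sum()) - ts
                vals[i, j] = vals[j, i] = _k2p_from_counts(
                    nn, ts, tv, f"pair ({labels[i]}, {labels[j]})"
                )
        return DistanceMatrix(labels, vals)

    base = nj_tree(_matrix(np.arange(ncols)))
    rng = np.random.default_rng(seed)
    counts: Dict[FrozenSet[str], int] = {}
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        try:
            rep_tree = nj_tree(_matrix(cols))
        except (SaturationError, ValueError):
            dropped += 1
            continue
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    if dropped > 0.10 * replicates:
        raise SaturationError(
            f"{dropped}/{replicates} bootstrap replicates saturated"
        )
    ok = replicates - dropped

    def _attach(node: TreeNode, all_leaves: Set[str], ref: str) -> Set[str]:
        if node.is_leaf:
            return {node.name or ""}
        below: Set[str] = set()
        for c in node.children:
            below |= _attach(c, all_leaves, ref)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            node.support = 100.0 * counts.get(frozenset(side), 0) / ok
        return below

    leaves = set(base.root.leaves())
    _attach(base.root, leaves, min(leaves))
    return base


@dataclass(frozen=True)
class HaplotypeAssignment:
    """Exact-sequence equivalence classes over retained alignment columns."""

    n_haplotypes: int
    assignment: Dict[str, int]
    used_sites: int


def count_haplotypes(
    records: Sequence[SequenceRecord], include_ambiguous: bool = False
) -> HaplotypeAssignment:
    """Haplotypes by exact match after complete deletion of unusable columns.

    Columns holding a gap or ambiguity code in *any* record are removed
    (the convention of standard haplotype software); with
    ``include_ambiguous`` gaps/ambiguities are kept as fifth states instead.
    Haplotype ids follow first occurrence in input order.
    """
    if not records:
        raise ValueError("no records")
    ncols = len(records[0].residues)
    if any(len(r.residues) != ncols for r in records):
        raise ValueError("records must be aligned to equal length")
    if include_ambiguous:
        keep = list(range(ncols))
    else:
        enc = np.stack([_encode(r.residues) for r in records])
        keep = [i for i in range(ncols) if (enc[:, i] >= 0).all()]
        if not keep:
            raise ValueError("no columns retained after complete deletion")
    seen: Dict[str, int] = {}
    assignment: Dict[str, int] = {}
    for r in records:
        key = "".join(r.residues[i] for i in keep)
        if key not in seen:
            seen[key] = len(seen) + 1
        assignment[r.id] = seen[key]
    return HaplotypeAssignment(len(seen), assignment, len(keep))


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.10g}"
    inner = ",".join(_newick_node(c) for c in node.children)
    label = "" if node.support is None else f"{node.support:.10g}"
    return f"({inner}){label}:{node.length:.10g}"


def to_newick(tree: Tree) -> str:
    """Newick string with branch lengths; bootstrap supports appear as
    internal node labels."""
    root = tree.root
    inner = ",".join(_newick_node(c) for c in root.children)
    return f"({inner});"
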