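"""Test-local tree oracles, independent of the package's NJ implementation.

* random unrooted binary trees with positive branch lengths, plus their
  additive leaf-leaf distance matrices and bipartition sets;
* exhaustive unrooted-topology enumeration with least-squares branch
  fitting, for verifying that the additive matrix's best-fit topology is the
  generating one.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

Adjacency = Dict[int, Dict[int, float]]


def random_unrooted_tree(
    n: int, rng: np.random.Generator, min_len: float = 0.1, max_len: float = 1.0
) -> Tuple[Adjacency, List[str]]:
    """Random binary unrooted tree over leaves 0..n-1 by random edge attachment."""
    assert n >= 3
    center = n  # internal node ids start at n; 0..n-1 are leaves
    adj: Adjacency = {0: {}, 1: {}, 2: {}, center: {}}
    for leaf in (0, 1, 2):
        w = float(rng.uniform(min_len, max_len))
        adj[leaf][center] = w
        adj[center][leaf] = w
    next_id = n + 1
    for leaf in range(3, n):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        mid, new_leaf = next_id, leaf
        next_id += 1
        old = adj[a].pop(b)
        adj[b].pop(a)
        split = float(rng.uniform(0.25, 0.75))
        adj[mid] = {}
        adj[a][mid] = adj[mid][a] = old * split
        adj[b][mid] = adj[mid][b] = old * (1 - split)
        w = float(rng.uniform(min_len, max_len))
        adj.setdefault(new_leaf, {})
        adj[new_leaf][mid] = w
        adj[mid][new_leaf] = w
    labels = [f"T{i:02d}" for i in range(n)]
    return adj, labels


def tree_distances(adj: Adjacency, n: int) -> np.ndarray:
    """Leaf-leaf path-length matrix via Dijkstra-free DFS (trees are acyclic)."""
    D = np.zeros((n, n))
    for src in range(n):
        stack = [(src, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node < n and node != src:
                D[src, node] = dist
            for nbr, w in adj[node].items():
                if nbr != parent:
                    stack.append((nbr, node, dist + w))
    return D


def tree_bipartitions(adj: Adjacency, n: int, labels: List[str]) -> Set[FrozenSet[str]]:
    """Non-trivial splits, canonicalised to exclude the smallest label."""
    ref = min(labels)
    out: Set[FrozenSet[str]] = set()
    for a in adj:
        for b in adj[a]:
            if a < b:
                side = _leaves_beyond(adj, b, a, n)
                names = {labels[x] for x in side}
                if 1 < len(names) < n - 1:
                    if ref in names:
                        names = set(labels) - names
                    out.add(frozenset(names))
    return out


def _leaves_beyond(adj: Adjacency, start: int, blocked: int, n: int) -> List[int]:
    seen, stack, leaves = {blocked}, [start], []
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        if node < n:
            leaves.append(node)
        stack.extend(adj[node])
    return leaves


# -- exhaustive enumeration + least squares ---------------------------------

def enumerate_topologies(n: int) -> List[Adjacency]:
    """All unrooted binary topologies over leaves 0..n-1 (unit lengths)."""
    assert 4 <= n <= 6, "enumeration is only affordable for small n"
    hub = n  # internal ids start at n
    base: Adjacency = {0: {hub: 1.0}, 1: {hub: 1.0}, 2: {hub: 1.0},
                      hub: {0: 1.0, 1: 1.0, 2: 1.0}}
    tops = [base]
    for leaf in range(3, n):
        grown: List[Adjacency] = []
        for top in tops:
            edges = [(a, b) for a in top for b in top[a] if a < b]
            for a, b in edges:
                new = {x: dict(y) for x, y in top.items()}
                mid = max(new) + 1
                del new[a][b]
                del new[b][a]
                new[mid] = {a: 1.0, b: 1.0, leaf: 1.0}
                new[a][mid] = new[b][mid] = 1.0
                new.setdefault(leaf, {})[mid] = 1.0
                grown.append(new)
        tops = grown
    return tops


def ls_fit_sse(top: Adjacency, D: np.ndarray, n: int) -> float:
    """Least-squares branch-length fit of a topology to a distance matrix."""
    edges = [(a, b) for a in top for b in top[a] if a < b]
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    for r, (i, j) in enumerate(pairs):
        path = _path_edges(top, i, j)
        for e in path:
            A[r, edges.index(e)] = 1.0
    y = np.array([D[i, j] for i, j in pairs])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ coef - y) ** 2).sum())


def _path_edges(top: Adjacency, src: int, dst: int) -> List[Tuple[int, int]]:
    stack = [(src, -1, [])]
    while stack:
        node, parent, path = stack.pop()
        if node == dst:
            return path
        for nbr in top[node]:
            if nbr != parent:
                e = (node, nbr) if node < nbr else (nbr, node)
                stack.append((nbr, node, path + [e]))
    raise AssertionError("no path in tree")


def best_ls_topology(D: np.ndarray, n: int, labels: List[str]) -> Set[FrozenSet[str]]:
    """Bipartition set of the minimum-SSE topology under exhaustive search."""
    best_sse, best_top = None, None
    for top in enumerate_topologies(n):
        sse = ls_fit_sse(top, D, n)
        if best_sse is None or sse < best_sse:
            best_sse, best_top = sse, top
    assert best_top is not None
    return tree_bipartitions(best_top, n, labels)
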