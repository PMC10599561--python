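"""Minimal unrooted phylogenetics: neighbor-joining, splits, Robinson-Foulds.

The genus-assignment logic needs reliable clade placement on modest numbers
of taxa, not maximum-likelihood branch lengths, so the tree machinery is a
compact exact NJ with deterministic tie-breaking (first minimal Q entry in
row-major order) and split-based tree comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PhyloTree:
    """Unrooted tree: leaves are nodes 0..n-1 (in ``labels`` order), internal
    nodes follow; ``edges`` are (node, node, branch length >= 0)."""

    labels: list[str]
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for a, b, w in self.edges:
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))
        return adj

    def splits(self, include_trivial: bool = False) -> set[frozenset]:
        """Bipartitions induced by edges, each canonicalized as the side that
        does not contain the lexicographically smallest leaf label."""
        n = self.n_leaves
        ref = min(range(n), key=lambda i: self.labels[i])
        adj = self._adjacency()
        out: set[frozenset] = set()
        for a, b, _ in self.edges:
            side = self._leaves_behind(adj, b, a)
            if ref in side:
                side = set(range(n)) - side
            if include_trivial or 2 <= len(side) <= n - 2:
                out.add(frozenset(self.labels[i] for i in side))
        return out

    def _leaves_behind(self, adj, node: int, blocked: int) -> set[int]:
        seen = {blocked, node}
        stack = [node]
        leaves = set()
        while stack:
            u = stack.pop()
            if u < self.n_leaves:
                leaves.add(u)
            for v, _ in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return leaves

    def newick(self, support: dict[frozenset, float] | None = None) -> str:
        """Newick string rooted arbitrarily at the highest-numbered internal
        node; optional per-split support written as internal node labels."""
        adj = self._adjacency()
        root = max(adj)
        n = self.n_leaves

        def rec(node: int, parent: int) -> str:
            children = [(v, w) for v, w in adj[node] if v != parent]
            if node < n and not children:
                return self.labels[node]
            parts = [f"{rec(v, node)}:{w:.6f}" for v, w in children]
            label = ""
            if support is not None and parent >= 0:
                side = frozenset(self.labels[i] for i in self._leaves_behind(adj, node, parent))
                ref = min(self.labels)
                key = side if ref not in side else frozenset(self.labels) - side
                if key in support:
                    label = f"{support[key]:.2f}"
            return f"({','.join(parts)}){label}"

        return rec(root, -1) + ";"


def nj_tree(labels: list[str], distances: np.ndarray) -> PhyloTree:
    """Standard neighbor-joining; exact on additive distances."""
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")

    D = D.copy()
    ids = list(range(n))  # current node id per matrix row
    next_id = n
    edges: list[tuple[int, int, float]] = []
    while len(ids) > 2:
        m = len(ids)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum in row-major order: fixed tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        li = min(max(li, 0.0), dij)
        lj = max(dij - li, 0.0)
        edges.append((ids[i], next_id, li))
        edges.append((ids[j], next_id, lj))
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        du = np.maximum(du, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        D = newD
        ids = [ids[k] for k in keep] + [next_id]
        next_id += 1
    edges.append((ids[0], ids[1], max(float(D[0, 1]), 0.0)))
    return PhyloTree(labels=list(labels), edges=edges)


def rf_distance(tree1: PhyloTree, tree2: PhyloTree) -> int:
    """Robinson-Foulds: non-trivial splits present in exactly one tree."""
    if set(tree1.labels) != set(tree2.labels):
        raise ValueError("trees must share the same leaf set")
    return len(tree1.splits() ^ tree2.splits())


def max_rf(n_leaves: int) -> int:
    """Maximum RF between two fully resolved unrooted trees on n leaves."""
    return 2 * max(n_leaves - 3, 0)
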