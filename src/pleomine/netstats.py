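"""Gene-sharing network and the integrase association statistics.

Proteins are grouped into clusters as connected components of the
reciprocal-significant-hit graph (both directions at e <= 1e-3); genomes are
linked when they share at least ``min_shared`` protein clusters (default 2,
the relaxed threshold suited to small, divergent genomes). The report runs
the three analyses of interest: degree vs integrase, genome length vs
integrase (rank-sum tests), and degree vs length (Pearson and Spearman).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .engines import SmithWatermanEngine

DEFAULT_MAX_EVALUE = 1e-3
DEFAULT_MIN_SHARED = 2


@dataclass
class TestResult:
    statistic: float
    p_value: float | None
    method: str  # wilcoxon-exact | wilcoxon-normal | pearson | spearman
    n: tuple[int, ...]
    note: str = ""

    def __post_init__(self):
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be a valid probability")


# ---------------------------------------------------------- protein clusters


def _kmer_candidates(
    seqs: list[str], k: int = 4, min_shared: int = 3
) -> set[tuple[int, int]]:
    """Candidate homolog pairs: proteins sharing >= ``min_shared`` exact
    k-mers. Random 200-residue proteins share < 1 tetramer in expectation, so
    this prunes the quadratic alignment work without touching real homologs."""
    index: dict[str, list[int]] = {}
    kmer_sets = []
    for i, s in enumerate(seqs):
        ks = {s[j : j + k] for j in range(len(s) - k + 1)}
        kmer_sets.append(ks)
        for km in ks:
            index.setdefault(km, []).append(i)
    counts: dict[tuple[int, int], int] = {}
    for members in index.values():
        if len(members) < 2 or len(members) > 200:
            continue
        for a, b in itertools.combinations(members, 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return {pair for pair, c in counts.items() if c >= min_shared}


def protein_clusters(
    proteins: Sequence[tuple[str, str, str]],  # (genome_id, protein_id, sequence)
    engine: SmithWatermanEngine | None = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> dict[tuple[str, str], int]:
    """Connected components of the reciprocal-significant-hit graph.

    Cluster ids are deterministic: clusters are numbered by their smallest
    member label.
    """
    engine = engine or SmithWatermanEngine()
    labels = [(g, p) for g, p, _ in proteins]
    seqs = [s for _, _, s in proteins]
    total_residues = sum(len(s) for s in seqs)
    parent = list(range(len(labels)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for a, b in sorted(_kmer_candidates(seqs)):
        raw = engine._aligner.score(seqs[a], seqs[b])
        bits = engine.bitscore(raw)
        e_ab = len(seqs[a]) * total_residues * math.pow(2.0, -bits)
        e_ba = len(seqs[b]) * total_residues * math.pow(2.0, -bits)
        if e_ab <= max_evalue and e_ba <= max_evalue:  # reciprocal significance
            union(a, b)

    roots: dict[int, list[int]] = {}
    for i in range(len(labels)):
        roots.setdefault(find(i), []).append(i)
    ordered = sorted(roots.values(), key=lambda idx: min(labels[i] for i in idx))
    out: dict[tuple[str, str], int] = {}
    for cid, members in enumerate(ordered):
        for i in members:
            out[labels[i]] = cid
    return out


# ------------------------------------------------------------------- network


def shared_gene_network(
    cluster_assignment: Mapping[tuple[str, str], int],
    node_attrs: Mapping[str, dict] | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> nx.Graph:
    """Edge between genomes iff they share >= ``min_shared`` protein clusters."""
    clusters_by_genome: dict[str, set[int]] = {}
    for (genome, _), cid in cluster_assignment.items():
        clusters_by_genome.setdefault(genome, set()).add(cid)
    G = nx.Graph()
    for genome, cids in sorted(clusters_by_genome.items()):
        attrs = dict(node_attrs.get(genome, {})) if node_attrs else {}
        G.add_node(genome, n_clusters=len(cids), **attrs)
    for a, b in itertools.combinations(sorted(clusters_by_genome), 2):
        shared = len(clusters_by_genome[a] & clusters_by_genome[b])
        if shared >= min_shared:
            G.add_edge(a, b, shared_clusters=shared)
    return G


# ---------------------------------------------------------------- statistics


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided rank-sum test: exact by enumeration for n+m <= 12 without
    ties, otherwise normal approximation with midranks, tie correction and
    continuity correction."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    combined = x + y
    order = sorted(range(n + m), key=lambda i: combined[i])
    ranks = [0.0] * (n + m)
    i = 0
    while i < n + m:
        j = i
        while j + 1 < n + m and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    W = sum(ranks[:n])
    has_ties = len(set(combined)) < n + m

    if n + m <= 12 and not has_ties:
        sums = [sum(c) for c in itertools.combinations(range(1, n + m + 1), n)]
        total = len(sums)
        lo = sum(1 for s in sums if s <= W) / total
        hi = sum(1 for s in sums if s >= W) / total
        p = min(1.0, 2.0 * min(lo, hi))
        return TestResult(W, p, "wilcoxon-exact", (n, m))

    N = n + m
    mean = n * (N + 1) / 2.0
    tie_term = 0.0
    for v in set(combined):
        t = combined.count(v)
        tie_term += t**3 - t
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return TestResult(W, 1.0, "wilcoxon-normal", (n, m), note="zero variance (all ties)")
    diff = W - mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(W, p, "wilcoxon-normal", (n, m))


def correlations(x: Sequence[float], y: Sequence[float]) -> tuple[TestResult, TestResult]:
    """Pearson and Spearman (midrank ties) correlation coefficients."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    n = (len(x),)
    if np.std(x) == 0 or np.std(y) == 0:
        und = "undefined: zero variance"
        return (
            TestResult(float("nan"), None, "pearson", n, note=und),
            TestResult(float("nan"), None, "spearman", n, note=und),
        )
    pr = stats.pearsonr(x, y)
    sp = stats.spearmanr(x, y)
    return (
        TestResult(float(pr.statistic), float(pr.pvalue), "pearson", n),
        TestResult(float(sp.statistic), float(sp.pvalue), "spearman", n),
    )


def integrase_association_report(network: nx.Graph) -> pd.DataFrame:
    """Degree~integrase and length~integrase rank-sum tests plus the
    degree~length correlations, one row per analysis. Nodes must carry
    ``integrase`` (bool) and ``length`` (bp) attributes."""
    nodes = sorted(network.nodes)
    for v in nodes:
        if "integrase" not in network.nodes[v] or "length" not in network.nodes[v]:
            raise ValueError(f"node {v!r} lacks integrase/length attributes")
    degree = {v: network.degree(v) for v in nodes}
    with_int = [v for v in nodes if network.nodes[v]["integrase"]]
    without = [v for v in nodes if not network.nodes[v]["integrase"]]
    rows = []

    def add(analysis: str, result: TestResult | None, reason: str = "") -> None:
        if result is None:
            rows.append(
                {"analysis": analysis, "statistic": float("nan"), "p_value": float("nan"),
                 "method": "skipped", "n": 0, "note": reason}
            )
        else:
            rows.append(
                {"analysis": analysis, "statistic": result.statistic,
                 "p_value": float("nan") if result.p_value is None else result.p_value,
                 "method": result.method, "n": sum(result.n), "note": result.note}
            )

    if with_int and without:
        add("degree~integrase", wilcoxon_rank_sum([degree[v] for v in with_int], [degree[v] for v in without]))
        add(
            "length~integrase",
            wilcoxon_rank_sum(
                [network.nodes[v]["length"] for v in with_int],
                [network.nodes[v]["length"] for v in without],
            ),
        )
    else:
        reason = "a group is empty: all or no genomes carry an integrase"
        add("degree~integrase", None, reason)
        add("length~integrase", None, reason)
    if len(nodes) >= 3:
        pear, spear = correlations([degree[v] for v in nodes], [network.nodes[v]["length"] for v in nodes])
        add("degree~length", pear)
        add("degree~length", spear)
    else:
        add("degree~length", None, "fewer than 3 nodes")
    return pd.DataFrame(rows)
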