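"""Protein-family simulation: i.i.d. per-site divergence and tree-structured evolution."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import mutate_protein, random_protein, substream


@dataclass
class ProteinFamily:
    """A simulated conserved protein family.

    ``members`` are (label, sequence) pairs; every member derives from
    ``consensus`` by per-site substitution, so for divergence ``d`` the mean
    pairwise identity is close to ``(1 - d)^2`` (two independent survival
    events per site, plus a small 1/19 coincidence term).
    """

    name: str
    consensus: str
    members: list[tuple[str, str]] = field(default_factory=list)

    def sequences(self) -> list[str]:
        return [s for _, s in self.members]

    def to_fasta(self) -> str:
        return "".join(f">{label}\n{seq}\n" for label, seq in self.members)


def generate_marker_family(
    consensus_length: int,
    n_members: int,
    divergence: float,
    seed: int,
    name: str = "family",
    consensus: str | None = None,
) -> ProteinFamily:
    """Draw a random consensus and ``n_members`` i.i.d. per-site mutants of it."""
    if consensus_length < 30:
        raise ValueError("consensus_length must be >= 30")
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = substream(seed, "marker-family", name)
    if consensus is None:
        consensus = random_protein(consensus_length, rng)
    members = [
        (f"{name}_m{i:03d}", mutate_protein(consensus, divergence, rng))
        for i in range(n_members)
    ]
    return ProteinFamily(name=name, consensus=consensus, members=members)


def random_topology(n: int, rng: np.random.Generator):
    """Random binary tree over leaves 0..n-1 (nested int/tuple structure)."""
    if n < 1:
        raise ValueError("need at least one leaf")
    nodes: list = list(range(n))
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(0, len(nodes))))
        b = nodes.pop(int(rng.integers(0, len(nodes))))
        nodes.append((a, b))
    return nodes[0]


def evolve_along(
    consensus: str, topology, n_leaves: int, branch_rate: float, rng: np.random.Generator
) -> list[str]:
    """Evolve a sequence down a fixed topology, mutating once per branch.

    Used for the ORF7/ORF8 markers so that both genes share one within-genus
    genealogy: their estimated trees are then congruent, while markers evolved
    on different guide structures (the host-keyed spike gene) are not.
    """
    out: dict[int, str] = {}

    def rec(node, seq: str) -> None:
        seq = mutate_protein(seq, branch_rate, rng)
        if isinstance(node, tuple):
            rec(node[0], seq)
            rec(node[1], seq)
        else:
            out[node] = seq

    rec(topology, consensus)
    return [out[i] for i in range(n_leaves)]
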