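"""Synthetic pleolipovirus-like genome construction.

Each genome carries the four-gene core cassette (spike / VP3-like / unknown /
ATPase, i.e. ORF4-, ORF6-, ORF7-, ORF8-like) in canonical order on the forward
strand, genus-specific hallmark replication genes downstream of the cassette,
a handful of accessory genes, and — with probability ``p_integrase`` — an
integrase plus cargo genes that inflate the genome by ``integrase_cargo_kb``.

Marker evolution is hierarchical: a family-wide root consensus per marker,
genus-keyed sub-consensuses for ORF7/ORF8 (evolved along one shared
within-genus genealogy so the two genes tell the same story), and host-keyed
sub-consensuses for the spike gene (so its tree follows the host, not the
taxonomy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import (
    mutate_protein,
    random_dna,
    random_protein,
    reverse_translate,
    substream,
)
from .config import (
    CORE_MARKERS,
    GENERA,
    HALLMARK_FAMILIES,
    HALLMARKS_BY_GENUS,
    SimulationConfig,
)
from .families import ProteinFamily, evolve_along, random_topology


@dataclass
class GeneSim:
    gene_id: str
    family: str  # e.g. "ORF4", "RCRE", "acc03", "cargo01", "decoy02"
    start: int  # 0-based half-open nucleotide coordinates on the genome
    end: int
    strand: str
    protein: str


@dataclass
class GenomeSim:
    genome_id: str
    genus: str
    host: str
    seq: str
    genes: list[GeneSim] = field(default_factory=list)
    integrase: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def hallmarks(self) -> frozenset[str]:
        present = {g.family for g in self.genes}
        return frozenset(present & set(HALLMARK_FAMILIES))

    def gene(self, family: str) -> GeneSim | None:
        for g in self.genes:
            if g.family == family:
                return g
        return None

    def core_gene_span(self) -> tuple[int, int]:
        starts = [g.start for g in self.genes if g.family in CORE_MARKERS]
        ends = [g.end for g in self.genes if g.family in CORE_MARKERS]
        return min(starts), max(ends)


class SimContext:
    """Shared consensus hierarchy for one (config, seed) simulation."""

    def __init__(self, config: SimulationConfig, seed: int):
        config.validate()
        self.config = config
        self.seed = seed
        c = config
        self.roots: dict[str, str] = {}
        for marker, length in c.core_gene_lengths.items():
            self.roots[marker] = random_protein(length, substream(seed, "root", marker))
        for marker, length in c.hallmark_gene_lengths.items():
            self.roots[marker] = random_protein(length, substream(seed, "root", marker))
        self.accessory_roots = [
            random_protein(150, substream(seed, "root", "acc", i))
            for i in range(c.n_accessory_families)
        ]
        self.cargo_roots = [
            random_protein(c.cargo_gene_length, substream(seed, "root", "cargo", i))
            for i in range(c.n_cargo_families)
        ]
        self._genus_consensus: dict[tuple[str, str], str] = {}
        self._host_consensus: dict[str, str] = {}

    # -- consensus hierarchy -------------------------------------------------

    def genus_consensus(self, marker: str, genus: str) -> str:
        """Genus-keyed sub-consensus (ORF7/ORF8 and the hallmark genes)."""
        key = (marker, genus)
        if key not in self._genus_consensus:
            rng = substream(self.seed, "genus-consensus", marker, genus)
            self._genus_consensus[key] = mutate_protein(
                self.roots[marker], self.config.genus_divergence, rng
            )
        return self._genus_consensus[key]

    def host_consensus(self, host: str) -> str:
        """Host-keyed spike (ORF4) consensus: spike evolution follows the host."""
        if host not in self._host_consensus:
            rng = substream(self.seed, "host-consensus", "ORF4", host)
            self._host_consensus[host] = mutate_protein(
                self.roots["ORF4"], self.config.host_divergence, rng
            )
        return self._host_consensus[host]

    # -- per-genus marker evolution ------------------------------------------

    def evolve_genus_markers(self, genus: str, n: int) -> dict[str, list[str]]:
        """ORF7/ORF8 member sequences for one genus, evolved along a shared
        genealogy (branch rate = divergence / 6 so root-to-leaf divergence is
        comparable to the i.i.d. member divergence)."""
        topo = random_topology(n, substream(self.seed, "genealogy", genus))
        rate = self.config.divergence / 6.0
        out = {}
        for marker in ("ORF7", "ORF8"):
            rng = substream(self.seed, "evolve", marker, genus)
            out[marker] = evolve_along(self.genus_consensus(marker, genus), topo, n, rate, rng)
        return out

    # -- genome assembly -----------------------------------------------------

    def build_genome(
        self,
        genome_id: str,
        genus: str,
        host: str,
        orf7: str,
        orf8: str,
        rng: np.random.Generator,
        force_integrase: bool | None = None,
    ) -> GenomeSim:
        c = self.config
        member_div = c.divergence * 0.5
        proteins: list[tuple[str, str]] = [
            ("ORF4", mutate_protein(self.host_consensus(host), member_div, rng)),
            ("ORF6", mutate_protein(self.roots["ORF6"], c.divergence, rng)),
            ("ORF7", orf7),
            ("ORF8", orf8),
        ]
        for hallmark in HALLMARKS_BY_GENUS[genus]:
            proteins.append(
                (hallmark, mutate_protein(self.genus_consensus(hallmark, genus), member_div, rng))
            )
        n_acc = int(rng.integers(c.accessory_per_genome[0], c.accessory_per_genome[1] + 1))
        acc_ids = rng.choice(len(self.accessory_roots), size=min(n_acc, len(self.accessory_roots)), replace=False)
        for i in sorted(int(x) for x in acc_ids):
            proteins.append((f"acc{i:02d}", mutate_protein(self.accessory_roots[i], 0.2, rng)))

        if force_integrase is None:
            has_integrase = bool(rng.random() < c.p_integrase)
        else:
            has_integrase = force_integrase
        if has_integrase:
            # cargo genes sized so the added material totals ~integrase_cargo_kb
            per_gene_bp = 3 * (c.cargo_gene_length + 1) + int(np.mean(c.intergenic_gap_range))
            n_cargo = max(0, round((c.integrase_cargo_kb * 1000 - 3 * 301) / per_gene_bp))
            cargo_ids = rng.choice(len(self.cargo_roots), size=min(n_cargo, len(self.cargo_roots)), replace=False)
            for i in sorted(int(x) for x in cargo_ids):
                proteins.append((f"cargo{i:02d}", mutate_protein(self.cargo_roots[i], 0.2, rng)))
            proteins.append(
                ("integrase", mutate_protein(self.genus_consensus("integrase", genus), member_div, rng))
            )

        parts: list[str] = [random_dna(int(rng.integers(*_inc(c.margin_range))), rng)]
        pos = len(parts[0])
        genes: list[GeneSim] = []
        for k, (family, prot) in enumerate(proteins):
            if k > 0:
                gap = random_dna(int(rng.integers(*_inc(c.intergenic_gap_range))), rng)
                parts.append(gap)
                pos += len(gap)
            cds = reverse_translate(prot, rng)
            genes.append(GeneSim(f"{genome_id}_g{k:02d}", family, pos, pos + len(cds), "+", prot))
            parts.append(cds)
            pos += len(cds)
        tail = random_dna(int(rng.integers(*_inc(c.margin_range))), rng)
        parts.append(tail)
        return GenomeSim(genome_id, genus, host, "".join(parts), genes, has_integrase)


def _inc(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def generate_virus_genome(
    genus: str,
    config: SimulationConfig,
    seed: int,
    genome_id: str | None = None,
    host: str | None = None,
) -> GenomeSim:
    """Generate a single genome of the given genus (standalone entry point).

    Within a full simulation genomes are built through :class:`SimContext`
    so they share one consensus hierarchy; this wrapper creates that context
    from (config, seed) for one genome.
    """
    if genus not in GENERA:
        raise ValueError(f"unknown genus {genus!r}; expected one of {GENERA}")
    ctx = SimContext(config, seed)
    host = host or "host_00"
    genome_id = genome_id or f"pv_{genus}_000"
    markers = ctx.evolve_genus_markers(genus, 1)
    rng = substream(seed, "genome", genome_id)
    return ctx.build_genome(genome_id, genus, host, markers["ORF7"][0], markers["ORF8"][0], rng)


def generate_genome_set(config: SimulationConfig, seed: int) -> tuple[list[GenomeSim], SimContext]:
    """Generate all genomes for a simulation, with host assignments."""
    ctx = SimContext(config, seed)
    hosts = [f"host_{i:02d}" for i in range(config.n_hosts)]
    genomes: list[GenomeSim] = []
    for genus in GENERA:
        n = config.n_genomes_per_genus.get(genus, 0)
        if n == 0:
            continue
        markers = ctx.evolve_genus_markers(genus, n)
        assign_rng = substream(seed, "host-assign", genus)
        for i in range(n):
            gid = f"pv_{genus}_{i:03d}"
            host = hosts[int(assign_rng.integers(0, len(hosts)))] if hosts else "host_00"
            rng = substream(seed, "genome", gid)
            genomes.append(
                ctx.build_genome(gid, genus, host, markers["ORF7"][i], markers["ORF8"][i], rng)
            )
    return genomes, ctx
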