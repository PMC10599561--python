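"""Contig emission: terminal repeats, proviruses, fragments, and decoy hosts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import random_dna, reverse_complement, reverse_translate, substream
from .config import CORE_MARKERS, SimulationConfig
from .families import ProteinFamily
from .genomes import GeneSim, GenomeSim
from .truth import ContigTruth, TruthTable


@dataclass
class ContigSim:
    contig_id: str
    seq: str
    kind: str  # "viral" or "decoy"
    source_genome: str | None = None
    completeness_class: str | None = None  # truth class for viral contigs
    genes: list[GeneSim] = field(default_factory=list)  # decoy/host genes only

    @property
    def length(self) -> int:
        return len(self.seq)


def make_decoy_contigs(
    decoy_families: list[ProteinFamily],
    config: SimulationConfig,
    seed: int,
    n_contigs: int | None = None,
    min_genes: int = 4,
    max_genes: int = 6,
    prefix: str = "decoy",
) -> list[ContigSim]:
    """Host-background contigs carrying decoy-family genes but no viral cassette."""
    if not decoy_families:
        raise ValueError("need at least one decoy family")
    n_contigs = config.n_decoy_contigs if n_contigs is None else n_contigs
    rng = substream(seed, "decoy-contigs", prefix)
    members = [(fam.name, seq) for fam in decoy_families for _, seq in fam.members]
    contigs = []
    for i in range(n_contigs):
        n_genes = int(rng.integers(min_genes, max_genes + 1))
        parts = [random_dna(int(rng.integers(150, 401)), rng)]
        pos = len(parts[0])
        genes: list[GeneSim] = []
        for k in range(n_genes):
            if k > 0:
                gap = random_dna(int(rng.integers(50, 401)), rng)
                parts.append(gap)
                pos += len(gap)
            fam, prot = members[int(rng.integers(0, len(members)))]
            cds = reverse_translate(prot, rng)
            genes.append(GeneSim(f"{prefix}_{i:03d}_g{k}", fam, pos, pos + len(cds), "+", prot))
            parts.append(cds)
            pos += len(cds)
        parts.append(random_dna(int(rng.integers(150, 401)), rng))
        contigs.append(ContigSim(f"{prefix}_{i:03d}", "".join(parts), "decoy", genes=genes))
    return contigs


def fragment_and_embed(
    genomes: list[GenomeSim],
    host_background: list[ContigSim],
    config: SimulationConfig,
    seed: int,
) -> tuple[list[ContigSim], TruthTable]:
    """Emit one contig per genome (DTR / ITR / provirus / fragment) plus the
    host-background decoys, with a ground-truth table for every contig."""
    if not genomes:
        raise ValueError("genome list must not be empty")
    rng = substream(seed, "fragment-and-embed")
    probs = config.class_probabilities()
    classes = list(probs)
    p = np.array([probs[c] for c in classes])
    truth = TruthTable()
    contigs: list[ContigSim] = []

    for gi, genome in enumerate(genomes):
        cls = classes[int(rng.choice(len(classes), p=p))]
        if cls == "complete-provirus" and not genome.integrase:
            # integrated proviruses carry an integrase; redraw for genomes
            # without one (unless the configuration demands proviruses only)
            alt = [c for c in classes if c != "complete-provirus"]
            q = np.array([probs[c] for c in alt])
            if q.sum() > 0:
                cls = alt[int(rng.choice(len(alt), p=q / q.sum()))]
        cid = f"contig_{gi:04d}"
        span = genome.core_gene_span()
        if cls == "complete-DTR":
            r = int(rng.integers(config.dtr_len_range[0], config.dtr_len_range[1] + 1))
            seq = genome.seq + genome.seq[:r]
            cass, complete = span, True
        elif cls == "complete-ITR":
            r = int(rng.integers(config.dtr_len_range[0], config.dtr_len_range[1] + 1))
            seq = genome.seq + reverse_complement(genome.seq[:r])
            cass, complete = span, True
        elif cls == "complete-provirus":
            host_contig = host_background[int(rng.integers(0, len(host_background)))]
            seq, offset = _embed(genome, host_contig, rng)
            cass, complete = (span[0] + offset, span[1] + offset), True
        else:  # fragment
            seq, cass, complete = _truncate(genome, rng)
        contigs.append(ContigSim(cid, seq, "viral", genome.genome_id, cls))
        truth.contigs[cid] = ContigTruth(
            contig_id=cid,
            source_genome=genome.genome_id,
            genus=genome.genus,
            cassette_start=None if cass is None else cass[0],
            cassette_end=None if cass is None else cass[1],
            strand=None if cass is None else "+",
            cassette_complete=complete,
            completeness_class=cls,
            host=genome.host,
        )

    for bg in host_background:
        contigs.append(bg)
        truth.contigs[bg.contig_id] = ContigTruth(
            contig_id=bg.contig_id,
            source_genome=None,
            genus=None,
            cassette_start=None,
            cassette_end=None,
            strand=None,
            cassette_complete=False,
            completeness_class="decoy",
            host=None,
        )

    for genome in genomes:
        from .truth import GenomeTruth

        truth.genomes[genome.genome_id] = GenomeTruth(
            genome_id=genome.genome_id,
            genus=genome.genus,
            host=genome.host,
            integrase=genome.integrase,
            length=genome.length,
            hallmarks=genome.hallmarks,
        )
    truth.check({c.contig_id: c.length for c in contigs})
    return contigs, truth


def _embed(genome: GenomeSim, host_contig: ContigSim, rng: np.random.Generator) -> tuple[str, int]:
    """Insert the genome into a copy of a host contig, keeping >= 2 host genes
    on each flank (the complete-provirus truth class requires both flanks)."""
    genes = sorted(host_contig.genes, key=lambda g: g.start)
    if len(genes) < 4:
        raise ValueError("host contig needs >= 4 genes to host a provirus")
    # insertion point: midway between the 2nd and 3rd-from-last gene boundaries
    left_end = genes[1].end
    right_start = genes[-2].start
    lo, hi = left_end + 10, max(left_end + 11, right_start - 10)
    point = int(rng.integers(lo, hi))
    seq = host_contig.seq[:point] + genome.seq + host_contig.seq[point:]
    return seq, point


def _truncate(
    genome: GenomeSim, rng: np.random.Generator
) -> tuple[str, tuple[int, int] | None, bool]:
    """5' or 3' fragment keeping 35-85% of the genome; core genes overlapping
    the cut are lost, so fragments lose >= 1 core gene with positive probability."""
    keep = 0.35 + 0.5 * rng.random()
    n_keep = max(1, int(genome.length * keep))
    if rng.random() < 0.5:  # keep 5' end
        seq = genome.seq[:n_keep]
        surviving = [g for g in genome.genes if g.family in CORE_MARKERS and g.end <= n_keep]
        shift = 0
    else:  # keep 3' end
        cut = genome.length - n_keep
        seq = genome.seq[cut:]
        surviving = [g for g in genome.genes if g.family in CORE_MARKERS and g.start >= cut]
        shift = -cut
    if not surviving:
        return seq, None, False
    cass = (min(g.start for g in surviving) + shift, max(g.end for g in surviving) + shift)
    return seq, cass, len(surviving) == len(CORE_MARKERS)
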