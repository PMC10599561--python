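"""End-to-end synthetic halovirome: genomes, contigs, decoys, CRISPR, truth.

A :class:`Halovirome` bundles everything the mining pipeline consumes —
contigs, a protein database, seed marker sets, calibration sets, host CRISPR
arrays, fabricated host scores — together with the ground truth every stage
is scored against. Identical (config, seed) produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .._seq import mutate_protein, substream
from .config import (
    CORE_MARKERS,
    GENERA,
    HALLMARK_FAMILIES,
    SimulationConfig,
)
from .contigs import ContigSim, fragment_and_embed, make_decoy_contigs
from .crispr import SpacerSets, generate_crispr_arrays, host_score_table
from .families import ProteinFamily, generate_marker_family
from .genomes import GenomeSim, generate_genome_set
from .truth import TruthTable

PROFILED_FAMILIES = CORE_MARKERS + HALLMARK_FAMILIES


@dataclass
class Halovirome:
    config: SimulationConfig
    seed: int
    genomes: list[GenomeSim]
    contigs: list[ContigSim]
    truth: TruthTable
    families: dict[str, ProteinFamily]
    decoy_families: list[ProteinFamily]
    spacer_sets: SpacerSets
    host_scores: pd.DataFrame
    hosts: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------ build

    @classmethod
    def generate(cls, config: SimulationConfig, seed: int | None = None) -> "Halovirome":
        config.validate()
        seed = config.seed if seed is None else seed
        genomes, ctx = generate_genome_set(config, seed)
        if not genomes:
            raise ValueError("configuration yields zero genomes")

        families = {
            name: ProteinFamily(name=name, consensus=ctx.roots[name]) for name in PROFILED_FAMILIES
        }
        for g in genomes:
            for gene in g.genes:
                if gene.family in families:
                    families[gene.family].members.append((f"{g.genome_id}|{gene.gene_id}", gene.protein))

        decoy_families = [
            generate_marker_family(
                config.decoy_gene_length,
                config.decoy_family_members,
                0.2,
                seed,
                name=f"decoy{i:02d}",
            )
            for i in range(config.n_decoy_families)
        ]
        background = make_decoy_contigs(decoy_families, config, seed)
        contigs, truth = fragment_and_embed(genomes, background, config, seed)

        hosts = sorted({g.host for g in genomes})
        spacer_sets = generate_crispr_arrays(hosts, genomes, config, seed)
        scores = host_score_table(genomes, hosts, seed)
        return cls(
            config=config,
            seed=seed,
            genomes=genomes,
            contigs=contigs,
            truth=truth,
            families=families,
            decoy_families=decoy_families,
            spacer_sets=spacer_sets,
            host_scores=scores,
            hosts=hosts,
        )

    # ---------------------------------------------------------------- lookups

    def genome(self, genome_id: str) -> GenomeSim:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def seed_proteins(self, family: str, n_mutants: int = 3) -> list[tuple[str, str]]:
        """Seed set for marker-database building: the family consensus plus a
        few lightly diverged variants (the simulated analogue of the isolate
        proteins the search starts from)."""
        fam = self.families[family]
        rng = substream(self.seed, "seed-proteins", family)
        seeds = [(f"{family}_seed0", fam.consensus)]
        for i in range(n_mutants):
            seeds.append((f"{family}_seed{i + 1}", mutate_protein(fam.consensus, 0.1, rng)))
        return seeds

    def protein_db(self) -> list[tuple[str, str]]:
        """All genome proteins plus all decoy-family members (search database)."""
        db = []
        for g in self.genomes:
            for gene in g.genes:
                db.append((f"{g.genome_id}|{gene.gene_id}|{gene.family}", gene.protein))
        for fam in self.decoy_families:
            for label, seq in fam.members:
                db.append((f"decoydb|{label}|{fam.name}", seq))
        return db

    def calibration_tp(self, family: str) -> list[tuple[str, str]]:
        return list(self.families[family].members)

    def calibration_tn(self) -> list[tuple[str, str]]:
        return [(label, seq) for fam in self.decoy_families for label, seq in fam.members]

    # ---------------------------------------------------------------- outputs

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "contigs.fna", [(c.contig_id, c.seq) for c in self.contigs])
        _write_fasta(outdir / "proteins.faa", self.protein_db())
        self._write_gff3(outdir / "genes.gff3")
        self.truth.contig_frame().to_csv(outdir / "truth_contigs.tsv", sep="\t", index=False)
        self.truth.genome_frame().to_csv(outdir / "truth_genomes.tsv", sep="\t", index=False)
        self.host_scores.to_csv(outdir / "host_scores.tsv", sep="\t", index=False)
        spacer_dir = outdir / "spacers"
        spacer_dir.mkdir(exist_ok=True)
        for host, spacers in self.spacer_sets.spacers.items():
            _write_fasta(spacer_dir / f"{host}.fna", spacers)
        self.config.to_yaml(outdir / "config.yaml")

    def _write_gff3(self, path: Path) -> None:
        lines = ["##gff-version 3"]
        for g in self.genomes:
            for gene in g.genes:
                # GFF3 is 1-based inclusive; internal coordinates are 0-based half-open
                lines.append(
                    "\t".join(
                        [
                            g.genome_id,
                            "pleomine-sim",
                            "CDS",
                            str(gene.start + 1),
                            str(gene.end),
                            ".",
                            gene.strand,
                            "0",
                            f"ID={gene.gene_id};family={gene.family}",
                        ]
                    )
                )
        Path(path).write_text("\n".join(lines) + "\n")


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
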