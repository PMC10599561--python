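"""Ground-truth bookkeeping for simulated contigs and genomes."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

COMPLETENESS_CLASSES = ("complete-DTR", "complete-ITR", "complete-provirus", "fragment")


@dataclass
class ContigTruth:
    contig_id: str
    source_genome: str | None  # None for decoy host contigs
    genus: str | None
    cassette_start: int | None  # 0-based half-open on the contig, + strand
    cassette_end: int | None
    strand: str | None
    cassette_complete: bool
    completeness_class: str  # one of COMPLETENESS_CLASSES or "decoy"
    host: str | None


@dataclass
class GenomeTruth:
    genome_id: str
    genus: str
    host: str
    integrase: bool
    length: int
    hallmarks: frozenset[str]


@dataclass
class TruthTable:
    contigs: dict[str, ContigTruth] = field(default_factory=dict)
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)

    @property
    def n_planted_cassettes(self) -> int:
        return sum(1 for c in self.contigs.values() if c.source_genome is not None)

    def viral_contigs(self) -> list[ContigTruth]:
        return [c for c in self.contigs.values() if c.source_genome is not None]

    def decoy_contigs(self) -> list[ContigTruth]:
        return [c for c in self.contigs.values() if c.source_genome is None]

    def contig_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig_id": c.contig_id,
                "source_genome": c.source_genome or "",
                "genus": c.genus or "",
                "cassette_start": -1 if c.cassette_start is None else c.cassette_start,
                "cassette_end": -1 if c.cassette_end is None else c.cassette_end,
                "strand": c.strand or "",
                "cassette_complete": c.cassette_complete,
                "completeness_class": c.completeness_class,
                "host": c.host or "",
            }
            for c in self.contigs.values()
        ]
        return pd.DataFrame(rows)

    def genome_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genome_id": g.genome_id,
                "genus": g.genus,
                "host": g.host,
                "integrase": g.integrase,
                "length": g.length,
                "hallmarks": ",".join(sorted(g.hallmarks)),
            }
            for g in self.genomes.values()
        ]
        return pd.DataFrame(rows)

    def check(self, contig_lengths: dict[str, int]) -> None:
        """Internal consistency: planted coordinates lie within their contig."""
        for c in self.contigs.values():
            if c.cassette_start is None:
                continue
            if not 0 <= c.cassette_start < c.cassette_end <= contig_lengths[c.contig_id]:
                raise AssertionError(f"cassette coordinates out of range on {c.contig_id}")
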