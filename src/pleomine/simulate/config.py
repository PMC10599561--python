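"""Simulation configuration for the synthetic halovirome."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

GENERA = ("alpha", "beta", "gamma", "delta", "epsilon")

CORE_MARKERS = ("ORF4", "ORF6", "ORF7", "ORF8")

#: genus-diagnostic replication modules (the "hallmark" genes); epsilon has none
HALLMARKS_BY_GENUS: dict[str, tuple[str, ...]] = {
    "alpha": ("RCRE",),
    "beta": ("Rep",),
    "gamma": ("polB",),
    "delta": ("Rep",),  # delta carries a divergent Rep variant; split from beta by phylogeny
    "epsilon": (),
}

HALLMARK_FAMILIES = ("RCRE", "Rep", "polB", "integrase")


def _default_genus_counts() -> dict[str, int]:
    return {"alpha": 25, "beta": 25, "gamma": 10, "delta": 20, "epsilon": 20}


def _default_core_lengths() -> dict[str, int]:
    # amino acids: spike (ORF4), VP3-like membrane protein (ORF6),
    # unknown-function protein (ORF7), ATPase (ORF8)
    return {"ORF4": 280, "ORF6": 140, "ORF7": 120, "ORF8": 230}


def _default_hallmark_lengths() -> dict[str, int]:
    return {"RCRE": 300, "Rep": 250, "polB": 350, "integrase": 300}


@dataclass
class SimulationConfig:
    """Ground-truth generator settings.

    The defaults describe a 100-genome, five-genus halovirome with the
    statistical structure the mining procedure assumes: a conserved four-gene
    cassette in canonical order, genus-specific replication hallmarks,
    integrase-linked genome-size inflation, a mixture of terminal-repeat,
    provirus and fragment contig classes, decoy host material, and host
    CRISPR arrays sampling spacers from their own viruses.
    """

    seed: int = 0
    n_genomes_per_genus: dict[str, int] = field(default_factory=_default_genus_counts)
    core_gene_lengths: dict[str, int] = field(default_factory=_default_core_lengths)
    hallmark_gene_lengths: dict[str, int] = field(default_factory=_default_hallmark_lengths)
    divergence: float = 0.3
    genus_divergence: float = 0.35
    host_divergence: float = 0.4
    intergenic_gap_range: tuple[int, int] = (20, 400)
    margin_range: tuple[int, int] = (150, 400)
    p_integrase: float = 0.3
    integrase_cargo_kb: float = 4.0
    # contig emission classes; normalized to a categorical distribution
    p_dtr: float = 0.45
    p_itr: float = 0.15
    p_provirus: float = 0.2
    p_fragment: float = 0.2
    dtr_len_range: tuple[int, int] = (20, 100)
    n_hosts: int = 8
    spacers_per_host: int = 12
    spacer_len: int = 35
    broad_range_k: int = 3
    n_decoy_families: int = 6
    decoy_family_members: int = 8
    decoy_gene_length: int = 200
    n_decoy_contigs: int = 25
    n_accessory_families: int = 20
    accessory_per_genome: tuple[int, int] = (2, 5)
    n_cargo_families: int = 8
    cargo_gene_length: int = 180

    def validate(self) -> None:
        probs = {
            "divergence": self.divergence,
            "genus_divergence": self.genus_divergence,
            "host_divergence": self.host_divergence,
            "p_integrase": self.p_integrase,
            "p_dtr": self.p_dtr,
            "p_itr": self.p_itr,
            "p_provirus": self.p_provirus,
            "p_fragment": self.p_fragment,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.divergence >= 1.0:
            raise ValueError("divergence must be < 1")
        counts = {
            "n_hosts": self.n_hosts,
            "spacers_per_host": self.spacers_per_host,
            "spacer_len": self.spacer_len,
            "n_decoy_families": self.n_decoy_families,
            "n_decoy_contigs": self.n_decoy_contigs,
            **{f"n_genomes[{g}]": c for g, c in self.n_genomes_per_genus.items()},
        }
        for name, c in counts.items():
            if c < 0:
                raise ValueError(f"{name} must be >= 0, got {c}")
        for name, rng_ in (
            ("intergenic_gap_range", self.intergenic_gap_range),
            ("margin_range", self.margin_range),
            ("dtr_len_range", self.dtr_len_range),
            ("accessory_per_genome", self.accessory_per_genome),
        ):
            lo, hi = rng_
            if lo < 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 <= min <= max, got {rng_}")
        for g in self.n_genomes_per_genus:
            if g not in GENERA:
                raise ValueError(f"unknown genus {g!r}")
        for m, length in self.core_gene_lengths.items():
            if length < 30:
                raise ValueError(f"core gene {m} length must be >= 30 aa")
        if self.p_dtr + self.p_itr + self.p_provirus + self.p_fragment <= 0:
            raise ValueError("contig class probabilities must not all be zero")

    def class_probabilities(self) -> dict[str, float]:
        raw = {
            "complete-DTR": self.p_dtr,
            "complete-ITR": self.p_itr,
            "complete-provirus": self.p_provirus,
            "fragment": self.p_fragment,
        }
        total = sum(raw.values())
        return {k: v / total for k, v in raw.items()}

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("intergenic_gap_range", "margin_range", "dtr_len_range", "accessory_per_genome"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("intergenic_gap_range", "margin_range", "dtr_len_range", "accessory_per_genome"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg
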