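"""Host CRISPR arrays and fabricated integrated host-score tables.

The generator plants an extremely narrow host range: every virus is spacer-
targeted by exactly one host, except one designated broad-range virus that is
targeted by ``broad_range_k`` hosts (the simulated analogue of a virus able to
cross host-family boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .._seq import reverse_complement, substream
from .config import SimulationConfig
from .genomes import GenomeSim


@dataclass
class SpacerSets:
    spacers: dict[str, list[tuple[str, str]]]  # host -> [(spacer_id, seq)]
    pairs: set[tuple[str, str]] = field(default_factory=set)  # (genome_id, host)
    broad_range_virus: str | None = None

    def all_spacers(self) -> list[tuple[str, str, str]]:
        return [(h, sid, seq) for h, lst in self.spacers.items() for sid, seq in lst]


def generate_crispr_arrays(
    hosts: list[str],
    genomes: list[GenomeSim],
    config: SimulationConfig,
    seed: int,
    broad_range_virus: str | None = None,
) -> SpacerSets:
    """Sample ``spacer_len`` substrings (either strand) of each host's viruses."""
    if len(hosts) < 1:
        raise ValueError("need at least one host")
    if not genomes:
        raise ValueError("genome list must not be empty")
    L = config.spacer_len
    short = min(g.length for g in genomes)
    if L > short:
        raise ValueError(f"spacer_len {L} exceeds shortest genome length {short}")
    rng = substream(seed, "crispr")
    by_id = {g.genome_id: g for g in genomes}
    assigned: dict[str, str] = {}
    for i, g in enumerate(genomes):
        assigned[g.genome_id] = g.host if g.host in hosts else hosts[i % len(hosts)]
    if broad_range_virus is None:
        broad_range_virus = genomes[0].genome_id
    k = min(max(config.broad_range_k, 1), len(hosts))

    spacers: dict[str, list[tuple[str, str]]] = {h: [] for h in hosts}
    pairs: set[tuple[str, str]] = set()

    def cut(genome: GenomeSim) -> str:
        pos = int(rng.integers(0, genome.length - L + 1))
        sub = genome.seq[pos : pos + L]
        return reverse_complement(sub) if rng.random() < 0.5 else sub

    for h in hosts:
        targets = [g for g in genomes if assigned[g.genome_id] == h]
        if not targets:
            continue
        queue = list(targets)
        while len(spacers[h]) < max(config.spacers_per_host, len(targets)):
            g = queue[len(spacers[h]) % len(targets)]
            spacers[h].append((f"{h}_sp{len(spacers[h]):03d}", cut(g)))
        for g in targets:
            pairs.add((g.genome_id, h))

    # the broad-range virus picks up spacers from k-1 additional hosts
    own = assigned[broad_range_virus]
    extra_hosts = [h for h in hosts if h != own][: k - 1]
    for h in extra_hosts:
        g = by_id[broad_range_virus]
        spacers[h].append((f"{h}_sp{len(spacers[h]):03d}", cut(g)))
        pairs.add((broad_range_virus, h))

    return SpacerSets(spacers=spacers, pairs=pairs, broad_range_virus=broad_range_virus)


def host_score_table(
    genomes: list[GenomeSim],
    hosts: list[str],
    seed: int,
    true_score_range: tuple[float, float] = (91.0, 99.5),
    other_score_range: tuple[float, float] = (20.0, 85.0),
) -> pd.DataFrame:
    """Fabricated integrated host-prediction scores (iPHoP-like, 0-100 scale):
    the true host scores inside ``true_score_range``, all others below 90."""
    rng = substream(seed, "host-scores")
    rows = []
    for g in genomes:
        for h in hosts:
            lo, hi = true_score_range if h == g.host else other_score_range
            rows.append(
                {"genome": g.genome_id, "host": h, "score": round(float(lo + (hi - lo) * rng.random()), 2)}
            )
    return pd.DataFrame(rows)
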