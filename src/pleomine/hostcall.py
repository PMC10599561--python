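"""Virus-host assignment: CRISPR-spacer matching with precedence over
integrated host scores.

Decision layer: if any candidate host has a spacer match against the virus,
the spacer-matched host with the most distinct matching spacers wins (ties:
higher score, then lexicographic host id). Otherwise the best integrated
score wins if it reaches 90. Otherwise no call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._seq import reverse_complement

DEFAULT_MIN_SCORE = 90.0
DEFAULT_MAX_MISMATCH = 1


@dataclass(frozen=True)
class SpacerMatch:
    host_id: str
    spacer_id: str
    genome_id: str
    position: int  # 0-based on the forward strand of the genome
    strand: str
    mismatches: int


@dataclass
class HostCall:
    genome_id: str
    host_id: str | None
    basis: str  # "crispr" | "score" | "none"
    score: float
    n_spacers: int = 0


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance, early-exiting once past ``limit``."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _occurrences(spacer: str, genome: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, mismatches) of ``spacer`` in ``genome`` with at most
    ``max_mismatch`` substitutions (no indels). With k mismatches allowed, at
    least one of k+1 equal blocks must match exactly, so exact substring
    search seeds the candidates."""
    L = len(spacer)
    if L == 0 or L > len(genome):
        return []
    out = []
    seen: set[int] = set()
    nblocks = max_mismatch + 1
    block = L // nblocks
    for b in range(nblocks):
        lo = b * block
        hi = L if b == nblocks - 1 else (b + 1) * block
        piece = spacer[lo:hi]
        start = 0
        while True:
            idx = genome.find(piece, start)
            if idx < 0:
                break
            pos = idx - lo
            start = idx + 1
            if pos < 0 or pos + L > len(genome) or pos in seen:
                continue
            seen.add(pos)
            mm = _mismatches(spacer, genome[pos : pos + L], max_mismatch)
            if mm <= max_mismatch:
                out.append((pos, mm))
    return sorted(out)


def match_spacers(
    spacer_sets: Mapping[str, Sequence[tuple[str, str]]],
    genome: tuple[str, str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[SpacerMatch]:
    """All occurrences of every host's spacers on either strand of the genome."""
    genome_id, seq = genome
    rc = reverse_complement(seq)
    L = len(seq)
    matches = []
    for host in sorted(spacer_sets):
        for spacer_id, spacer in spacer_sets[host]:
            if not spacer:
                raise ValueError(f"empty spacer {spacer_id!r}")
            for pos, mm in _occurrences(spacer, seq, max_mismatch):
                matches.append(SpacerMatch(host, spacer_id, genome_id, pos, "+", mm))
            for pos, mm in _occurrences(spacer, rc, max_mismatch):
                fwd = L - pos - len(spacer)
                matches.append(SpacerMatch(host, spacer_id, genome_id, fwd, "-", mm))
    matches.sort(key=lambda m: (m.host_id, m.spacer_id, m.position, m.strand))
    return matches


def decide_host(
    genome_id: str,
    candidate_scores: Mapping[str, float],
    spacer_matches: Sequence[SpacerMatch],
    min_score: float = DEFAULT_MIN_SCORE,
) -> HostCall:
    """CRISPR precedence, then best integrated score >= ``min_score``."""
    for h, s in candidate_scores.items():
        if not 0 <= s <= 100:
            raise ValueError(f"score for host {h!r} outside [0, 100]: {s}")
    by_host: dict[str, set[str]] = {}
    for m in spacer_matches:
        if m.genome_id == genome_id:
            by_host.setdefault(m.host_id, set()).add(m.spacer_id)
    if by_host:
        # most distinct spacers, then highest score, then lexicographic host id
        best = min(
            by_host,
            key=lambda h: (-len(by_host[h]), -candidate_scores.get(h, 0.0), h),
        )
        return HostCall(
            genome_id,
            best,
            "crispr",
            float(candidate_scores.get(best, 0.0)),
            n_spacers=len(by_host[best]),
        )
    if candidate_scores:
        best = min(candidate_scores, key=lambda h: (-candidate_scores[h], h))
        if candidate_scores[best] >= min_score:
            return HostCall(genome_id, best, "score", float(candidate_scores[best]))
    return HostCall(genome_id, None, "none", 0.0)


def host_range_summary(
    spacer_matches: Iterable[SpacerMatch], genomes: Sequence[str] | None = None
) -> tuple[dict[str, int], Counter]:
    """Distinct targeting-host count per genome, plus the count histogram."""
    hosts_by_genome: dict[str, set[str]] = {}
    for m in spacer_matches:
        hosts_by_genome.setdefault(m.genome_id, set()).add(m.host_id)
    counts = {g: len(h) for g, h in hosts_by_genome.items()}
    if genomes is not None:
        for g in genomes:
            counts.setdefault(g, 0)
    return counts, Counter(counts.values())
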