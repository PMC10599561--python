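"""Species-rank dereplication: fragment-based ANI and greedy 95% clustering.

ANI is computed by slicing one genome into windows, aligning each window into
the other genome (edit-distance infix alignment), and averaging identity over
the aligned windows; the reported value is the better of the two directions.
Clustering is greedy longest-first: each genome joins the first existing
representative at >= 95% identity over >= 85% of the shorter genome, else it
founds a new cluster — the standard uncultivated-virus species convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

DEFAULT_ANI_THRESHOLD = 95.0
DEFAULT_AF_THRESHOLD = 0.85
_WINDOW = 500
_MIN_WINDOW_IDENTITY = 0.7
_PREFILTER_K = 16


@dataclass
class AniResult:
    query_id: str
    subject_id: str
    ani: float  # percent identity over aligned windows
    aligned_fraction: float  # fraction of the shorter genome aligned

    def __post_init__(self):
        if not 0.0 <= self.ani <= 100.0:
            raise ValueError("ani must be in [0, 100]")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction must be in [0, 1]")


@dataclass
class SpeciesCluster:
    cluster_id: int
    representative: str
    members: list[str] = field(default_factory=list)
    ani_to_representative: dict[str, float] = field(default_factory=dict)


def _directional(query: str, subject: str) -> tuple[float, float]:
    """(mean identity %, aligned fraction) mapping query windows into subject."""
    aligned_len = 0
    weighted_identity = 0.0
    n = len(query)
    starts = list(range(0, n, _WINDOW))
    for s in starts:
        window = query[s : s + _WINDOW]
        if len(window) < 100 and len(starts) > 1:
            continue  # trailing sliver
        result = edlib.align(window, subject, mode="HW", task="distance")
        dist = result["editDistance"]
        identity = 1.0 - dist / len(window)
        if identity >= _MIN_WINDOW_IDENTITY:
            aligned_len += len(window)
            weighted_identity += identity * len(window)
    if aligned_len == 0:
        return 0.0, 0.0
    return 100.0 * weighted_identity / aligned_len, aligned_len / n


def _shares_kmers(a: str, b: str, k: int = _PREFILTER_K, min_shared: int = 3) -> bool:
    """Exact-k-mer candidate check: unrelated random genomes share no 16-mers,
    while genomes above the species threshold share thousands."""
    if len(a) < k or len(b) < k:
        return True
    ka = {a[i : i + k] for i in range(0, len(a) - k + 1, 4)}
    shared = 0
    for j in range(0, len(b) - k + 1):
        if b[j : j + k] in ka:
            shared += 1
            if shared >= min_shared:
                return True
    return False


def pairwise_ani(
    a: tuple[str, str], b: tuple[str, str], prefilter: bool = True
) -> AniResult:
    """Symmetric ANI between two (id, sequence) genomes."""
    aid, aseq = a
    bid, bseq = b
    if not aseq or not bseq:
        raise ValueError("genome sequences must be non-empty")
    short_first = len(aseq) <= len(bseq)
    if prefilter and not _shares_kmers(aseq, bseq):
        return AniResult(aid, bid, 0.0, 0.0)
    ani_ab, af_ab = _directional(aseq, bseq)
    ani_ba, af_ba = _directional(bseq, aseq)
    ani = max(ani_ab, ani_ba)
    af = af_ab if short_first else af_ba  # fraction of the shorter genome
    return AniResult(aid, bid, round(ani, 4), round(af, 4))


def cluster_species(
    genomes: Sequence[tuple[str, str]],
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    prefilter: bool = True,
) -> list[SpeciesCluster]:
    """Greedy longest-first clustering against cluster representatives."""
    if not genomes:
        raise ValueError("need at least one genome")
    order = sorted(genomes, key=lambda g: (-len(g[1]), g[0]))
    clusters: list[SpeciesCluster] = []
    reps: list[tuple[str, str]] = []
    for gid, seq in order:
        placed = False
        for cluster, rep in zip(clusters, reps):
            res = pairwise_ani((gid, seq), rep, prefilter=prefilter)
            if res.ani >= ani_threshold and res.aligned_fraction >= af_threshold:
                cluster.members.append(gid)
                cluster.ani_to_representative[gid] = res.ani
                placed = True
                break
        if not placed:
            cluster = SpeciesCluster(len(clusters), gid, [gid], {gid: 100.0})
            clusters.append(cluster)
            reps.append((gid, seq))
    return clusters
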