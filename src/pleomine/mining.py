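"""Contig screening: ORF calling, marker scanning, cassette synteny, terminal
repeats, provirus detection, and the integrated completeness rule.

A contig is a pleolipovirus candidate when it is at least 2 kb and carries at
least one passing core marker; it is high-confidence when at least 4.5 kb and
carrying the full four-gene cassette (ORF4-, ORF6-, ORF7-, ORF8-like) in
canonical order, on one strand, with every adjacent inter-gene gap <= 4.5 kb.
A genome is complete iff it has terminal repeats (direct or inverted), is a
complete integrated provirus (>= 2 host genes on both flanks plus an internal
integrase), or carries an external completeness score of 100.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from ._seq import reverse_complement
from .markerdb import MarkerProfile, scan
from .simulate.config import CORE_MARKERS

DEFAULT_MAX_GAP = 4500
DEFAULT_MIN_CANDIDATE_LEN = 2000
DEFAULT_MIN_HC_LEN = 4500
DEFAULT_MIN_ORF_CODONS = 90
DEFAULT_MIN_TR_LEN = 20

_VALID_NT = set("ACGTN")


# --------------------------------------------------------------------- types


@dataclass(frozen=True)
class GeneCall:
    contig_id: str
    start: int  # 0-based half-open, includes the stop codon
    end: int
    strand: str
    protein: str

    @property
    def key(self) -> tuple:
        return (self.start, self.end, self.strand)


@dataclass(frozen=True)
class MarkerPlacement:
    marker: str
    start: int
    end: int
    strand: str
    score: float


@dataclass
class CassetteMatch:
    contig_id: str
    hits: tuple[MarkerPlacement, ...]  # in canonical marker order
    orientation: str  # "forward" or "reverse"
    max_adjacent_gap: int
    span: int

    @property
    def start(self) -> int:
        return min(h.start for h in self.hits)

    @property
    def end(self) -> int:
        return max(h.end for h in self.hits)


@dataclass
class TerminalRepeat:
    kind: str  # "DTR", "ITR" or "none"
    length: int


@dataclass
class ProvirusCall:
    start: int
    end: int
    n_left_flank: int
    n_right_flank: int
    complete: bool


@dataclass
class CompletenessCall:
    status: str  # "complete" | "incomplete"
    evidence: set[str] = field(default_factory=set)  # {"DTR","ITR","provirus","external_score_100"}
    repeat_length: int | None = None


@dataclass
class ContigScreen:
    contig_id: str
    length: int
    tier: str  # "high-confidence" | "candidate" | "excluded"
    markers: dict[str, MarkerPlacement] = field(default_factory=dict)  # best pass per profile
    placements: list[MarkerPlacement] = field(default_factory=list)  # all passing hits
    cassette: CassetteMatch | None = None
    gene_calls: list[GeneCall] = field(default_factory=list)
    reason: str = ""

    @property
    def n_core_markers(self) -> int:
        return sum(1 for m in self.markers if m in CORE_MARKERS)


@dataclass
class ScreenResult:
    contigs: list[ContigScreen]
    log: list[str] = field(default_factory=list)

    def by_id(self) -> dict[str, ContigScreen]:
        return {c.contig_id: c for c in self.contigs}

    def tier(self, name: str) -> list[ContigScreen]:
        return [c for c in self.contigs if c.tier == name]

    def high_confidence(self) -> list[ContigScreen]:
        return self.tier("high-confidence")

    def candidates(self) -> list[ContigScreen]:
        # tiers are nested: every high-confidence contig is also a candidate
        return [c for c in self.contigs if c.tier in ("candidate", "high-confidence")]


# --------------------------------------------------------------- gene calling


def call_genes(contig_id: str, seq: str, min_codons: int = DEFAULT_MIN_ORF_CODONS) -> list[GeneCall]:
    """All maximal ATG-initiated, stop-terminated ORFs of >= ``min_codons``
    codons on both strands (an internal stand-in for an external gene caller;
    externally supplied GFF3 calls may bypass this)."""
    seq = seq.upper()
    if set(seq) - _VALID_NT:
        bad = sorted(set(seq) - _VALID_NT)
        raise ValueError(f"contig {contig_id!r} contains non-nucleotide characters {bad}")
    calls = list(_scan_strand(contig_id, seq, "+", min_codons))
    rc = reverse_complement(seq)
    for call in _scan_strand(contig_id, rc, "-", min_codons):
        L = len(seq)
        calls.append(GeneCall(contig_id, L - call.end, L - call.start, "-", call.protein))
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


def _scan_strand(contig_id: str, seq: str, strand: str, min_codons: int):
    from Bio.Seq import Seq

    for frame in range(3):
        sub = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
        if len(sub) < 3:
            continue
        prot = str(Seq(sub).translate())
        seg_start = 0
        for segment in prot.split("*"):
            seg_end = seg_start + len(segment)
            if seg_end >= len(prot):  # trailing segment: no stop codon
                break
            m = segment.find("M")
            if m >= 0 and len(segment) - m >= min_codons:
                aa_start = seg_start + m
                nt_start = frame + 3 * aa_start
                nt_end = frame + 3 * (seg_end + 1)  # include the stop codon
                yield GeneCall(contig_id, nt_start, nt_end, strand, segment[m:])
            seg_start = seg_end + 1


# ------------------------------------------------------------------ cassette


def detect_cassette(
    contig_id: str,
    placements: Sequence[MarkerPlacement],
    max_gap: int = DEFAULT_MAX_GAP,
    markers: Sequence[str] = CORE_MARKERS,
    max_hits_per_marker: int = 5,
) -> CassetteMatch | None:
    """Find four co-linear marker hits in canonical order (either orientation)
    with every adjacent inter-gene gap <= ``max_gap``; smallest span wins."""
    by_marker: dict[str, list[MarkerPlacement]] = {m: [] for m in markers}
    for p in placements:
        if p.marker in by_marker:
            by_marker[p.marker].append(p)
    if any(not v for v in by_marker.values()):
        return None
    for m in by_marker:
        by_marker[m] = sorted(by_marker[m], key=lambda p: -p.score)[:max_hits_per_marker]

    best: CassetteMatch | None = None
    for combo in itertools.product(*(by_marker[m] for m in markers)):
        for orientation in ("forward", "reverse"):
            match = _check_combo(contig_id, combo, orientation, max_gap)
            if match and (best is None or match.span < best.span):
                best = match
    return best


def _check_combo(contig_id, combo, orientation, max_gap) -> CassetteMatch | None:
    strand = "+" if orientation == "forward" else "-"
    if any(p.strand != strand for p in combo):
        return None
    gaps = []
    for a, b in zip(combo, combo[1:]):
        if orientation == "forward":
            if b.start < a.start:
                return None
            gaps.append(b.start - a.end)
        else:
            if b.start > a.start:
                return None
            gaps.append(a.start - b.end)
    if any(g > max_gap for g in gaps):
        return None
    span = max(p.end for p in combo) - min(p.start for p in combo)
    return CassetteMatch(contig_id, tuple(combo), orientation, max(gaps), span)


# ----------------------------------------------------------------- screening


def screen_contigs(
    contigs: Sequence[tuple[str, str]],
    profiles: dict[str, MarkerProfile],
    min_candidate_len: int = DEFAULT_MIN_CANDIDATE_LEN,
    min_hc_len: int = DEFAULT_MIN_HC_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
    gene_calls: dict[str, list[GeneCall]] | None = None,
    core_markers: Sequence[str] = CORE_MARKERS,
) -> ScreenResult:
    """Tiered marker screen over contigs. All profiles are scanned (core
    markers drive the tiers; hallmark/integrase placements ride along for
    downstream use)."""
    rows: list[ContigScreen] = []
    log: list[str] = []
    for contig_id, seq in contigs:
        calls = gene_calls.get(contig_id, []) if gene_calls is not None else call_genes(contig_id, seq)
        placements: list[MarkerPlacement] = []
        best: dict[str, MarkerPlacement] = {}
        for name, profile in profiles.items():
            hits = scan(profile, [(f"{i}", c.protein) for i, c in enumerate(calls)])
            for h in hits:
                if not h.passed:
                    continue
                gene = calls[int(h.protein_id)]
                p = MarkerPlacement(name, gene.start, gene.end, gene.strand, h.score)
                placements.append(p)
                if name not in best or p.score > best[name].score:
                    best[name] = p
        core_present = [m for m in core_markers if m in best]
        cassette = detect_cassette(contig_id, placements, max_gap=max_gap, markers=core_markers)
        length = len(seq)
        if cassette is not None and length >= min_hc_len:
            tier, reason = "high-confidence", "cassette + length"
        elif length >= min_candidate_len and core_present:
            tier = "candidate"
            reason = "no cassette" if cassette is None else f"length < {min_hc_len}"
        else:
            tier = "excluded"
            if length < min_candidate_len:
                reason = f"length < {min_candidate_len}"
            else:
                reason = "no passing core marker"
        log.append(f"{contig_id}\t{tier}\t{reason}")
        rows.append(
            ContigScreen(
                contig_id=contig_id,
                length=length,
                tier=tier,
                markers=best,
                placements=placements,
                cassette=cassette,
                gene_calls=calls,
                reason=reason,
            )
        )
    return ScreenResult(contigs=rows, log=log)


# ---------------------------------------------------------- terminal repeats


def detect_terminal_repeats(
    seq: str, min_len: int = DEFAULT_MIN_TR_LEN, max_len: int = 500
) -> TerminalRepeat:
    """Longest exact direct (prefix == suffix) or inverted (prefix ==
    revcomp(suffix)) terminal repeat; DTR takes precedence on ties."""
    if len(seq) <= 2 * min_len:
        raise ValueError(f"contig length must exceed 2*min_len = {2 * min_len}")
    cap = min(max_len, len(seq) // 2)
    dtr = itr = 0
    for k in range(cap, min_len - 1, -1):
        if dtr == 0 and seq[:k] == seq[-k:]:
            dtr = k
        if itr == 0 and seq[:k] == reverse_complement(seq[-k:]):
            itr = k
        if dtr and itr:
            break
    if dtr >= min_len and dtr >= itr:
        return TerminalRepeat("DTR", dtr)
    if itr >= min_len:
        return TerminalRepeat("ITR", itr)
    return TerminalRepeat("none", 0)


# ------------------------------------------------------------------ provirus


def call_provirus(
    contig_id: str,
    cassette: CassetteMatch,
    gene_calls: Sequence[GeneCall],
    viral_gene_keys: set[tuple],
    integrase_gene_keys: set[tuple],
    min_flank_genes: int = 2,
) -> ProvirusCall | None:
    """Integrated-provirus rule: >= ``min_flank_genes`` non-viral genes strictly
    on each side of the viral region AND an integrase hit inside it."""
    if cassette is None:
        raise ValueError("provirus detection requires a cassette match")
    viral = [g for g in gene_calls if g.key in viral_gene_keys]
    if not viral:
        return None
    start = min(g.start for g in viral)
    end = max(g.end for g in viral)
    has_integrase = any(
        k in integrase_gene_keys for k in (g.key for g in gene_calls) if start <= k[0] and k[1] <= end
    )
    if not has_integrase:
        return None
    left = [g for g in gene_calls if g.key not in viral_gene_keys and g.end <= start]
    right = [g for g in gene_calls if g.key not in viral_gene_keys and g.start >= end]
    if len(left) >= min_flank_genes and len(right) >= min_flank_genes:
        return ProvirusCall(start, end, len(left), len(right), complete=True)
    return None


# -------------------------------------------------------------- completeness


def integrate_completeness(
    tr_result: TerminalRepeat | None,
    provirus_result: ProvirusCall | None,
    external_score: float | None = None,
) -> CompletenessCall:
    """Complete iff terminal repeats, complete provirus, or external score 100."""
    if external_score is not None and not 0 <= external_score <= 100:
        raise ValueError("external completeness score must be in [0, 100]")
    evidence: set[str] = set()
    repeat_length = None
    if tr_result is not None and tr_result.kind in ("DTR", "ITR"):
        evidence.add(tr_result.kind)
        repeat_length = tr_result.length
    if provirus_result is not None and provirus_result.complete:
        evidence.add("provirus")
    if external_score is not None and external_score == 100:
        evidence.add("external_score_100")
    status = "complete" if evidence else "incomplete"
    return CompletenessCall(status=status, evidence=evidence, repeat_length=repeat_length)
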