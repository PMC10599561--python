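"""Genome mining: ORF calling, cassette synteny, tiers, terminal repeats,
provirus rule, and the integrated completeness call."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pleomine._seq import random_dna, random_protein, reverse_complement, reverse_translate, substream
from pleomine.mining import (
    CassetteMatch,
    GeneCall,
    MarkerPlacement,
    ProvirusCall,
    TerminalRepeat,
    call_genes,
    call_provirus,
    detect_cassette,
    detect_terminal_repeats,
    integrate_completeness,
    screen_contigs,
)
from pleomine.simulate import CORE_MARKERS


def _contig_with_orf(seed: int, codons: int = 200) -> tuple[str, str, int, int]:
    rng = substream(seed, "orf-contig")
    prot = random_protein(codons, rng)
    cds = reverse_translate(prot, rng)
    left = random_dna(400, rng)
    right = random_dna(400, rng)
    return left + cds + right, prot, len(left), len(left) + len(cds)


def six_frame_oracle(seq: str, min_codons: int = 90):
    """Independent brute-force ORF scan: walk codons in all six frames."""
    out = set()
    stops = {"TAA", "TAG", "TGA"}
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        L = len(s)
        for frame in range(3):
            start = None
            pos = frame
            while pos + 3 <= L:
                codon = s[pos : pos + 3]
                if codon in stops:
                    if start is not None and (pos - start) // 3 >= min_codons:
                        a, b = start, pos + 3
                        if strand == "-":
                            a, b = L - (pos + 3), L - start
                        out.add((a, b, strand))
                    start = None
                elif codon == "ATG" and start is None:
                    start = pos
                pos += 3
    return out


class TestCallGenes:
    def test_planted_orf_recovered_exactly(self):
        seq, prot, start, end = _contig_with_orf(1)
        calls = [c for c in call_genes("c", seq) if c.strand == "+"]
        spans = {(c.start, c.end): c for c in calls}
        assert (start, end) in spans
        assert spans[(start, end)].protein == prot

    def test_reverse_complement_symmetry(self):
        seq, _, _, _ = _contig_with_orf(2)
        fwd = call_genes("c", seq)
        rev = call_genes("c", reverse_complement(seq))
        assert {c.protein for c in fwd} == {c.protein for c in rev}
        L = len(seq)
        mapped = {(L - c.end, L - c.start, "+-"["+-".index(c.strand) ^ 1]) for c in rev}
        assert {(c.start, c.end, c.strand) for c in fwd} == mapped

    def test_agreement_with_six_frame_oracle(self):
        for seed in range(10):
            rng = substream(seed, "oracle-contig")
            seq = random_dna(5000, rng)
            # plant one real gene so the oracle sees structure, not just noise
            prot = random_protein(100, rng)
            seq = seq[:1000] + reverse_translate(prot, rng) + seq[1000:]
            got = {(c.start, c.end, c.strand) for c in call_genes("c", seq)}
            assert got == six_frame_oracle(seq)

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(ValueError):
            call_genes("c", "ACGTQACGT")

    def test_orf_length_divisible_by_three(self):
        seq, _, _, _ = _contig_with_orf(3)
        for c in call_genes("c", seq):
            assert (c.end - c.start) % 3 == 0


def _place(marker, start, length=600, strand="+", score=100.0):
    return MarkerPlacement(marker, start, start + length, strand, score)


def exhaustive_cassette_oracle(placements, max_gap=4500):
    """Enumerate every one-hit-per-marker subset and orientation."""
    by_marker = {m: [p for p in placements if p.marker == m] for m in CORE_MARKERS}
    if any(not v for v in by_marker.values()):
        return None
    best = None
    for combo in itertools.product(*(by_marker[m] for m in CORE_MARKERS)):
        for orientation in ("forward", "reverse"):
            want = "+" if orientation == "forward" else "-"
            if any(p.strand != want for p in combo):
                continue
            ordered = list(combo) if orientation == "forward" else list(combo)[::-1]
            if [p.start for p in ordered] != sorted(p.start for p in ordered):
                continue
            gaps = [b.start - a.end for a, b in zip(ordered, ordered[1:])]
            if any(g > max_gap for g in gaps):
                continue
            span = max(p.end for p in combo) - min(p.start for p in combo)
            if best is None or span < best:
                best = span
    return best


class TestDetectCassette:
    def test_canonical_order_with_bounded_gaps_matches(self):
        ps = []
        pos = 0
        for marker, gap in zip(CORE_MARKERS, [0, 1000, 2000, 4000]):
            pos += gap
            ps.append(_place(marker, pos))
            pos += 600
        m = detect_cassette("c", ps)
        assert m is not None and m.orientation == "forward"
        assert m.span == max(p.end for p in ps) - min(p.start for p in ps)

    def test_single_gap_over_limit_rejected(self):
        ps = []
        pos = 0
        for marker, gap in zip(CORE_MARKERS, [0, 1000, 5000, 1000]):
            pos += gap
            ps.append(_place(marker, pos))
            pos += 600
        assert detect_cassette("c", ps) is None

    def test_reverse_orientation_detected(self):
        ps = []
        pos = 0
        for marker in reversed(CORE_MARKERS):
            ps.append(_place(marker, pos, strand="-"))
            pos += 700
        m = detect_cassette("c", ps)
        assert m is not None and m.orientation == "reverse"

    def test_mixed_strands_rejected(self):
        ps = [_place(m, i * 700) for i, m in enumerate(CORE_MARKERS)]
        ps[2] = _place("ORF7", 1400, strand="-")
        assert detect_cassette("c", ps) is None

    def test_agrees_with_exhaustive_subset_oracle_on_random_layouts(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ps = []
            for m in CORE_MARKERS:
                for _ in range(rng.integers(0, 3)):
                    ps.append(
                        _place(
                            m,
                            int(rng.integers(0, 20000)),
                            length=int(rng.integers(300, 900)),
                            strand="+-"[rng.integers(0, 2)],
                        )
                    )
            got = detect_cassette("c", ps)
            want = exhaustive_cassette_oracle(ps)
            if want is None:
                assert got is None
            else:
                assert got is not None and got.span == want


class TestScreenTiers:
    def test_tier_rules_on_simulated_contigs(self, sim_small, profiles_small):
        res = screen_contigs([(c.contig_id, c.seq) for c in sim_small.contigs], profiles_small)
        truth = sim_small.truth
        by_id = res.by_id()
        for t in truth.contigs.values():
            row = by_id[t.contig_id]
            if t.source_genome is None:
                assert row.tier == "excluded"  # decoys never pass markers
            elif t.cassette_complete and row.length >= 4500:
                assert row.tier == "high-confidence"
        # tiers nested
        hc = {c.contig_id for c in res.high_confidence()}
        cand = {c.contig_id for c in res.candidates()}
        assert hc <= cand

    def test_short_contig_excluded_even_with_marker(self, sim_small, profiles_small):
        # take a real genome and cut a 1.5 kb piece containing ORF7
        g = sim_small.genomes[0]
        gene = g.gene("ORF7")
        start = max(0, gene.start - 100)
        piece = g.seq[start : start + 1500]
        res = screen_contigs([("short", piece)], profiles_small)
        assert res.contigs[0].tier == "excluded"

    def test_reverse_complement_invariance_of_cassette_detection(self, sim_small, profiles_small):
        viral = next(c for c in sim_small.contigs if c.kind == "viral")
        fwd = screen_contigs([(viral.contig_id, viral.seq)], profiles_small)
        rev = screen_contigs([(viral.contig_id, reverse_complement(viral.seq))], profiles_small)
        a, b = fwd.contigs[0].cassette, rev.contigs[0].cassette
        assert (a is None) == (b is None)
        if a is not None:
            assert a.span == b.span
            assert {a.orientation, b.orientation} == {"forward", "reverse"}


class TestTerminalRepeats:
    def test_constructed_dtr(self):
        rng = substream(1, "tr")
        core = random_dna(3000, rng)
        seq = core + core[:30]
        tr = detect_terminal_repeats(seq)
        assert tr.kind == "DTR" and tr.length == 30

    def test_constructed_itr(self):
        rng = substream(2, "tr")
        core = random_dna(3000, rng)
        seq = core + reverse_complement(core[:25])
        tr = detect_terminal_repeats(seq)
        # the repeat can extend by chance if flanking bases complement
        assert tr.kind == "ITR" and tr.length >= 25

    def test_random_contigs_never_called(self):
        rng = substream(3, "tr-null")
        for _ in range(300):
            assert detect_terminal_repeats(random_dna(5000, rng)).kind == "none"

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError):
            detect_terminal_repeats("ACGT" * 10, min_len=20)


class TestProvirus:
    def _setup(self, n_left, n_right, with_integrase):
        genes = []
        viral_keys = set()
        integrase_keys = set()
        pos = 100
        for i in range(n_left):
            genes.append(GeneCall("c", pos, pos + 300, "+", "M" + "A" * 99))
            pos += 400
        viral_start = pos
        for marker in CORE_MARKERS:
            g = GeneCall("c", pos, pos + 300, "+", "M" + "C" * 99)
            genes.append(g)
            viral_keys.add(g.key)
            pos += 400
        if with_integrase:
            g = GeneCall("c", pos, pos + 300, "+", "M" + "D" * 99)
            genes.append(g)
            viral_keys.add(g.key)
            integrase_keys.add(g.key)
            pos += 400
        for i in range(n_right):
            genes.append(GeneCall("c", pos, pos + 300, "+", "M" + "A" * 99))
            pos += 400
        hits = tuple(
            MarkerPlacement(m, g.start, g.end, "+", 100.0)
            for m, g in zip(CORE_MARKERS, [g for g in genes if g.key in viral_keys])
        )
        cassette = CassetteMatch("c", hits, "forward", 100, 1500)
        return cassette, genes, viral_keys, integrase_keys

    def test_flanked_cassette_with_integrase_is_complete_provirus(self):
        cassette, genes, vk, ik = self._setup(3, 3, True)
        call = call_provirus("c", cassette, genes, vk, ik)
        assert call is not None and call.complete
        assert call.n_left_flank == 3 and call.n_right_flank == 3

    def test_cassette_at_contig_edge_is_not_a_provirus(self):
        cassette, genes, vk, ik = self._setup(0, 3, True)
        assert call_provirus("c", cassette, genes, vk, ik) is None

    def test_cassette_without_integrase_is_not_a_provirus(self):
        cassette, genes, vk, ik = self._setup(3, 3, False)
        assert call_provirus("c", cassette, genes, vk, ik) is None

    def test_cassette_alone_is_not_a_provirus(self):
        cassette, genes, vk, ik = self._setup(0, 0, True)
        assert call_provirus("c", cassette, genes, vk, ik) is None


class TestCompleteness:
    def test_dtr_only(self):
        call = integrate_completeness(TerminalRepeat("DTR", 30), None)
        assert call.status == "complete" and call.evidence == {"DTR"}
        assert call.repeat_length == 30

    def test_external_score_below_100_is_incomplete(self):
        call = integrate_completeness(TerminalRepeat("none", 0), None, external_score=87)
        assert call.status == "incomplete" and not call.evidence

    def test_external_score_100_is_complete(self):
        call = integrate_completeness(None, None, external_score=100)
        assert call.status == "complete" and call.evidence == {"external_score_100"}

    def test_provirus_evidence(self):
        call = integrate_completeness(None, ProvirusCall(0, 10, 2, 2, True))
        assert call.status == "complete" and call.evidence == {"provirus"}

    def test_invalid_external_score(self):
        with pytest.raises(ValueError):
            integrate_completeness(None, None, external_score=120)

    def test_status_iff_evidence(self):
        for tr in (None, TerminalRepeat("none", 0), TerminalRepeat("ITR", 22)):
            for ext in (None, 50.0, 100.0):
                call = integrate_completeness(tr, None, ext)
                assert (call.status == "complete") == bool(call.evidence)
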