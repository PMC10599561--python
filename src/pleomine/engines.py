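"""Pluggable homology-search engines.

The marker-database procedure is engine-agnostic: anything that maps a
(query set, database) to a list of :class:`SearchHit` can drive the iterative
expansion. The reference engine is exact Smith-Waterman local alignment with
BLOSUM62 (gap open 11 / extend 1) and a Karlin-Altschul-style bit score and
e-value computed against the database size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, Sequence

Record = tuple[str, str]  # (label, sequence)


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_id: str
    bitscore: float
    e_value: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


class SearchEngine(Protocol):
    def search(self, queries: Sequence[Record], database: Sequence[Record]) -> list[SearchHit]:
        ...


# Karlin-Altschul parameters for gapped BLOSUM62 (11/1), as used by blastp
_LAMBDA = 0.267
_K = 0.041
_LN2 = math.log(2.0)


class SmithWatermanEngine:
    """Exact local alignment over all query x database pairs.

    Intended for the modest databases this package works with; no seeding or
    banding heuristics.
    """

    def __init__(self, max_evalue: float = 10.0, min_bitscore: float = 0.0):
        from Bio.Align import PairwiseAligner, substitution_matrices

        self.max_evalue = max_evalue
        self.min_bitscore = min_bitscore
        self._aligner = PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-11.0,
            extend_gap_score=-1.0,
        )

    def bitscore(self, raw_score: float) -> float:
        return (_LAMBDA * raw_score - math.log(_K)) / _LN2

    def search(self, queries: Sequence[Record], database: Sequence[Record]) -> list[SearchHit]:
        db_residues = sum(len(s) for _, s in database)
        hits: list[SearchHit] = []
        for qid, qseq in queries:
            for sid, sseq in database:
                raw = self._aligner.score(qseq, sseq)
                bits = self.bitscore(raw)
                if bits < self.min_bitscore:
                    continue
                evalue = len(qseq) * db_residues * math.pow(2.0, -bits)
                if evalue <= self.max_evalue:
                    hits.append(SearchHit(qid, sid, round(bits, 3), evalue))
        hits.sort(key=lambda h: (-h.bitscore, h.query_id, h.subject_id))
        return hits
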