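"""Calibrated marker profiles by iterative homology expansion.

The procedure mirrors how conserved-gene databases are grown from a handful
of isolate proteins: search the database with the current family, admit every
significant hit (e-value < 1e-5 and score > 50 by default), and iterate until
a fixed point; then build a position-specific scoring model from the family
and calibrate its acceptance threshold against true-positive / true-negative
score sets using the rule

    threshold = max( min(TP scores), max(TN scores) + 10 )

i.e. a passing score must reach the lowest true positive and clear the
highest true negative by 10 score units. Pass is inclusive (score >= threshold).
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import AMINO_ACIDS, encode_protein, random_protein, substream
from .engines import Record, SearchEngine, SearchHit, SmithWatermanEngine

DEFAULT_E_MAX = 1e-5
DEFAULT_S_MIN = 50.0
_BACKGROUND = 1.0 / 20.0
_PSEUDOCOUNT = 0.5


# --------------------------------------------------------------------- types


@dataclass
class CalibrationSet:
    true_positive_scores: list[float]
    true_negative_scores: list[float]

    def __post_init__(self):
        if not self.true_positive_scores or not self.true_negative_scores:
            raise ValueError("calibration requires non-empty TP and TN score lists")


@dataclass
class CalibrationResult:
    threshold: float
    excluded_true_positives: int
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MarkerHit:
    protein_id: str
    marker: str
    score: float
    passed: bool


@dataclass
class MarkerProfile:
    """Per-column log-odds scoring model over a uniform residue background.

    Scoring is ungapped: the shorter of (profile, target) slides along the
    longer and the best window sum (in bits) is the profile score.
    """

    name: str
    matrix: np.ndarray  # (length, 20) log2 odds
    members: list[str]  # member labels
    calibrated_threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def score(self, sequence: str) -> float:
        t = encode_protein(sequence)
        S = self.matrix
        lp, lt = S.shape[0], t.shape[0]
        if lt == 0:
            return float("-inf")
        if lt >= lp:
            windows = np.lib.stride_tricks.sliding_window_view(t, lp)
            return float(S[np.arange(lp), windows].sum(axis=1).max())
        best = -np.inf
        cols = np.arange(lt)
        for off in range(lp - lt + 1):
            best = max(best, float(S[cols + off, t].sum()))
        return best

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))

    # -- portable serialization ----------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            matrix=self.matrix,
            name=np.array(self.name),
            members=np.array(self.members),
            threshold=np.array(
                np.nan if self.calibrated_threshold is None else self.calibrated_threshold
            ),
        )

    @classmethod
    def load(cls, path) -> "MarkerProfile":
        data = np.load(path, allow_pickle=False)
        thr = float(data["threshold"])
        return cls(
            name=str(data["name"]),
            matrix=data["matrix"],
            members=[str(m) for m in data["members"]],
            calibrated_threshold=None if math.isnan(thr) else thr,
        )


# ---------------------------------------------------------------- operations


def _mafft_align(records: Sequence[Record]) -> list[Record]:
    import io as _io

    from Bio import SeqIO

    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.faa"
        with open(fin, "w") as fh:
            for i, (label, seq) in enumerate(records):
                fh.write(f">s{i}\n{seq}\n")
        out = subprocess.run(
            ["mafft", "--quiet", "--auto", str(fin)], capture_output=True, text=True, check=True
        )
        aligned = {r.id: str(r.seq).upper() for r in SeqIO.parse(_io.StringIO(out.stdout), "fasta")}
    return [(records[i][0], aligned[f"s{i}"]) for i in range(len(records))]


def build_profile(family: Sequence[Record], name: str = "marker") -> MarkerProfile:
    """Build an (uncalibrated) position-specific scoring model from a family.

    Equal-length members are stacked directly; mixed lengths are first aligned
    with MAFFT. Columns are scored as log2((freq + pseudocount) / background);
    gaps contribute nothing to column counts.
    """
    if not family:
        raise ValueError("family must contain at least one sequence")
    for label, seq in family:
        stripped = seq.replace("-", "")
        if any(ch not in AMINO_ACIDS for ch in stripped):
            raise ValueError(f"sequence {label!r} contains non-amino-acid characters")
    seqs = [seq for _, seq in family]
    if len({len(s) for s in seqs}) > 1:
        aligned = _mafft_align(list(family))
        seqs = [seq for _, seq in aligned]
    L = len(seqs[0])
    counts = np.zeros((L, 20))
    for seq in seqs:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i, aa in enumerate(AMINO_ACIDS):  # gap columns match no residue
            counts[arr == ord(aa), i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = (counts + _PSEUDOCOUNT) / (totals + 20 * _PSEUDOCOUNT)
    matrix = np.log2(freqs / _BACKGROUND)
    return MarkerProfile(
        name=name,
        matrix=matrix,
        members=sorted(label for label, _ in family),
        provenance={"n_members": len(family)},
    )


def calibrate_threshold(profile: MarkerProfile, calibration: CalibrationSet) -> CalibrationResult:
    """Apply the TP/TN threshold rule and stamp the profile as calibrated."""
    tp = calibration.true_positive_scores
    tn = calibration.true_negative_scores
    threshold = max(min(tp), max(tn) + 10.0)
    excluded = sum(1 for s in tp if s < threshold)
    warnings = []
    if excluded:
        warnings.append(
            f"{profile.name}: threshold {threshold:.2f} excludes {excluded} true positive(s)"
        )
    profile.calibrated_threshold = threshold
    return CalibrationResult(threshold=threshold, excluded_true_positives=excluded, warnings=warnings)


def calibration_set_from_sequences(
    profile: MarkerProfile, tp: Sequence[Record], tn: Sequence[Record]
) -> CalibrationSet:
    return CalibrationSet(
        true_positive_scores=[profile.score(s) for _, s in tp],
        true_negative_scores=[profile.score(s) for _, s in tn],
    )


def scan(profile: MarkerProfile, proteins: Sequence[Record]) -> list[MarkerHit]:
    """Score proteins against a calibrated profile; pass iff score >= threshold."""
    if profile.calibrated_threshold is None:
        raise RuntimeError(f"profile {profile.name!r} is not calibrated")
    thr = profile.calibrated_threshold
    hits = []
    for pid, seq in proteins:
        s = profile.score(seq)
        hits.append(MarkerHit(pid, profile.name, round(s, 4), s >= thr))
    hits.sort(key=lambda h: (-h.score, h.protein_id))
    return hits


# ------------------------------------------------------- profile search engine


class ProfileSearchEngine:
    """SearchEngine that scores the database against a profile built from the
    current query family. The e-value comes from a Gumbel null fitted on
    random background sequences (deterministic given ``seed``)."""

    def __init__(self, seed: int = 0, n_null: int = 100):
        self.seed = seed
        self.n_null = n_null

    def search(self, queries: Sequence[Record], database: Sequence[Record]) -> list[SearchHit]:
        profile = build_profile(list(queries), name="query-family")
        rng = substream(self.seed, "profile-null", len(queries), profile.length)
        null_scores = np.array(
            [profile.score(random_protein(profile.length, rng, start_met=False)) for _ in range(self.n_null)]
        )
        mu, sigma = float(null_scores.mean()), float(null_scores.std())
        lam = math.pi / (sigma * math.sqrt(6.0)) if sigma > 0 else 1.0
        loc = mu - 0.5772156649 / lam
        hits = []
        for sid, sseq in database:
            s = profile.score(sseq)
            z = lam * (s - loc)
            p = 1.0 - math.exp(-math.exp(-z)) if z < 30 else math.exp(-z)
            evalue = max(len(database) * p, 0.0)
            hits.append(SearchHit("query-family", sid, round(s, 3), evalue))
        hits.sort(key=lambda h: (-h.bitscore, h.subject_id))
        return hits


# -------------------------------------------------------- iterative expansion


@dataclass
class ExpansionResult:
    family: list[Record]
    iterations: int
    log: list[dict] = field(default_factory=list)

    def member_ids(self) -> set[str]:
        return {label for label, _ in self.family}


def iterative_expand(
    seed_sequences: Sequence[Record],
    protein_database: Sequence[Record],
    engine: SearchEngine | None = None,
    e_max: float = DEFAULT_E_MAX,
    s_min: float = DEFAULT_S_MIN,
    search_with: str = "new",
    max_iterations: int | None = None,
) -> ExpansionResult:
    """Expand a seed family to its fixed point under the significance rule.

    ``search_with="new"`` queries only the members admitted in the previous
    round (pairwise engines: previously searched members cannot contribute new
    hits). ``search_with="family"`` re-queries the whole family each round,
    which is the right mode for profile engines that rescore the database
    against the updated family model.
    """
    if not seed_sequences:
        raise ValueError("seed_sequences must not be empty")
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if search_with not in ("new", "family"):
        raise ValueError("search_with must be 'new' or 'family'")
    engine = engine or SmithWatermanEngine()
    db_by_id = dict(protein_database)
    family: dict[str, str] = dict(seed_sequences)
    log: list[dict] = [
        {"iteration": 0, "member": label, "admitted_by": "seed", "bitscore": float("nan"), "e_value": float("nan")}
        for label, _ in seed_sequences
    ]
    queries = list(seed_sequences)
    iterations = 0
    while queries:
        iterations += 1
        hits = engine.search(queries, protein_database)
        new: dict[str, SearchHit] = {}
        for h in hits:
            if h.subject_id in family or h.subject_id not in db_by_id:
                continue
            if h.e_value < e_max and h.bitscore > s_min:
                if h.subject_id not in new or h.bitscore > new[h.subject_id].bitscore:
                    new[h.subject_id] = h
        for sid in sorted(new):
            h = new[sid]
            family[sid] = db_by_id[sid]
            log.append(
                {
                    "iteration": iterations,
                    "member": sid,
                    "admitted_by": h.query_id,
                    "bitscore": h.bitscore,
                    "e_value": h.e_value,
                }
            )
        if not new:
            break
        if search_with == "new":
            queries = [(sid, db_by_id[sid]) for sid in sorted(new)]
        else:
            queries = list(family.items())
        if max_iterations is not None and iterations >= max_iterations:
            break
    return ExpansionResult(family=list(family.items()), iterations=iterations, log=log)
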