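"""Five-genus classification: hallmark detection, concatenated ORF7+ORF8
distance phylogeny, bootstrap support, and the genus decision rules.

Hallmark precedence: a protein-primed type B polymerase marks gamma, an RCRE
marks alpha, a Rep protein marks the beta/delta pair (split by clade
placement on the concatenated tree), and genomes lacking all replication
hallmarks are epsilon when they fall inside the epsilon reference clade with
bootstrap support >= 0.95. Conflicting replication hallmarks or unplaceable
genomes stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import substream
from .markerdb import MarkerProfile, _mafft_align, scan
from .trees import PhyloTree, nj_tree

GENUS_SUPPORT_THRESHOLD = 0.95

#: replication hallmarks that are mutually exclusive across genera
_REPLICATION_HALLMARKS = ("polB", "RCRE", "Rep")


# --------------------------------------------------------------------- types


@dataclass
class HallmarkProfileCall:
    RCRE: bool = False
    Rep: bool = False
    polB: bool = False
    ORF8_like: bool = False
    integrase: bool = False
    VP3_type1: bool = False
    VP3_type2: bool = False

    def replication_hallmarks(self) -> set[str]:
        return {h for h in _REPLICATION_HALLMARKS if getattr(self, h)}


@dataclass
class GenusCall:
    genome_id: str
    genus: str  # alpha|beta|gamma|delta|epsilon|unassigned
    evidence: list[str] = field(default_factory=list)


@dataclass
class ConcatAlignment:
    labels: list[str]
    rows: dict[str, str]
    blocks: dict[str, tuple[int, int]]  # marker -> [start, end) columns
    warnings: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.vstack(
            [np.frombuffer(self.rows[lab].encode(), dtype=np.uint8) for lab in self.labels]
        )


# ---------------------------------------------------------------- operations


def detect_hallmarks(
    proteins: Sequence[tuple[str, str]], profiles: dict[str, MarkerProfile]
) -> HallmarkProfileCall:
    """Each boolean is true iff >= 1 passing scan hit for that hallmark."""
    call = HallmarkProfileCall()
    for name, profile in profiles.items():
        if not hasattr(call, name):
            continue
        hits = scan(profile, list(proteins))
        if any(h.passed for h in hits):
            setattr(call, name, True)
    return call


def align_markers(marker_seqs: dict[str, dict[str, str]]) -> ConcatAlignment:
    """Per-marker multiple alignment, columns concatenated; genomes missing a
    marker get a gap-only block. Genomes with no marker at all are excluded
    with a warning."""
    labels = sorted({g for seqs in marker_seqs.values() for g in seqs})
    warnings: list[str] = []
    rows = {g: [] for g in labels}
    blocks: dict[str, tuple[int, int]] = {}
    offset = 0
    for marker in marker_seqs:
        seqs = marker_seqs[marker]
        present = sorted(seqs)
        if not present:
            continue
        if len({len(seqs[g]) for g in present}) > 1:
            aligned = dict(_mafft_align([(g, seqs[g]) for g in present]))
        else:
            aligned = {g: seqs[g] for g in present}
        width = len(next(iter(aligned.values())))
        for g in labels:
            rows[g].append(aligned.get(g, "-" * width))
        blocks[marker] = (offset, offset + width)
        offset += width
    return ConcatAlignment(
        labels=labels,
        rows={g: "".join(parts) for g, parts in rows.items()},
        blocks=blocks,
        warnings=warnings,
    )


def align_and_concat(
    orf7: dict[str, str], orf8: dict[str, str], genomes: Sequence[str] | None = None
) -> ConcatAlignment:
    """Concatenated ORF7 + ORF8 marker alignment."""
    aln = align_markers({"ORF7": orf7, "ORF8": orf8})
    if genomes is not None:
        missing = sorted(set(genomes) - set(aln.labels))
        for g in missing:
            aln.warnings.append(f"{g}: neither ORF7 nor ORF8 present; excluded from phylogeny")
    return aln


def distance_matrix(
    alignment: ConcatAlignment,
) -> tuple[list[str], np.ndarray, list[tuple[str, str]]]:
    """Poisson-corrected p-distance over mutually ungapped columns.

    Pairs with zero mutually ungapped columns get NaN and are reported as
    excluded; d(x, x) = 0 and the matrix is symmetric by construction.
    """
    labels = alignment.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 aligned rows")
    A = alignment.matrix()
    valid = A != ord("-")
    n = len(labels)
    D = np.zeros((n, n))
    excluded: list[tuple[str, str]] = []
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        mism = (A[i] != A[i + 1 :]) & both
        counts = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(counts > 0, mism.sum(axis=1) / np.maximum(counts, 1), np.nan)
        d = -np.log(np.clip(1.0 - p, 1e-6, None))
        for k, j in enumerate(range(i + 1, n)):
            if counts[k] == 0:
                D[i, j] = D[j, i] = np.nan
                excluded.append((labels[i], labels[j]))
            else:
                D[i, j] = D[j, i] = d[k]
    return labels, D, excluded


def bootstrap_support(
    alignment: ConcatAlignment, n_replicates: int, seed: int
) -> dict[frozenset, float]:
    """Column-resampling bootstrap over NJ trees; support per split."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = alignment.labels
    A = alignment.matrix()
    L = A.shape[1]
    counts: dict[frozenset, int] = {}
    rng = substream(seed, "bootstrap")
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        sub = ConcatAlignment(
            labels=labels,
            rows={lab: A[i, cols].tobytes().decode() for i, lab in enumerate(labels)},
            blocks={},
        )
        try:
            labs, D, _ = distance_matrix(sub)
            tree = nj_tree(labs, D)
        except ValueError:
            continue
        for split in tree.splits():
            counts[split] = counts.get(split, 0) + 1
    return {s: c / n_replicates for s, c in counts.items()}


def _clade_genus(
    genome_id: str,
    tree: PhyloTree,
    supports: dict[frozenset, float],
    references: dict[str, str],
    min_support: float = GENUS_SUPPORT_THRESHOLD,
) -> tuple[str | None, str]:
    """Genus of the smallest supported clade containing the genome and
    references of exactly one genus; None when no such clade exists."""
    all_leaves = frozenset(tree.labels)
    candidates: list[tuple[int, str]] = []
    for split in tree.splits():
        if supports.get(split, 0.0) < min_support:
            continue
        for side in (split, all_leaves - split):
            if genome_id not in side:
                continue
            ref_genera = {references[r] for r in side if r in references and r != genome_id}
            if len(ref_genera) == 1:
                candidates.append((len(side), next(iter(ref_genera))))
    if not candidates:
        return None, "no supported single-genus clade"
    size, genus = min(candidates, key=lambda t: t[0])
    return genus, f"clade of {size} leaves, support >= {min_support}"


def assign_genus(
    genome_id: str,
    hallmarks: HallmarkProfileCall,
    tree: PhyloTree,
    supports: dict[frozenset, float],
    references: dict[str, str],
    min_support: float = GENUS_SUPPORT_THRESHOLD,
) -> GenusCall:
    """Apply the genus rules: polB -> gamma; RCRE -> alpha; Rep (and/or an
    ORF8-like replication protein) -> beta vs delta by clade; no hallmark ->
    epsilon by clade; conflicts or unplaceable genomes -> unassigned."""
    if references and not set(references.values()) >= {"alpha", "beta", "gamma", "delta", "epsilon"}:
        missing = {"alpha", "beta", "gamma", "delta", "epsilon"} - set(references.values())
        raise ValueError(f"reference set lacks genera: {sorted(missing)}")
    rep = hallmarks.replication_hallmarks()
    if len(rep) > 1:
        return GenusCall(genome_id, "unassigned", [f"conflict: {'+'.join(sorted(rep))}"])
    if hallmarks.polB:
        return GenusCall(genome_id, "gamma", ["hallmark: polB"])
    if hallmarks.RCRE:
        return GenusCall(genome_id, "alpha", ["hallmark: RCRE"])
    if genome_id not in tree.labels:
        return GenusCall(genome_id, "unassigned", ["not placed in tree"])
    clade_genus, why = _clade_genus(genome_id, tree, supports, references, min_support)
    if hallmarks.Rep or hallmarks.ORF8_like:
        basis = "Rep" if hallmarks.Rep else "ORF8_like"
        if clade_genus in ("beta", "delta"):
            return GenusCall(genome_id, clade_genus, [f"hallmark: {basis}", why])
        return GenusCall(genome_id, "unassigned", [f"hallmark: {basis}", f"clade: {clade_genus or why}"])
    if clade_genus == "epsilon":
        return GenusCall(genome_id, "epsilon", ["no replication hallmark", why])
    return GenusCall(genome_id, "unassigned", ["no replication hallmark", f"clade: {clade_genus or why}"])
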