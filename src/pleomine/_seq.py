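"""Shared sequence primitives: alphabets, deterministic RNG streams, mutation models.

All randomness in the package flows through :func:`substream`, which derives an
independent ``numpy`` Generator from a root seed plus a tuple of string/int tags.
Identical (seed, tags) always yield the identical stream, on every platform.
"""

from __future__ import annotations

import zlib
from typing import Iterable

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_ARR = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")

# Standard-code codons per amino acid (stops excluded), fixed order for determinism.
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(standard_dna_table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    for aa, codons in by_aa.items():
        CODONS_BY_AA[aa] = tuple(codons)


_build_codon_table()


def substream(seed: int, *tags: int | str) -> np.random.Generator:
    """Derive a deterministic, independent RNG from ``seed`` and a tag path."""
    keys = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            keys.append(zlib.crc32(t.encode()))
        else:
            keys.append(int(t) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


def encode_protein(seq: str) -> np.ndarray:
    """Protein string -> int array over the 20-letter alphabet."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for aa, i in _AA_INDEX.items():
        idx[arr == ord(aa)] = i
    if (idx < 0).any():
        bad = chr(arr[int(np.argmax(idx < 0))])
        raise ValueError(f"non-amino-acid character {bad!r} in protein sequence")
    return idx


def decode_protein(idx: np.ndarray) -> str:
    return _AA_ARR[idx].tobytes().decode()


def random_protein(length: int, rng: np.random.Generator, start_met: bool = True) -> str:
    """Uniform random protein; first residue fixed to Met so the encoded gene
    begins with the canonical ATG start codon."""
    if length < 1:
        raise ValueError("protein length must be positive")
    idx = rng.integers(0, 20, size=length)
    seq = decode_protein(idx)
    if start_met:
        seq = "M" + seq[1:]
    return seq


def mutate_protein(
    seq: str, rate: float, rng: np.random.Generator, keep_first: bool = True
) -> str:
    """Per-site substitution: each site mutates with probability ``rate`` to a
    uniformly chosen *different* residue. Site 0 (the start Met) is kept fixed
    when ``keep_first`` so reading frames stay ATG-initiated."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("mutation rate must be in [0, 1)")
    idx = encode_protein(seq)
    hit = rng.random(idx.shape) < rate
    if keep_first and len(idx):
        hit[0] = False
    # offset 1..19 guarantees the replacement differs from the original
    offsets = rng.integers(1, 20, size=idx.shape)
    idx = np.where(hit, (idx + offsets) % 20, idx)
    return decode_protein(idx)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        return 1.0
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((x == y).mean())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    arr = rng.integers(0, 4, size=length)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[arr].tobytes().decode()


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein as DNA with uniformly chosen synonymous codons plus a
    uniformly chosen stop codon."""
    codons = []
    for aa in protein:
        options = CODONS_BY_AA.get(aa)
        if options is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(0, len(options))])
    codons.append(STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def translate(dna: str) -> str:
    """Translate a stop-free coding sequence (no trailing stop handling)."""
    from Bio.Seq import Seq

    return str(Seq(dna).translate())


def chunked(items: Iterable, n: int):
    buf = []
    for it in items:
        buf.append(it)
        if len(buf) == n:
            yield buf
            buf = []
    if buf:
        yield buf
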