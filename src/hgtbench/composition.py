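"""Compositional criteria for parametric HGT detection.

Each criterion maps a nucleotide sequence (or an in-frame CDS) to a fixed
length real vector:

========== ====== ==============================================
criterion  length contents
========== ====== ==============================================
GC         1      G+C fraction
GC1GC3     2      G+C fraction at codon positions 1 and 3
CODON      61     sense-codon frequencies (stops excluded)
AA         20     amino-acid frequencies
DINUC_NORM 16     dinucleotide relative abundances rho*(XY)
DINUC31    16     normalized codon-junction (3:1) dinucleotides
TETRA      256    plain overlapping tetranucleotide frequencies
TETRA_NORM 256    tetranucleotide abundances relative to the
                  zero-order (mononucleotide-product) expectation
========== ====== ==============================================

Plain frequency vectors sum to 1 when any valid unit was counted;
normalized-ratio vectors have neutral value 1.  K-mers overlapping an N
are skipped and the denominator shrinks accordingly.  The rho-style
vectors (DINUC_NORM, TETRA_NORM) are symmetrized: counts are accumulated
over the sequence and its reverse complement so the result is strand
independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(BASES, repeat=3))
    if c not in _STANDARD.stop_codons
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(_STANDARD.forward_table.values())))
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
# codon index -> amino-acid index, aligned with SENSE_CODONS
CODON_TO_AA = np.array(
    [_AA_INDEX[_STANDARD.forward_table[c]] for c in SENSE_CODONS], dtype=np.intp
)


class Criterion(str, Enum):
    GC = "GC"
    GC1GC3 = "GC1GC3"
    CODON = "CODON"
    AA = "AA"
    DINUC_NORM = "DINUC_NORM"
    DINUC31 = "DINUC31"
    TETRA = "TETRA"
    TETRA_NORM = "TETRA_NORM"


CRITERION_DIM = {
    Criterion.GC: 1,
    Criterion.GC1GC3: 2,
    Criterion.CODON: 61,
    Criterion.AA: 20,
    Criterion.DINUC_NORM: 16,
    Criterion.DINUC31: 16,
    Criterion.TETRA: 256,
    Criterion.TETRA_NORM: 256,
}


@dataclass(frozen=True)
class CompositionVector:
    """A criterion vector plus the number of units (bases, k-mers or
    codons) it was estimated from; ``support == 0`` marks an unusable
    vector (e.g. an all-N window)."""

    criterion: Criterion
    values: np.ndarray
    support: int

    @property
    def usable(self) -> bool:
        return self.support > 0

    def __post_init__(self) -> None:
        expected = CRITERION_DIM[self.criterion]
        if self.values.shape != (expected,):
            raise ValueError(
                f"{self.criterion}: expected length {expected}, "
                f"got {self.values.shape}"
            )


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes A=0 C=1 G=2 T=3, N/other=-1."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[raw == ord(base)] = idx
    return codes


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def kmer_labels(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def _kmer_counts_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Overlapping k-mer counts from an integer code array; windows
    containing a negative code (N) are skipped."""
    n = codes.size
    if n < k:
        return np.zeros(4**k, dtype=np.int64)
    windows = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        col = codes[j : n - k + 1 + j]
        valid &= col >= 0
        windows = windows * 4 + np.where(col >= 0, col, 0)
    return np.bincount(windows[valid], minlength=4**k)


def kmer_counts(seq: str, k: int) -> np.ndarray:
    return _kmer_counts_codes(encode(seq), k)


def kmer_freqs(seq: str, k: int):
    """Overlapping k-mer frequencies (forward strand, lexicographic order).

    Supported k: 1, 2 and 4.  The vector is the plain (un-normalized)
    frequency vector; for k == 2 and k == 4 the criterion tags are
    DINUC_NORM / TETRA to match the vector lengths used downstream, and
    for k == 1 an untyped 4-vector is returned.
    """
    if k not in (1, 2, 4):
        raise ValueError(f"k must be 1, 2 or 4, got {k}")
    counts = kmer_counts(seq, k)
    total = int(counts.sum())
    values = counts / total if total else counts.astype(float)
    if k == 1:
        return _RawVector(values, total)
    crit = Criterion.DINUC_NORM if k == 2 else Criterion.TETRA
    return CompositionVector(crit, values, total)


@dataclass(frozen=True)
class _RawVector:
    """Internal: an untyped frequency vector (mononucleotides)."""

    values: np.ndarray
    support: int

    @property
    def usable(self) -> bool:
        return self.support > 0


def tetra_freqs(seq: str) -> CompositionVector:
    """Plain tetranucleotide frequency vector (the genomic signature)."""
    return kmer_freqs(seq, 4)


def gc_content(seq: str) -> CompositionVector:
    codes = encode(seq)
    valid = codes >= 0
    support = int(valid.sum())
    if support == 0:
        return CompositionVector(Criterion.GC, np.zeros(1), 0)
    gc = np.isin(codes, (_BASE_INDEX["G"], _BASE_INDEX["C"])).sum()
    return CompositionVector(Criterion.GC, np.array([gc / support]), support)


def gc_codon_positions(cds: str) -> CompositionVector:
    """GC fraction at codon positions 1 and 3 of an in-frame CDS."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    codes = encode(cds)
    out = np.zeros(2)
    supports = []
    for slot, pos in ((0, 0), (1, 2)):
        col = codes[pos::3]
        valid = col >= 0
        n = int(valid.sum())
        supports.append(n)
        if n:
            gc = np.isin(col[valid], (_BASE_INDEX["G"], _BASE_INDEX["C"])).sum()
            out[slot] = gc / n
    support = min(supports)
    return CompositionVector(Criterion.GC1GC3, out, support)


def _codon_indices(cds: str) -> np.ndarray:
    """Indices into SENSE_CODONS for each codon; stops and codons with N
    are dropped."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    cds = cds.upper()
    idx = [
        _CODON_INDEX[cds[i : i + 3]]
        for i in range(0, len(cds), 3)
        if cds[i : i + 3] in _CODON_INDEX
    ]
    return np.asarray(idx, dtype=np.intp)


def codon_usage(cds: str) -> CompositionVector:
    """Frequencies over the 61 sense codons of the standard code."""
    idx = _codon_indices(cds)
    counts = np.bincount(idx, minlength=61).astype(float)
    total = int(counts.sum())
    values = counts / total if total else counts
    return CompositionVector(Criterion.CODON, values, total)


def amino_acid_usage(cds: str) -> CompositionVector:
    """Frequencies over the 20 amino acids (standard-code translation,
    stops excluded)."""
    idx = _codon_indices(cds)
    counts = np.bincount(CODON_TO_AA[idx], minlength=20).astype(float)
    total = int(counts.sum())
    values = counts / total if total else counts
    return CompositionVector(Criterion.AA, values, total)


def _symmetrized_counts(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(k-mer counts, mononucleotide counts) accumulated over the sequence
    and its reverse complement, treated as two separate strings."""
    fwd = encode(seq)
    rev = encode(reverse_complement(seq))
    kc = _kmer_counts_codes(fwd, k) + _kmer_counts_codes(rev, k)
    mc = _kmer_counts_codes(fwd, 1) + _kmer_counts_codes(rev, 1)
    return kc, mc


def normalized_dinucleotides(seq: str) -> CompositionVector:
    """Karlin's dinucleotide relative abundance rho*(XY) = f*(XY) /
    (f*(X) f*(Y)), with frequencies from the sequence plus its reverse
    complement."""
    kc, mc = _symmetrized_counts(seq, 2)
    ktot, mtot = kc.sum(), mc.sum()
    if ktot == 0 or (mc == 0).any():
        return CompositionVector(Criterion.DINUC_NORM, np.zeros(16), 0)
    f2 = kc / ktot
    f1 = mc / mtot
    expected = np.outer(f1, f1).ravel()
    return CompositionVector(Criterion.DINUC_NORM, f2 / expected, int(ktot) // 2)


def normalized_tetranucleotides(seq: str) -> CompositionVector:
    """Tetranucleotide abundance relative to the zero-order expectation:
    rho(w1..w4) = f(w) / (f(w1) f(w2) f(w3) f(w4)), symmetrized."""
    kc, mc = _symmetrized_counts(seq, 4)
    ktot, mtot = kc.sum(), mc.sum()
    if ktot == 0 or (mc == 0).any():
        return CompositionVector(Criterion.TETRA_NORM, np.zeros(256), 0)
    f4 = kc / ktot
    f1 = mc / mtot
    expected = np.einsum("i,j,k,l->ijkl", f1, f1, f1, f1).ravel()
    return CompositionVector(Criterion.TETRA_NORM, f4 / expected, int(ktot) // 2)


def dinuc_31(cds: str) -> CompositionVector:
    """Normalized dinucleotides at codon position 3:1 — the dimer formed
    by the third base of codon i and the first base of codon i+1,
    normalized by the position-specific base frequencies."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    codes = encode(cds)
    n_codons = codes.size // 3
    if n_codons < 2:
        return CompositionVector(Criterion.DINUC31, np.zeros(16), 0)
    third = codes[2::3][: n_codons - 1]  # codons 1..n-1
    first = codes[0::3][1:n_codons]  # codons 2..n
    valid = (third >= 0) & (first >= 0)
    support = int(valid.sum())
    if support == 0:
        return CompositionVector(Criterion.DINUC31, np.zeros(16), 0)
    pair = third[valid] * 4 + first[valid]
    f31 = np.bincount(pair, minlength=16) / support
    f3 = np.bincount(third[valid], minlength=4) / support
    f1 = np.bincount(first[valid], minlength=4) / support
    expected = np.outer(f3, f1).ravel()
    values = np.divide(
        f31, expected, out=np.zeros(16), where=expected > 0
    )
    return CompositionVector(Criterion.DINUC31, values, support)


def junction_dimer_freqs(cds: str) -> CompositionVector:
    """Raw (un-normalized) 3:1 junction dimer frequencies; sums to 1."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    codes = encode(cds)
    n_codons = codes.size // 3
    if n_codons < 2:
        return CompositionVector(Criterion.DINUC31, np.zeros(16), 0)
    third = codes[2::3][: n_codons - 1]
    first = codes[0::3][1:n_codons]
    valid = (third >= 0) & (first >= 0)
    support = int(valid.sum())
    if support == 0:
        return CompositionVector(Criterion.DINUC31, np.zeros(16), 0)
    pair = third[valid] * 4 + first[valid]
    f31 = np.bincount(pair, minlength=16) / support
    return CompositionVector(Criterion.DINUC31, f31, support)
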