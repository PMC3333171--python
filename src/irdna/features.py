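"""Tetranucleotide composition vectors and the L1 metric.

A DNA sequence is summarised by the frequencies of its overlapping k-mers
(k=4 by default, giving the classic 256-dimensional tetranucleotide
signature).  Signatures are genome- and region-characteristic, which is what
lets compositionally conserved marker genes such as 16S rDNA be separated
from bulk genomic background without any alignment.

Coordinates follow base-4 encoding with A=0, C=1, G=2, T=3, most significant
digit first, so ``AAAA`` -> 0 and ``TTTT`` -> 255.  Windows containing any
non-ACGT symbol (N, IUPAC ambiguity codes) are skipped; counts are normalised
by the number of valid windows so sequences of different lengths are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateSequenceError, DimensionMismatchError, InvalidKmerError

ALPHABET = "ACGT"

# uppercase/lowercase ACGT -> 0..3, everything else (incl. U) -> -1
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class FeatureSpec:
    """Defines the k-mer feature space (k=4 -> 256 dimensions)."""

    k: int = 4
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def dimension(self) -> int:
        return len(self.alphabet) ** self.k


DEFAULT_SPEC = FeatureSpec()


@dataclass(frozen=True)
class FeatureVector:
    """A k-mer frequency profile plus the number of windows that produced it.

    ``values`` sums to 1 whenever ``valid_window_count > 0``.
    """

    values: np.ndarray
    valid_window_count: int
    spec: FeatureSpec = field(default=DEFAULT_SPEC)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (self.spec.dimension,):
            raise DimensionMismatchError(
                f"expected {self.spec.dimension} entries, got {self.values.shape}"
            )


def kmer_index(kmer: str, spec: FeatureSpec = DEFAULT_SPEC) -> int:
    """Map a k-mer to its coordinate, base-4 with A=0,C=1,G=2,T=3.

    Raises InvalidKmerError on non-ACGT symbols or wrong length.
    """
    if len(kmer) != spec.k:
        raise InvalidKmerError(f"expected a {spec.k}-mer, got {kmer!r}")
    idx = 0
    for ch in kmer:
        code = _CODE[ord(ch)] if ord(ch) < 256 else -1
        if code < 0:
            raise InvalidKmerError(f"non-ACGT symbol {ch!r} in {kmer!r}")
        idx = idx * 4 + code
    return int(idx)


def index_to_kmer(index: int, spec: FeatureSpec = DEFAULT_SPEC) -> str:
    """Inverse of :func:`kmer_index`."""
    if not 0 <= index < spec.dimension:
        raise InvalidKmerError(f"index {index} outside [0, {spec.dimension})")
    out = []
    for _ in range(spec.k):
        out.append(ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(out))


def encode_sequence(seq: str) -> np.ndarray:
    """Sequence -> int codes 0..3, with -1 marking ambiguous symbols."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[raw]


def counts_from_codes(codes: np.ndarray, k: int = 4) -> tuple[np.ndarray, int]:
    """Window counts over an encoded sequence, skipping ambiguous windows."""
    if len(codes) < k:
        return np.zeros(4**k, dtype=np.int64), 0
    wins = sliding_window_view(codes, k)
    valid = (wins >= 0).all(axis=1)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    idx = wins[valid] @ weights
    counts = np.bincount(idx, minlength=4**k)
    return counts, int(valid.sum())


def tetra_vector(seq: str, spec: FeatureSpec = DEFAULT_SPEC) -> FeatureVector:
    """Compute the k-mer frequency vector of a sequence.

    A width-k window slides with step 1; windows containing any non-ACGT
    symbol are skipped; counts are divided by the number of valid windows.
    Raises DegenerateSequenceError when the sequence is shorter than k or no
    window is ambiguity-free.
    """
    if len(seq) < spec.k:
        raise DegenerateSequenceError(
            f"sequence of length {len(seq)} shorter than k={spec.k}"
        )
    counts, n_valid = counts_from_codes(encode_sequence(seq), spec.k)
    if n_valid == 0:
        raise DegenerateSequenceError("no ambiguity-free window in sequence")
    return FeatureVector(counts / n_valid, n_valid, spec)


def manhattan_distance(a: FeatureVector, b: FeatureVector) -> float:
    """L1 distance between two feature vectors built under the same spec."""
    if a.values.shape != b.values.shape:
        raise DimensionMismatchError(
            f"dimension mismatch: {a.values.shape} vs {b.values.shape}"
        )
    return float(np.abs(a.values - b.values).sum())


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement; ambiguous symbols pass through unchanged."""
    return seq.translate(_RC)[::-1]
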