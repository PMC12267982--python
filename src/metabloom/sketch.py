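"""Canonical k-mer hashing and winnowing-minimizer sketches.

Sequences are reduced to sets of 64-bit hash values before indexing or
querying.  Every k-mer is canonicalized (the lexicographically smaller of
the k-mer and its reverse complement under the 2-bit A<C<G<T encoding) so
matching is strand-agnostic, then hashed with a seeded splitmix64 finalizer
to spread values uniformly for the Bloom filters downstream.

With window size ``w > k`` only the winnowing minimizer of each window of
``w - k + 1`` consecutive k-mers is kept, trading classification
sensitivity for a much smaller index; ``w == k`` disables winnowing and
keeps every canonical k-mer.  Ambiguous bases (anything outside ACGT)
invalidate only the k-mers that span them.  Sequences shorter than ``w``
contain no complete window and sketch to the empty set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

_U64 = np.uint64
_SENTINEL = _U64(0xFFFFFFFFFFFFFFFF)

DEFAULT_HASH_SEED = 0x1F0A5EED

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def splitmix64(x) -> np.ndarray:
    """Vectorized splitmix64 finalizer over uint64 values (wrapping)."""
    z = np.asarray(x, dtype=_U64)
    with np.errstate(over="ignore"):
        z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
        z = z ^ (z >> _U64(31))
    return z


@dataclass(frozen=True)
class SketchParams:
    """k-mer length, window size and hash seed of a sketch.

    ``w >= k``; ``w == k`` keeps all canonical k-mers.  The seed fixes the
    hash family so that index and query sketches are comparable.
    """

    k: int = 19
    w: int = 31
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self):
        if not 1 <= self.k <= 31:
            raise ParameterError(f"k must be in [1, 31], got {self.k}")
        if self.w < self.k:
            raise ParameterError(f"w ({self.w}) must be >= k ({self.k})")
        if not 0 <= self.hash_seed < 2 ** 63:
            raise ParameterError("hash_seed must fit in a non-negative int64")

    @property
    def _seed64(self) -> np.uint64:
        # pre-mixed so that canon ^ seed decorrelates from raw k-mer codes
        return splitmix64(np.array([self.hash_seed], dtype=_U64))[0]


@dataclass(frozen=True)
class MinimizerSet:
    """A distinct, sorted set of 64-bit sketch values."""

    values: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=_U64))

    def __post_init__(self):
        v = np.asarray(self.values, dtype=_U64)
        object.__setattr__(self, "values", np.unique(v))

    @property
    def cardinality(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.cardinality

    def union(self, other: "MinimizerSet") -> "MinimizerSet":
        return MinimizerSet(np.union1d(self.values, other.values))

    def intersection_count(self, other: "MinimizerSet") -> int:
        return int(np.intersect1d(self.values, other.values).size)


def encode(seq: str) -> np.ndarray:
    """2-bit codes (int8) of a sequence; -1 marks ambiguous bases."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def _kmer_hashes(codes: np.ndarray, params: SketchParams) -> np.ndarray:
    """Hash of the canonical k-mer at every position; sentinel where the
    k-mer spans an ambiguous base.  Length = len(codes) - k + 1."""
    k = params.k
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=_U64)
    bad = np.convolve((codes < 0).astype(np.int32), np.ones(k, dtype=np.int32),
                      mode="valid") > 0
    c = np.where(codes < 0, 0, codes).astype(_U64)
    rc = _U64(3) - c
    fwd = np.zeros(n, dtype=_U64)
    rev = np.zeros(n, dtype=_U64)
    for j in range(k):
        fwd = (fwd << _U64(2)) | c[j:j + n]
        rev = (rev << _U64(2)) | rc[k - 1 - j:k - 1 - j + n]
    canon = np.minimum(fwd, rev)
    h = splitmix64(canon ^ params._seed64)
    h[bad] = _SENTINEL
    return h


def canonical_value(kmer: str, params: SketchParams) -> int | None:
    """Hash of one canonical k-mer, or None if it has an ambiguous base."""
    if len(kmer) != params.k:
        raise ParameterError(
            f"k-mer length {len(kmer)} != k = {params.k}")
    h = _kmer_hashes(encode(kmer), params)
    return None if h[0] == _SENTINEL else int(h[0])


def minimizers(seq: str, params: SketchParams) -> MinimizerSet:
    """Winnowing-minimizer sketch of one sequence.

    For each window of ``w - k + 1`` consecutive k-mer positions the
    smallest valid canonical hash is emitted (ties resolve to the leftmost
    occurrence, which does not affect the value set); windows whose k-mers
    are all invalid emit nothing.
    """
    h = _kmer_hashes(encode(seq), params)
    if h.size == 0:
        return MinimizerSet()
    if params.w == params.k:
        vals = h[h != _SENTINEL]
        return MinimizerSet(vals)
    span = params.w - params.k + 1
    if h.size < span:
        return MinimizerSet()
    wins = np.lib.stride_tricks.sliding_window_view(h, span).min(axis=1)
    vals = wins[wins != _SENTINEL]
    return MinimizerSet(vals)


def sketch_sequences(seqs, params: SketchParams) -> MinimizerSet:
    """Union sketch of several sequences (e.g. the contigs of one assembly)."""
    parts = [minimizers(s, params).values for s in seqs]
    if not parts:
        return MinimizerSet()
    return MinimizerSet(np.concatenate(parts))


def sketch_reads(read1: str, read2: str | None,
                 params: SketchParams) -> MinimizerSet:
    """Joint sketch of a read or mate pair (union of per-mate sketches)."""
    m1 = minimizers(read1, params)
    if read2 is None:
        return m1
    return m1.union(minimizers(read2, params))
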