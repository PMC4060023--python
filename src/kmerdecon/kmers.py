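"""Canonical k-mer spaces and metagenome composition vectors.

A metagenome is summarized here as a single *ensemble* composition: one
frequency vector over canonical k-mer classes, computed jointly from every
read, rather than a per-read classification.  Counting is strand-symmetric —
a k-mer and its reverse complement are the same feature — which halves the
dimension for odd k and makes the profile of a read set identical to the
profile of its reverse complement.

For odd k no k-mer equals its own reverse complement, so the number of
canonical classes is m = 4^k / 2.  For even k the 4^(k/2) reverse-complement
palindromes are their own class and m = (4^k + 4^(k/2)) / 2.  The defaults
used throughout the package are k = 7 (m = 8192), with k = 6 (m = 2080) and
k = 8 (m = 32896) as the supported command-line range.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "KmerSpace",
    "MetagenomeVector",
    "canonical_index",
    "count_sequence",
    "profile_reads",
    "revcomp",
]

# Base encoding: A,C,G,T -> 0..3 (case-insensitive); every other byte -> 4,
# which marks the containing windows invalid.  The 2-bit numeric order
# coincides with lexicographic order over {A,C,G,T}, so "numerically
# smaller code" and "lexicographically smaller k-mer" are the same thing.
_INVALID = 4
_BASE_LUT = np.full(256, _INVALID, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _BASE_LUT[_c] = _i
    _BASE_LUT[_c + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _BASE_LUT[raw]


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of 2-bit packed k-mer codes."""
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (c & 3))
        c >>= 2
    return rc


class KmerSpace:
    """Canonical k-mer index for a fixed word length ``k``.

    Defines the feature dimension ``m`` and a deterministic bijection from
    canonical k-mer (the lexicographically smaller of a k-mer and its
    reverse complement) to a column position in ``[0, m)``; positions follow
    lexicographic order of the canonical representatives.

    The implementation keeps a dense code->index lookup table of size 4^k,
    so k is limited to at most 13 (beyond that both the table and the
    m-dimensional frequency vectors stop fitting in ordinary memory).
    """

    MAX_K = 13

    def __init__(self, k: int):
        k = int(k)
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k > self.MAX_K:
            raise ValueError(
                f"k={k} is not supported: the canonical index uses dense "
                f"4^k tables, feasible only for k <= {self.MAX_K}"
            )
        self.k = k
        codes = np.arange(4**k, dtype=np.int64)
        canon = np.minimum(codes, _revcomp_codes(codes, k))
        self._reps = np.unique(canon)  # sorted canonical codes
        self.m = int(self._reps.size)
        # code -> canonical class index, for every 2-bit packed k-mer code
        self._lut = np.searchsorted(self._reps, canon).astype(np.int32)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"KmerSpace(k={self.k}, m={self.m})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, KmerSpace) and other.k == self.k

    def __hash__(self) -> int:
        return hash(("KmerSpace", self.k))

    def kmer_at(self, index: int) -> str:
        """Canonical k-mer string occupying column ``index``."""
        code = int(self._reps[index])
        bases = [(code >> (2 * (self.k - 1 - j))) & 3 for j in range(self.k)]
        return bytes(_DECODE[bases]).decode("ascii")


def canonical_index(kmer: str, space: KmerSpace) -> int | None:
    """Index of a k-mer's canonical class, or ``None`` for ambiguous bases.

    Raises ``ValueError`` if the k-mer length does not match the space.
    """
    if len(kmer) != space.k:
        raise ValueError(
            f"k-mer length {len(kmer)} does not match space k={space.k}"
        )
    enc = encode(kmer)
    if (enc >= _INVALID).any():
        return None
    code = 0
    for b in enc:
        code = (code << 2) | int(b)
    return int(space._lut[code])


def _window_indices_pos(
    enc: np.ndarray, space: KmerSpace
) -> tuple[np.ndarray, np.ndarray]:
    """Class index and start position of every valid k-window.

    Windows touching a non-ACGT byte are dropped; a sequence shorter than k
    yields empty arrays.
    """
    k = space.k
    n_win = enc.size - k + 1
    if n_win <= 0:
        empty = np.empty(0, dtype=np.int64)
        return np.empty(0, dtype=np.int32), empty
    code = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        b = enc[j : j + n_win]
        valid &= b < _INVALID
        code <<= 2
        code |= b
    pos = np.flatnonzero(valid)
    return space._lut[code[pos]], pos


def _window_indices(enc: np.ndarray, space: KmerSpace) -> np.ndarray:
    """Canonical class index of every valid k-window of an encoded sequence."""
    return _window_indices_pos(enc, space)[0]


def count_sequence(
    seq: str, space: KmerSpace, counts: np.ndarray
) -> np.ndarray:
    """Add canonical k-mer counts of every valid window of ``seq`` to ``counts``.

    Windows containing a non-ACGT character contribute nothing; sequences
    shorter than k contribute nothing.  Returns the updated ``counts``.
    """
    if counts.shape != (space.m,):
        raise ValueError(
            f"counts has shape {counts.shape}, expected ({space.m},)"
        )
    idx = _window_indices(encode(seq), space)
    if idx.size:
        counts += np.bincount(idx, minlength=space.m)
    return counts


@dataclass
class MetagenomeVector:
    """Normalized ensemble k-mer composition of a read set.

    ``frequencies`` sums to 1 whenever any k-mer was observed; a read set
    yielding zero usable k-mers produces an all-zero vector flagged via
    ``is_degenerate``.
    """

    space: KmerSpace
    frequencies: np.ndarray
    total_kmers: int
    n_reads: int

    @property
    def is_degenerate(self) -> bool:
        return self.total_kmers == 0


# Flush threshold for the streaming counter: reads are concatenated (with an
# invalid separator byte, which voids boundary-crossing windows) into batches
# of roughly this many bases before one vectorized counting pass.
_BATCH_BASES = 2_000_000
_SEPARATOR = np.array([_INVALID], dtype=np.uint8)


def iter_count_reads(
    reads: Iterable[str], space: KmerSpace
) -> tuple[np.ndarray, int, int]:
    """Count canonical k-mers over a stream of reads.

    Returns ``(counts, total_kmers, n_reads)``.
    """
    counts = np.zeros(space.m, dtype=np.int64)
    total = 0
    n_reads = 0
    buf: list[np.ndarray] = []
    buffered = 0

    def flush() -> None:
        nonlocal counts, total, buffered
        if not buf:
            return
        idx = _window_indices(np.concatenate(buf), space)
        if idx.size:
            counts += np.bincount(idx, minlength=space.m)
            total += int(idx.size)
        buf.clear()
        buffered = 0

    for seq in reads:
        n_reads += 1
        enc = encode(seq)
        buf.append(enc)
        buf.append(_SEPARATOR)
        buffered += enc.size + 1
        if buffered >= _BATCH_BASES:
            flush()
    flush()
    return counts, total, n_reads


def profile_reads(
    reads: "str | os.PathLike[str] | Iterable[str]", space: KmerSpace
) -> MetagenomeVector:
    """Ensemble canonical k-mer frequency vector of a read set.

    ``reads`` is either a path to a FASTA/FASTQ file (plain or gzipped,
    format auto-detected) or any iterable of sequence strings.  Frequencies
    are counts divided by the total number of k-mer tokens; if no window is
    usable the vector is all-zero and a warning is emitted.
    """
    if isinstance(reads, (str, os.PathLike)):
        from .fastx import read_sequences

        reads = read_sequences(reads)
    counts, total, n_reads = iter_count_reads(reads, space)
    if total > 0:
        freq = counts / float(total)
    else:
        warnings.warn(
            "read set yielded no usable k-mers; returning an all-zero "
            "composition vector",
            stacklevel=2,
        )
        freq = np.zeros(space.m, dtype=np.float64)
    return MetagenomeVector(
        space=space, frequencies=freq, total_kmers=total, n_reads=n_reads
    )


def per_read_indices(
    reads: Iterable[str], space: KmerSpace
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical class indices of each read, as (indices, offsets).

    ``indices[offsets[i]:offsets[i+1]]`` are the class indices of read i.
    Used by the jackknife to recount subsamples without re-parsing.
    Reads are processed in separator-joined batches; a valid window is
    attributed to its read by its start position.
    """
    idx_chunks: list[np.ndarray] = []
    count_chunks: list[np.ndarray] = []
    buf: list[np.ndarray] = []
    starts: list[int] = []
    buffered = 0

    def flush() -> None:
        nonlocal buffered
        if not starts:
            return
        idx, pos = _window_indices_pos(np.concatenate(buf), space)
        start_arr = np.asarray(starts, dtype=np.int64)
        # separator-containing windows are invalid, so each valid window
        # lies wholly inside one read and maps to it by start position
        read_of = np.searchsorted(start_arr, pos, side="right") - 1
        idx_chunks.append(idx)
        count_chunks.append(
            np.bincount(read_of, minlength=start_arr.size).astype(np.int64)
        )
        buf.clear()
        starts.clear()
        buffered = 0

    for seq in reads:
        enc = encode(seq)
        starts.append(buffered)
        buf.append(enc)
        buf.append(_SEPARATOR)
        buffered += enc.size + 1
        if buffered >= _BATCH_BASES:
            flush()
    flush()

    if idx_chunks:
        indices = np.concatenate(idx_chunks)
        counts = np.concatenate(count_chunks)
    else:
        indices = np.empty(0, dtype=np.int32)
        counts = np.empty(0, dtype=np.int64)
    offsets = np.zeros(counts.size + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    return indices, offsets
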