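"""FASTA/FASTQ sequence streaming with gzip and format auto-detection.

Format is sniffed from the first non-blank character ('>' FASTA, '@' FASTQ);
gzip is detected from the file's magic bytes.  Parsing itself is delegated
to Biopython's low-level iterators; errors are re-raised with the 1-based
record number at which parsing failed.  Quality strings are discarded — the
profiling model uses composition only.
"""

from __future__ import annotations

import gzip
import os
from typing import IO, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastxFormatError

__all__ = ["open_text", "sniff_format", "read_sequences", "read_jellyfish_dump"]

_GZIP_MAGIC = b"\x1f\x8b"


def open_text(path: "str | os.PathLike[str]") -> IO[str]:
    """Open a possibly gzip-compressed text file for reading."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(handle: IO[str]) -> str:
    """Peek the first non-blank character and return 'fasta' or 'fastq'.

    The handle must be seekable; it is rewound before returning.
    """
    handle.seek(0)
    while True:
        ch = handle.read(1)
        if ch == "":
            raise FastxFormatError("empty sequence file")
        if not ch.isspace():
            break
    handle.seek(0)
    if ch == ">":
        return "fasta"
    if ch == "@":
        return "fastq"
    raise FastxFormatError(
        f"cannot detect FASTA/FASTQ format: first character {ch!r} "
        "is neither '>' nor '@'"
    )


def read_sequences(path: "str | os.PathLike[str]") -> Iterator[str]:
    """Yield raw sequence strings from a FASTA or FASTQ file.

    Multi-line FASTA and 4-line FASTQ records are supported, plain or
    gzipped.  A malformed record aborts with :class:`FastxFormatError`
    naming the record number.
    """
    with open_text(path) as handle:
        try:
            fmt = sniff_format(handle)
        except FastxFormatError as exc:
            if "empty" in str(exc):
                return  # no records: caller reports a degenerate profile
            raise
        if fmt == "fasta":
            records = SimpleFastaParser(handle)
        else:
            records = ((t, s) for t, s, _q in FastqGeneralIterator(handle))
        n = 0
        while True:
            try:
                _title, seq = next(records)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastxFormatError(
                    f"malformed {fmt.upper()} input in {os.fspath(path)} "
                    f"at record {n + 1}: {exc}"
                ) from exc
            n += 1
            yield seq


def read_jellyfish_dump(path: "str | os.PathLike[str]", space) -> "np.ndarray":
    """Parse a Jellyfish column text dump ("kmer count" per line) into counts.

    K-mers are canonicalized into ``space``; a k-mer and its reverse
    complement therefore accumulate into the same class.  Returns an int64
    count vector of length ``space.m``.
    """
    import numpy as np

    from .kmers import canonical_index

    counts = np.zeros(space.m, dtype=np.int64)
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FastxFormatError(
                    f"malformed Jellyfish dump line {lineno}: {line!r}"
                )
            kmer, count = parts
            try:
                c = int(count)
            except ValueError as exc:
                raise FastxFormatError(
                    f"non-integer count on Jellyfish dump line {lineno}"
                ) from exc
            idx = canonical_index(kmer, space)
            if idx is None:
                continue
            counts[idx] += c
    return counts
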