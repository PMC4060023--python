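"""Reference k-mer matrix: build from genome FASTA files, serialize, subset.

The reference is a dense m×n matrix A whose column j is the column-normalized
canonical k-mer frequency vector of genome j (all contigs/replicons pooled),
with an aligned taxonomy table of eight named ranks per genome.  Profiling a
metagenome amounts to finding the non-negative mixture of these columns that
best reproduces the metagenome's own composition vector.

Serialization is a small versioned binary container: an ASCII magic and
little-endian header (version, k, m, n, label-block length), a UTF-8 TSV
block with the genome ids and taxonomy, then the row-major float64 matrix.
Round-tripping is bit-exact and carries no timestamp, so rebuilding or
re-saving identical inputs yields byte-identical files.
"""

from __future__ import annotations

import io
import struct
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DatabaseFormatError, RankError, ReferenceBuildError
from .kmers import KmerSpace, iter_count_reads

__all__ = [
    "RANKS",
    "ReferenceMatrix",
    "build_reference",
    "save_reference",
    "load_reference",
    "ablate_reference",
    "read_taxonomy_table",
]

#: Taxonomic ranks, coarsest to finest.  "strain" identifies one reference
#: genome; aggregation at "strain" is the identity map of the genome profile.
RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

#: Sentinel for an unassigned taxon at some rank.
UNKNOWN = "unknown"

_MAGIC = b"KDRF"
_VERSION = 1
_HEADER = struct.Struct("<4sIIQQQ")  # magic, version, k, m, n, label bytes

_COLSUM_TOL = 1e-9


def _normalize_taxonomy(
    taxonomy: pd.DataFrame, genome_ids: Sequence[str]
) -> pd.DataFrame:
    """Align a taxonomy table to genome_ids; fill gaps with sentinels.

    Missing/blank entries become "unknown", except strain which defaults to
    the genome id so that strain labels stay unique per genome.
    """
    out = pd.DataFrame(index=pd.Index(genome_ids, name="genome_id"))
    for rank in RANKS:
        if rank in taxonomy.columns:
            col = taxonomy[rank].reindex(out.index).astype("object")
        else:
            col = pd.Series(index=out.index, dtype="object")
        col = col.where(col.notna() & (col.astype(str).str.strip() != ""),
                        other=None)
        if rank == "strain":
            col = col.where(col.notna() & (col != UNKNOWN), other=None)
            col = col.fillna(pd.Series(out.index, index=out.index))
        else:
            col = col.fillna(UNKNOWN)
        out[rank] = col.astype(str)
    dup = out["strain"].duplicated()
    if dup.any():
        raise ReferenceBuildError(
            "strain labels must be unique per genome; duplicated: "
            + ", ".join(sorted(out['strain'][dup].unique()))
        )
    return out


class ReferenceMatrix:
    """Column-normalized canonical k-mer frequency matrix with taxonomy.

    Parameters
    ----------
    space : KmerSpace
        Canonical k-mer space defining the row dimension m.
    matrix : ndarray, shape (m, n)
        Non-negative columns, each summing to 1.
    genome_ids : sequence of str
        Unique identifier per column.
    taxonomy : DataFrame
        One row per genome (indexed by genome_id) with the eight rank
        columns; missing ranks are filled with "unknown".
    """

    def __init__(
        self,
        space: KmerSpace,
        matrix: np.ndarray,
        genome_ids: Sequence[str],
        taxonomy: pd.DataFrame,
    ):
        matrix = np.ascontiguousarray(matrix, dtype=np.float64)
        genome_ids = [str(g) for g in genome_ids]
        if matrix.ndim != 2 or matrix.shape[0] != space.m:
            raise ValueError(
                f"matrix shape {matrix.shape} incompatible with m={space.m}"
            )
        n = matrix.shape[1]
        if n < 1:
            raise ValueError("reference must contain at least one genome")
        if len(genome_ids) != n:
            raise ValueError("genome_ids length does not match matrix columns")
        if len(set(genome_ids)) != n:
            raise ReferenceBuildError("duplicate genome_id in reference")
        if (matrix < 0).any():
            raise ValueError("reference matrix must be non-negative")
        colsums = matrix.sum(axis=0)
        bad = np.flatnonzero(np.abs(colsums - 1.0) > _COLSUM_TOL)
        if bad.size:
            raise ValueError(
                "columns not normalized to sum 1: "
                + ", ".join(genome_ids[i] for i in bad[:5])
            )
        self.space = space
        self.matrix = matrix
        self.genome_ids = genome_ids
        self.taxonomy = _normalize_taxonomy(taxonomy, genome_ids)

    @property
    def k(self) -> int:
        return self.space.k

    @property
    def m(self) -> int:
        return self.space.m

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ReferenceMatrix(k={self.k}, m={self.m}, n={self.n})"


def build_reference(
    genomes: Iterable[tuple[str, "str", Mapping[str, str]]], k: int
) -> ReferenceMatrix:
    """Build a reference matrix from (genome_id, fasta_path, label) triples.

    Each genome's contigs are pooled into one column of canonical k-mer
    frequencies.  A genome with zero usable k-mers, or a duplicated
    genome_id, is a hard error.  Construction is deterministic: identical
    inputs give a bit-identical matrix.
    """
    from .fastx import read_sequences

    space = KmerSpace(k)
    ids: list[str] = []
    cols: list[np.ndarray] = []
    labels: list[Mapping[str, str]] = []
    for genome_id, fasta_path, label in genomes:
        genome_id = str(genome_id)
        if genome_id in ids:
            raise ReferenceBuildError(f"duplicate genome_id: {genome_id!r}")
        counts, total, _n = iter_count_reads(read_sequences(fasta_path), space)
        if total == 0:
            raise ReferenceBuildError(
                f"genome {genome_id!r} ({fasta_path}) yields no usable "
                f"k-mers at k={k}"
            )
        ids.append(genome_id)
        cols.append(counts / float(total))
        labels.append(dict(label))
    taxonomy = pd.DataFrame(labels, index=pd.Index(ids, name="genome_id"))
    return ReferenceMatrix(space, np.column_stack(cols), ids, taxonomy)


def save_reference(db: ReferenceMatrix, path: "str") -> None:
    """Write a reference matrix to the versioned binary container."""
    buf = io.StringIO()
    table = db.taxonomy.reset_index()
    table.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    label_bytes = buf.getvalue().encode("utf-8")
    header = _HEADER.pack(
        _MAGIC, _VERSION, db.k, db.m, db.n, len(label_bytes)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(label_bytes)
        fh.write(np.ascontiguousarray(db.matrix).tobytes(order="C"))


def load_reference(path: "str", expect_k: int | None = None) -> ReferenceMatrix:
    """Load a reference matrix saved by :func:`save_reference`.

    ``expect_k`` asserts the database was built at a particular word length
    (e.g. a command-line request); a mismatch is an explicit error.
    """
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER.size)
        if len(raw) != _HEADER.size:
            raise DatabaseFormatError(f"{path}: truncated header")
        magic, version, k, m, n, label_len = _HEADER.unpack(raw)
        if magic != _MAGIC:
            raise DatabaseFormatError(f"{path}: not a reference database")
        if version != _VERSION:
            raise DatabaseFormatError(
                f"{path}: format version {version}, expected {_VERSION}"
            )
        if expect_k is not None and k != expect_k:
            raise DatabaseFormatError(
                f"{path}: database was built with k={k}, requested k={expect_k}"
            )
        label_bytes = fh.read(label_len)
        if len(label_bytes) != label_len:
            raise DatabaseFormatError(f"{path}: truncated label block")
        taxonomy = pd.read_csv(
            io.StringIO(label_bytes.decode("utf-8")), sep="\t", dtype=str
        ).set_index("genome_id")
        data = fh.read(8 * m * n)
        if len(data) != 8 * m * n:
            raise DatabaseFormatError(f"{path}: truncated matrix block")
    space = KmerSpace(k)
    if space.m != m:
        raise DatabaseFormatError(
            f"{path}: header m={m} inconsistent with k={k} (expected {space.m})"
        )
    matrix = np.frombuffer(data, dtype=np.float64).reshape(m, n).copy()
    return ReferenceMatrix(space, matrix, list(taxonomy.index), taxonomy)


def ablate_reference(
    db: ReferenceMatrix, rank: str, value: str
) -> ReferenceMatrix:
    """Remove every genome labeled ``value`` at ``rank``.

    Mirrors the leave-taxon-out protocol used to probe behavior on novel
    organisms: the profiler must then spread mass over the closest remaining
    references.  Removing a value present in no genome returns an equivalent
    database; removing everything is a hard error.
    """
    if rank not in RANKS:
        raise RankError(
            f"unknown rank {rank!r}; valid ranks: {', '.join(RANKS)}"
        )
    keep = (db.taxonomy[rank] != value).to_numpy()
    if keep.all():
        return ReferenceMatrix(
            db.space, db.matrix, db.genome_ids, db.taxonomy
        )
    if not keep.any():
        raise ReferenceBuildError(
            f"removing {rank}={value!r} would empty the reference"
        )
    ids = [g for g, k_ in zip(db.genome_ids, keep) if k_]
    return ReferenceMatrix(
        db.space, db.matrix[:, keep], ids, db.taxonomy.loc[ids]
    )


def read_taxonomy_table(path: "str") -> pd.DataFrame:
    """Read the taxonomy TSV sidecar (genome_id + eight rank columns).

    Unrecognized columns are ignored; missing rank columns are filled with
    "unknown" when the table is attached to a reference.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in table.columns:
        raise ReferenceBuildError(
            f"{path}: taxonomy table must have a 'genome_id' column"
        )
    if table["genome_id"].duplicated().any():
        raise ReferenceBuildError(f"{path}: duplicate genome_id in taxonomy")
    return table.set_index("genome_id")
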