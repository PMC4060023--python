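"""Jackknife (delete-half) uncertainty for abundance profiles.

Sampling variability of the fitted abundances is estimated by repeatedly
re-profiling a random half of the reads: each replicate draws
floor(fraction·n_reads) reads uniformly *without replacement*, recomputes
the full pipeline (ensemble k-mer vector → regularized NNLS → simplex
normalization → rank aggregation), and the per-taxon mean and population
standard deviation across replicates summarize the spread.  Defaults follow
the canonical protocol: fraction 0.5 and 1000 replicates.

Replicates use counter-based substreams — replicate r draws from
``default_rng([seed, r])`` — so results are reproducible for a fixed seed
regardless of execution order or thread count.  Per-read k-mer class
indices are extracted once and stored sparsely, so each replicate is a row
subset sum rather than a re-parse.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .kmers import per_read_indices
from .reference import RANKS, ReferenceMatrix
from .solve import DEFAULT_LAMBDA, normalize_to_simplex, solve_regularized

__all__ = ["JackknifeSummary", "jackknife_profile"]


@dataclass
class JackknifeSummary:
    """Per-taxon mean and spread of abundances over jackknife replicates.

    ``sd`` is the population (divide-by-reps) standard deviation.  Taxa are
    every taxon present in the reference at this rank; ``n_degenerate``
    counts replicates excluded because subsampling left no usable signal.
    """

    rank: str
    taxa: list[str]
    mean: np.ndarray
    sd: np.ndarray
    reps: int
    fraction: float
    seed: int
    n_degenerate: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Taxa with mean and sd, sorted by descending mean then name."""
        df = pd.DataFrame(
            {"taxon": self.taxa, "mean": self.mean, "sd": self.sd}
        )
        return df.sort_values(
            ["mean", "taxon"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


def _read_matrix(
    reads: Sequence[str], db: ReferenceMatrix
) -> sp.csr_matrix:
    """Sparse (n_reads × m) matrix of per-read canonical k-mer counts."""
    indices, offsets = per_read_indices(reads, db.space)
    data = np.ones(indices.size, dtype=np.float64)
    return sp.csr_matrix(
        (data, indices.astype(np.int64), offsets),
        shape=(len(reads), db.m),
    )


def _rank_groupings(
    db: ReferenceMatrix, ranks: Sequence[str]
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per rank: (taxa names, genome→taxon index array) for fast pooling."""
    out = {}
    for rank in ranks:
        labels = db.taxonomy.loc[db.genome_ids, rank].astype(str)
        taxa = sorted(labels.unique())
        pos = {t: i for i, t in enumerate(taxa)}
        out[rank] = (taxa, labels.map(pos).to_numpy(dtype=np.int64))
    return out


def jackknife_profile(
    reads: "str | os.PathLike[str] | Iterable[str]",
    db: ReferenceMatrix,
    fraction: float = 0.5,
    reps: int = 1000,
    seed: int = 0,
    lam: float = DEFAULT_LAMBDA,
    ranks: Sequence[str] = RANKS,
) -> dict[str, JackknifeSummary]:
    """Jackknife summaries of the abundance profile at each requested rank.

    ``reads`` is a FASTA/FASTQ path or an iterable of sequences; reads are
    materialized once.  Raises ``ValueError`` when the subsample size would
    be zero or when every replicate is degenerate.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    for rank in ranks:
        if rank not in RANKS:
            from .errors import RankError

            raise RankError(
                f"unknown rank {rank!r}; valid ranks: {', '.join(RANKS)}"
            )
    if isinstance(reads, (str, os.PathLike)):
        from .fastx import read_sequences

        reads = list(read_sequences(reads))
    else:
        reads = list(reads)
    n_reads = len(reads)
    n_sub = math.floor(fraction * n_reads)
    if n_sub < 1:
        raise ValueError(
            f"subsample of {n_reads} reads at fraction {fraction} is empty"
        )

    mat = _read_matrix(reads, db)
    groupings = _rank_groupings(db, ranks)
    per_rank: dict[str, list[np.ndarray]] = {rank: [] for rank in ranks}
    n_degenerate = 0
    for r in range(reps):
        rng = np.random.default_rng([int(seed), r])
        sel = rng.choice(n_reads, size=n_sub, replace=False)
        counts = np.asarray(mat[sel].sum(axis=0)).ravel()
        total = counts.sum()
        if total == 0:
            n_degenerate += 1
            continue
        raw, _ = solve_regularized(db.matrix, counts / total, lam)
        x, degenerate = normalize_to_simplex(raw)
        if degenerate:
            n_degenerate += 1
            continue
        for rank, (taxa, g) in groupings.items():
            per_rank[rank].append(
                np.bincount(g, weights=x, minlength=len(taxa))
            )
    n_ok = reps - n_degenerate
    if n_ok == 0:
        raise ValueError("every jackknife replicate was degenerate")

    out = {}
    for rank, (taxa, _g) in groupings.items():
        stack = np.vstack(per_rank[rank])
        out[rank] = JackknifeSummary(
            rank=rank,
            taxa=list(taxa),
            mean=stack.mean(axis=0),
            sd=stack.std(axis=0, ddof=0),
            reps=n_ok,
            fraction=fraction,
            seed=int(seed),
            n_degenerate=n_degenerate,
        )
    return out


def write_jackknife_report(
    summaries: Mapping[str, JackknifeSummary],
    path: "str | os.PathLike[str]",
) -> None:
    """Write all rank summaries as one TSV: rank, taxon, mean, sd."""
    lines = ["rank\ttaxon\tmean\tsd"]
    ranks = [r for r in RANKS if r in summaries]
    ranks += [r for r in summaries if r not in RANKS]
    for rank in ranks:
        for row in summaries[rank].to_frame().itertuples(index=False):
            lines.append(
                f"{rank}\t{row.taxon}\t{row.mean:.6f}\t{row.sd:.6f}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
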