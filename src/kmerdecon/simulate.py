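"""Synthetic genomes and shotgun read sets with known composition.

Every other module is testable without external data: genomes are i.i.d.
base sequences at a chosen GC content, and reads are drawn by (1) picking a
source genome from the ground-truth proportions, (2) a uniform start
position, (3) a uniform strand, and (4) i.i.d. per-base substitution errors
(uniform over the three alternative bases — no indels).  The generator
emits standard 4-line FASTQ (constant quality 'I') plus a read→genome truth
table, and is fully deterministic per seed.

Defaults mirror a single-end short-read study design: 100 nt reads, a
five-genome community at proportions (0.40, 0.25, 0.20, 0.10, 0.05), a flat
1% substitution rate, and 500,000 reads (tests and the acceptance protocol
use a 100,000-read scaled run).  Since reads have constant length and
substitution errors never create ambiguous bases, each read contributes the
same number of k-mer tokens, and the k-mer-space ground truth equals the
per-genome read fractions recorded in the truth table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import RANKS

__all__ = [
    "SimulationSpec",
    "generate_genome",
    "generate_reads",
    "write_fastq",
    "default_taxonomy",
    "truth_proportions",
]

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = {c: i for i, c in enumerate("ACGT")}

DEFAULT_PROPORTIONS = (0.40, 0.25, 0.20, 0.10, 0.05)


@dataclass
class SimulationSpec:
    """Parameters of one synthetic community and its read set."""

    n_genomes: int = 5
    genome_length: int = 50_000
    gc_content: "float | Sequence[float]" = 0.5
    proportions: Sequence[float] | None = None
    n_reads: int = 500_000
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.proportions is None:
            if self.n_genomes == len(DEFAULT_PROPORTIONS):
                self.proportions = DEFAULT_PROPORTIONS
            else:
                self.proportions = tuple(
                    [1.0 / self.n_genomes] * self.n_genomes
                )
        p = np.asarray(self.proportions, dtype=np.float64)
        if p.size != self.n_genomes:
            raise ValueError(
                f"{p.size} proportions for {self.n_genomes} genomes"
            )
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be >= 0 and sum to 1")
        self.proportions = tuple(float(v) for v in p)
        gc = self.gc_content
        if np.isscalar(gc):
            gc = [float(gc)] * self.n_genomes
        gc = [float(v) for v in gc]
        if len(gc) != self.n_genomes:
            raise ValueError("gc_content list must match n_genomes")
        if any(not 0 <= v <= 1 for v in gc):
            raise ValueError("gc_content must be in [0, 1]")
        self.gc_content = tuple(gc)

    def genome_ids(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_genomes)]


def _decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def generate_genome(length: int, gc_content: float, seed) -> str:
    """I.i.d. genome sequence: P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2.

    ``seed`` may be an int or an already-constructed Generator.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_content <= 1:
        raise ValueError("gc_content must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    bases = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return _decode(bases)


def generate_genomes(spec: SimulationSpec) -> list[str]:
    """All genomes of the community; genome i uses substream [seed, 0, i]."""
    return [
        generate_genome(
            spec.genome_length,
            spec.gc_content[i],
            np.random.default_rng([spec.seed, 0, i]),
        )
        for i in range(spec.n_genomes)
    ]


def generate_reads(
    spec: SimulationSpec, genomes: Sequence[str]
) -> tuple[list[str], pd.DataFrame]:
    """Draw the read set; returns (reads, truth table).

    The truth table has columns ``read_id`` ("r1", "r2", …, in emission
    order) and ``genome_id``.  Raises if any genome is shorter than the
    read length.
    """
    if len(genomes) != spec.n_genomes:
        raise ValueError("genomes do not match spec.n_genomes")
    rl = spec.read_length
    for i, g in enumerate(genomes):
        if len(g) < rl:
            raise ValueError(
                f"genome {i + 1} (length {len(g)}) shorter than "
                f"read_length {rl}"
            )
    enc = [
        np.array([_ENCODE[c] for c in g.upper()], dtype=np.uint8)
        for g in genomes
    ]
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_reads
    src = rng.choice(spec.n_genomes, size=n, p=list(spec.proportions))
    max_start = np.array([len(g) - rl + 1 for g in genomes], dtype=np.int64)
    starts = np.floor(rng.random(n) * max_start[src]).astype(np.int64)
    strands = rng.integers(0, 2, size=n)

    block = np.empty((n, rl), dtype=np.uint8)
    for i in range(n):
        block[i] = enc[src[i]][starts[i] : starts[i] + rl]
    rev = np.flatnonzero(strands == 1)
    if rev.size:
        block[rev] = 3 - block[rev, ::-1]
    if spec.error_rate > 0:
        hit = rng.random((n, rl)) < spec.error_rate
        n_hits = int(hit.sum())
        if n_hits:
            shift = rng.integers(1, 4, size=n_hits).astype(np.uint8)
            block[hit] = (block[hit] + shift) % 4

    reads = [_decode(row) for row in block]
    ids = spec.genome_ids()
    truth = pd.DataFrame(
        {
            "read_id": [f"r{i + 1}" for i in range(n)],
            "genome_id": [ids[s] for s in src],
        }
    )
    return reads, truth


def write_fastq(
    reads: Sequence[str],
    path: "str | os.PathLike[str]",
    ids: Sequence[str] | None = None,
) -> None:
    """Write reads as 4-line FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            rid = ids[i] if ids is not None else f"r{i + 1}"
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def default_taxonomy(genome_ids: Sequence[str]) -> pd.DataFrame:
    """A distinct synthetic lineage per genome (shared kingdom 'Bacteria').

    Rank values are systematic ("phylum1", "genus3", …); strain equals the
    genome id.  Tests that need genomes sharing a rank build their own
    tables.
    """
    rows = {}
    for i, gid in enumerate(genome_ids, start=1):
        row = {"kingdom": "Bacteria"}
        for rank in RANKS[1:-1]:
            row[rank] = f"{rank}{i}"
        row["strain"] = str(gid)
        rows[str(gid)] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genome_id"
    return df


def truth_proportions(
    truth: pd.DataFrame, genome_ids: Sequence[str]
) -> np.ndarray:
    """Realized per-genome read fractions from a truth table.

    With constant read length and substitution-only errors this equals the
    k-mer-space ground truth the profiler estimates.
    """
    counts = truth["genome_id"].value_counts()
    total = float(len(truth))
    return np.array(
        [counts.get(g, 0) / total for g in genome_ids], dtype=np.float64
    )
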