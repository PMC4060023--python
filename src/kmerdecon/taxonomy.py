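"""Rank-level aggregation of genome abundances, profile comparison, reports.

Genome-level abundances are pooled upward by summing over genomes sharing a
taxon name at the requested rank; "unknown" labels pool into a single
"unknown" entry.  Aggregation is linear and conserves total mass, so the sum
at any rank equals the strain-level sum.  Profiles of the same rank are
compared by Euclidean distance over the union of their taxa (absent taxa
imputed as zero).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import RankError
from .reference import RANKS
from .solve import AbundanceProfile

__all__ = ["RankProfile", "aggregate", "euclidean_distance", "write_report"]


@dataclass
class RankProfile:
    """Relative abundances pooled at one taxonomic rank.

    ``entries`` maps taxon name to abundance fraction, ordered by
    descending abundance with alphabetical tie-break.  A degenerate source
    profile (no signal) gives an all-zero entry set with ``degenerate`` set.
    """

    rank: str
    entries: dict[str, float]
    degenerate: bool = False

    def total(self) -> float:
        return float(sum(self.entries.values()))


def _sorted_entries(pairs: Mapping[str, float]) -> dict[str, float]:
    return dict(sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0])))


def aggregate(
    profile: AbundanceProfile, taxonomy: pd.DataFrame, rank: str
) -> RankProfile:
    """Pool genome abundances to ``rank`` by summing shared taxon names."""
    if rank not in RANKS:
        raise RankError(
            f"unknown rank {rank!r}; valid ranks: {', '.join(RANKS)}"
        )
    labels = taxonomy.loc[profile.genome_ids, rank].astype(str).to_numpy()
    sums: dict[str, float] = {}
    for name, a in zip(labels, profile.abundances):
        sums[name] = sums.get(name, 0.0) + float(a)
    return RankProfile(
        rank=rank,
        entries=_sorted_entries(sums),
        degenerate=profile.degenerate,
    )


def euclidean_distance(p: RankProfile, q: RankProfile) -> float:
    """Euclidean distance between two same-rank profiles.

    Taken over the union of taxa, with taxa missing from one profile
    imputed as zero abundance; symmetric, zero iff identical.
    """
    if p.rank != q.rank:
        raise RankError(
            f"cannot compare profiles of different ranks: "
            f"{p.rank!r} vs {q.rank!r}"
        )
    taxa = sorted(set(p.entries) | set(q.entries))
    return sqrt(
        sum(
            (p.entries.get(t, 0.0) - q.entries.get(t, 0.0)) ** 2
            for t in taxa
        )
    )


def _render_rank(profile: RankProfile) -> str:
    lines = ["taxon\tabundance"]
    if profile.degenerate:
        lines.append("unknown\t0.000000")
    else:
        for taxon, a in profile.entries.items():
            lines.append(f"{taxon}\t{a:.6f}")
    return "\n".join(lines) + "\n"


def write_report(
    profiles: Mapping[str, RankProfile], destination: "str | os.PathLike[str]"
) -> list[str]:
    """Write one TSV per rank plus a long-format all-ranks TSV.

    Abundances are printed with 6 decimal places in the deterministic order
    produced by :func:`aggregate`.  Files are written whole from in-memory
    content (content is fully rendered before any file is touched), so a
    rendering failure never leaves partial reports.  Returns the paths
    written.
    """
    destination = os.fspath(destination)
    os.makedirs(destination, exist_ok=True)
    ranks = [r for r in RANKS if r in profiles]
    ranks += [r for r in profiles if r not in RANKS]  # preserve extras
    rendered: dict[str, str] = {}
    long_lines = ["rank\ttaxon\tabundance"]
    for rank in ranks:
        profile = profiles[rank]
        rendered[f"{rank}.tsv"] = _render_rank(profile)
        if profile.degenerate:
            long_lines.append(f"{rank}\tunknown\t0.000000")
        else:
            for taxon, a in profile.entries.items():
                long_lines.append(f"{rank}\t{taxon}\t{a:.6f}")
    rendered["all_ranks.tsv"] = "\n".join(long_lines) + "\n"
    paths = []
    for name, content in rendered.items():
        path = os.path.join(destination, name)
        with open(path, "w") as fh:
            fh.write(content)
        paths.append(path)
    return paths
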