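"""Model/results interface over the profiling pipeline.

`KmerMixtureModel` pairs a reference matrix with one metagenome; `fit()`
runs the regularized NNLS deconvolution and returns a `KmerMixtureResults`
carrying the simplex abundances, the fit residual, rank-level views, a text
summary, and jackknife uncertainty estimates.

    >>> model = KmerMixtureModel(reference, reads=reads)
    >>> res = model.fit()
    >>> res.at_rank("genus")
    >>> res.jackknife(reps=100, seed=7)["genus"].to_frame()
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .jackknife import JackknifeSummary, jackknife_profile
from .kmers import MetagenomeVector, profile_reads
from .reference import RANKS, ReferenceMatrix, load_reference
from .solve import DEFAULT_LAMBDA, AbundanceProfile, fit_profile
from .taxonomy import RankProfile, aggregate

__all__ = ["KmerMixtureModel", "KmerMixtureResults"]


class KmerMixtureModel:
    """Non-negative mixture model of a metagenome over reference genomes.

    The observation is the metagenome's ensemble canonical k-mer frequency
    vector b; the design is the reference matrix A of per-genome k-mer
    signatures; the parameters are relative DNA abundances x ≥ 0, Σx = 1.

    Parameters
    ----------
    reference : ReferenceMatrix
        Column-normalized k-mer signatures with taxonomy.
    reads : path or iterable of str, optional
        The metagenome's reads; parsed and profiled once, and retained
        (as a list) so results can jackknife.  Either ``reads`` or
        ``metagenome`` must be given.
    metagenome : MetagenomeVector, optional
        A pre-computed composition vector (jackknife then unavailable).
    """

    def __init__(
        self,
        reference: ReferenceMatrix,
        reads: "str | os.PathLike[str] | Iterable[str] | None" = None,
        metagenome: MetagenomeVector | None = None,
    ):
        if (reads is None) == (metagenome is None):
            raise ValueError("provide exactly one of reads or metagenome")
        self.reference = reference
        if reads is not None:
            if isinstance(reads, (str, os.PathLike)):
                from .fastx import read_sequences

                reads = read_sequences(reads)
            self.reads: list[str] | None = list(reads)
            metagenome = profile_reads(self.reads, reference.space)
        else:
            self.reads = None
        if metagenome.space != reference.space:
            raise ValueError(
                f"metagenome k={metagenome.space.k} does not match "
                f"reference k={reference.k}"
            )
        self.metagenome = metagenome

    @classmethod
    def from_files(
        cls,
        database: "str | os.PathLike[str]",
        reads: "str | os.PathLike[str]",
        expect_k: int | None = None,
    ) -> "KmerMixtureModel":
        """Build from a saved reference database and a FASTA/FASTQ file."""
        return cls(load_reference(os.fspath(database), expect_k), reads=reads)

    def fit(
        self,
        lam: float = DEFAULT_LAMBDA,
        min_abundance: float = 0.0,
    ) -> "KmerMixtureResults":
        """Fit abundances by Tikhonov-regularized NNLS.

        Parameters
        ----------
        lam : float
            Ridge strength λ; 0 gives plain NNLS.
        min_abundance : float
            Reporting cutoff: entries below it are zeroed and the profile
            renormalized.
        """
        profile = fit_profile(
            self.reference, self.metagenome, lam=lam,
            min_abundance=min_abundance,
        )
        return KmerMixtureResults(self, profile)


class KmerMixtureResults:
    """Fitted abundance profile with rank views and uncertainty."""

    def __init__(self, model: KmerMixtureModel, profile: AbundanceProfile):
        self.model = model
        self.profile = profile

    @property
    def params(self) -> pd.Series:
        """Genome-level abundances as a Series indexed by genome_id."""
        return pd.Series(
            self.profile.abundances,
            index=pd.Index(self.profile.genome_ids, name="genome_id"),
            name="abundance",
        )

    @property
    def residual_norm(self) -> float:
        return self.profile.residual_norm

    @property
    def lambda_used(self) -> float:
        return self.profile.lambda_used

    @property
    def degenerate(self) -> bool:
        return self.profile.degenerate

    def at_rank(self, rank: str) -> pd.Series:
        """Abundances pooled at one rank, sorted descending."""
        rp = aggregate(self.profile, self.model.reference.taxonomy, rank)
        return pd.Series(rp.entries, name="abundance").rename_axis(rank)

    def rank_profiles(
        self, ranks: Sequence[str] = RANKS
    ) -> dict[str, RankProfile]:
        """RankProfile per requested rank (for reports and comparisons)."""
        return {
            rank: aggregate(
                self.profile, self.model.reference.taxonomy, rank
            )
            for rank in ranks
        }

    def jackknife(
        self,
        fraction: float = 0.5,
        reps: int = 1000,
        seed: int = 0,
        ranks: Sequence[str] = RANKS,
    ) -> dict[str, JackknifeSummary]:
        """Delete-half jackknife of the fitted profile (needs stored reads)."""
        if self.model.reads is None:
            raise ValueError(
                "jackknife requires the model to be built from reads"
            )
        return jackknife_profile(
            self.model.reads,
            self.model.reference,
            fraction=fraction,
            reps=reps,
            seed=seed,
            lam=self.profile.lambda_used,
            ranks=ranks,
        )

    def summary(self, rank: str = "genus", top: int = 10) -> str:
        """Plain-text summary of the fit and the top taxa at one rank."""
        mv = self.model.metagenome
        ref = self.model.reference
        lines = [
            "Canonical k-mer NNLS mixture model",
            "=" * 50,
            f"k (word length):        {ref.k}",
            f"m (k-mer classes):      {ref.m}",
            f"n (reference genomes):  {ref.n}",
            f"reads:                  {mv.n_reads}",
            f"k-mer tokens:           {mv.total_kmers}",
            f"lambda (ridge):         {self.lambda_used:g}",
            f"residual ||Ax - b||:    {self.residual_norm:.6g}",
            f"degenerate:             {self.degenerate}",
            "",
            f"Top taxa at rank '{rank}':",
            f"{'taxon':<30}abundance",
            "-" * 50,
        ]
        for taxon, a in self.at_rank(rank).head(top).items():
            lines.append(f"{taxon:<30}{a:.6f}")
        return "\n".join(lines)
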