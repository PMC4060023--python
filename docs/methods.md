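# Methods

## Model

A metagenome is summarized as one *ensemble* composition vector rather than
a collection of individually classified reads. For a word length k, every
window of k consecutive A/C/G/T bases in every read is mapped to its
canonical class — the lexicographically smaller of the k-mer and its
reverse complement — and the class counts, divided by the total number of
k-mer tokens, form the observation **b** ∈ ℝ^m. Canonicalization makes the
profile exactly invariant to the sequenced strand and halves the feature
dimension for odd k: m = 4^k/2 for odd k and (4^k + 4^(k/2))/2 for even k
(8192 at the default k = 7; 2080 at k = 6; 32896 at k = 8).

Each reference genome j (all contigs pooled) is summarized the same way as
a column of the reference matrix **A** ∈ ℝ^(m×n); every column sums to 1.
Abundances solve the non-negative ridge problem

    min_x ½‖Ax − b‖² + ½λ²‖x‖²,  x ≥ 0,

and are then normalized to Σxᵢ = 1. The model therefore assumes (i) the
metagenome's composition is approximately a convex combination of the
reference compositions, (ii) composition is a stable genome signature at
the chosen k, and (iii) abundance is measured in DNA (k-mer) space — no
genome-length correction is applied, so a large genome at equal cell count
receives proportionally more mass.

## Solver

The core solver is a Lawson–Hanson active-set iteration: starting from
x = 0 with all variables active (clamped at zero), it repeatedly moves the
variable with the most positive gradient into the passive set, solves the
unconstrained least-squares problem on the passive columns, and steps back
to the feasible boundary when a passive coefficient would go negative. At
termination the Karush–Kuhn–Tucker conditions hold: the gradient of the
objective vanishes on passive variables and is non-positive
(≤ anti-cycling tolerance) on active ones.

Determinism was a design goal: ties in the entering-variable choice are
broken by lowest column index, the boundary step removes the first index
attaining the minimal step, and the tolerance is fixed at 10·ε·‖A‖₂. Two
identical reference columns therefore always receive identical treatment,
and repeated runs are bit-identical. Rank-deficient passive sets are
handled by the minimum-norm least-squares solution, which splits mass
evenly among exactly collinear columns.

The ridge term is implemented by augmenting A with λ·I rows and b with
zeros, so λ = 0 reduces *exactly* to plain NNLS. The default λ = 10⁻⁴ is
small relative to the unit-sum columns of A: on well-conditioned problems
it perturbs the solution below the sampling noise of realistic read
counts, while for (near-)collinear columns it selects the symmetric,
even-split solution. The reported residual ‖Ax − b‖ is always measured on
the original, unaugmented system.

The simplex constraint is enforced by post-hoc normalization rather than
inside the solver; an all-zero raw solution (a query sharing no k-mer
class with the reference) yields an explicitly flagged degenerate profile
instead of an error. An optional reporting cutoff zeroes abundances below
a threshold and renormalizes — thresholding happens before the final
renormalization.

The test suite certifies the solver two independent ways: against scipy's
reference NNLS, and against a projected-gradient (FISTA) solver run to
KKT convergence, with the optimality conditions additionally checked
directly from the problem data.

## Taxonomy and reports

Eight ranks are used (kingdom, phylum, class, order, family, genus,
species, strain). Aggregation sums genome abundances sharing a taxon name
at the requested rank; missing labels pool into an "unknown" entry, except
strain, which defaults to the genome id so that strain-level aggregation
is the identity map and strain labels stay unique. Aggregation is linear
and conserves mass across ranks. Reports are one TSV per rank plus a
long-format table, abundances at 6 decimals, sorted by descending
abundance with alphabetical tie-break — a fully deterministic byte layout.
Profiles are compared by Euclidean distance over the sorted union of taxa,
with absent taxa imputed as zero (the only convention under which
profiles with different taxa sets are comparable).

## Jackknife

Uncertainty is estimated by delete-half jackknife: each replicate draws
⌊fraction·n_reads⌋ reads uniformly **without replacement** (fraction 0.5,
1000 replicates by default) and recomputes the entire pipeline. Without
replacement is the canonical delete-d jackknife reading of half-sampling;
the reported spread is the **population** (divide-by-reps) standard
deviation. Replicate r draws from the counter-based substream
`default_rng([seed, r])`, so summaries are reproducible for a fixed seed
independent of execution order. Per-read k-mer class indices are extracted
once into a sparse reads×classes matrix, making each replicate a row
subset sum rather than a re-parse. Replicates whose subsample contains no
usable k-mer are excluded and counted; summaries are computed over the
surviving replicates at every rank.

## Synthetic data

The generator emulates a single-end short-read study design: i.i.d. base
sequences at a chosen GC content stand in for genomes, and reads are drawn
by sampling a source genome from the ground-truth proportions, a uniform
start, a uniform strand, and i.i.d. per-base substitutions (uniform over
the three alternatives). Defaults are 5 genomes × 50 kb, proportions
(0.40, 0.25, 0.20, 0.10, 0.05), 500,000 single 100 nt reads, and a flat 1%
substitution rate; the test suite and the acceptance script run the same
design at 100,000 reads, which keeps every check within desk-scale compute
while leaving multinomial sampling error well below the tolerances being
verified. Because reads have constant length and substitutions never
create ambiguous bases, each read contributes the same number of k-mer
tokens and the k-mer-space ground truth equals the realized per-genome
read fractions in the truth table.

What the simulator deliberately does **not** model: real genomes'
repeat structure and shared ancestry (i.i.d. genomes are nearly orthogonal
in k-mer space, so synthetic mixtures are better conditioned than real
communities of related strains), platform-specific error spectra and
quality profiles, indels, coverage bias, and paired ends. Passing the
recovery tests therefore demonstrates correctness of the pipeline and
robustness to uniform substitution noise — not profiling accuracy on
communities of closely related organisms, which is governed by the
conditioning of the real reference matrix. The ablation fixture (a decoy
sharing 95% of the target's sequence) probes exactly that regime in
miniature: with the true species removed, the profiler concentrates mass
on the most compositionally similar remaining genome.

## Numerical and design choices

- Ambiguous bases (N, IUPAC codes, U) invalidate only the k-windows that
  touch them, never the whole read; reads shorter than k contribute
  nothing. Counting is case-insensitive; FASTQ qualities are ignored.
- Streamed counting concatenates reads with a separator byte that
  automatically voids boundary-crossing windows, so batch boundaries can
  never create phantom k-mers.
- The canonical index uses a dense 4^k lookup table; k is limited to ≤ 13
  (beyond that the table and the m-dimensional vectors are infeasible in
  ordinary memory). The command line restricts k to 6–8.
- Reference serialization is a versioned little-endian container (magic,
  version, k, m, n, UTF-8 taxonomy block, row-major float64 matrix) with
  bit-exact round-trip and no timestamp, so identical inputs always
  produce byte-identical databases.
- Zero-information inputs are errors where silence would corrupt results
  (a reference genome with no usable k-mer, an emptied reference after
  ablation) and flagged degenerate where the query is at fault (empty read
  set, no shared composition).
- The library does not forbid n > m (more genomes than k-mer classes);
  the active-set solver remains KKT-optimal, though the optimum may be
  non-unique there.

## Limitations

Profiles are only as complete as the reference: organisms absent from the
database are absorbed by their closest compositional relatives. Abundances
are DNA proportions, not cell proportions. Very short or low-complexity
queries can be degenerate or dominated by regularization. The jackknife
captures read-sampling variability only — not reference or model error.
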