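# kmerdecon

Alignment-free taxonomic profiling of shotgun metagenomes by non-negative
least-squares deconvolution of canonical k-mer frequencies.

## The problem and the model

Shotgun sequencing of a microbial community produces millions of unannotated
reads; the first question is *which organisms are present, and at what
relative abundance*. Read-by-read classification (mapping or marker-gene
search) scales with the number of reads. `kmerdecon` instead treats the
**entire metagenome as one composition**: a single frequency vector over
canonical k-mer classes (a k-mer and its reverse complement are the same
feature), computed jointly from all reads, and models it as a non-negative
mixture of reference genome signatures.

Let **A** ∈ ℝ^(m×n) be the reference matrix whose column *j* is the
column-normalized canonical k-mer frequency vector of reference genome *j*
(m = 8192 classes at the default k = 7; k = 6–8 supported on the command
line), and let **b** ∈ ℝ^m be the metagenome's own normalized k-mer vector.
Abundances **x** solve

    min_x  ½‖Ax − b‖²  +  ½λ²‖x‖²,   subject to x ≥ 0,

by a Lawson–Hanson active-set method satisfying the Karush–Kuhn–Tucker
conditions; the Tikhonov (ridge) term λ²‖x‖² (default λ = 10⁻⁴,
implemented by augmenting A with λ·I) stabilizes the split among reference
genomes with near-identical composition. The solution is normalized to the
probability simplex (Σxᵢ = 1), so abundances are relative DNA proportions,
uncorrected for genome length. Genome-level abundances are then pooled at
every taxonomic rank (kingdom … strain), and uncertainty is estimated by a
delete-half jackknife: half the reads are resampled (default 1000×), the
profile recomputed each time, and the per-taxon mean and standard deviation
reported.

The package is aimed at microbiome researchers who need fast, scalable
profiles against a custom reference collection, and ships a synthetic
community generator so every stage is testable with known ground truth.

## Worked example

Simulate a three-genome community (60/30/10 mixture, 20,000 reads of
100 nt at a 1% error rate), build a reference, and profile the reads:

```bash
kmerdecon simulate --n-genomes 3 --genome-length 20000 \
    --proportions 0.6,0.3,0.1 --n-reads 20000 --read-length 100 \
    --error-rate 0.01 --seed 42 -o sim
kmerdecon build sim/genomes.tsv --taxonomy sim/taxonomy.tsv -k 7 -o ref.db
kmerdecon profile sim/reads.fastq -d ref.db -o report
cat report/genus.tsv
```

```
taxon	abundance
genus1	0.579190
genus2	0.307326
genus3	0.113484
```

The estimated genus abundances recover the simulated 0.6/0.3/0.1 mixture to
about two percentage points despite sequencing errors. The jackknife
quantifies how stable those numbers are under read resampling:

```bash
kmerdecon jackknife sim/reads.fastq -d ref.db --reps 100 --seed 7 -o jk.tsv
```

```
rank	taxon	mean	sd
genus	genus1	0.578807	0.003356
genus	genus2	0.307357	0.003001
genus	genus3	0.113835	0.002507
```

Small standard deviations (≈0.003) indicate the profile is robust to which
half of the reads is used. The same analysis from Python:

```python
from kmerdecon import KmerMixtureModel

model = KmerMixtureModel.from_files("ref.db", "sim/reads.fastq")
res = model.fit()
print(res.summary(rank="genus"))
```

```
Canonical k-mer NNLS mixture model
==================================================
k (word length):        7
m (k-mer classes):      8192
n (reference genomes):  3
reads:                  20000
k-mer tokens:           1880000
lambda (ridge):         0.0001
residual ||Ax - b||:    0.000834996
degenerate:             False

Top taxa at rank 'genus':
taxon                         abundance
--------------------------------------------------
genus1                        0.579190
genus2                        0.307326
genus3                        0.113484
```

`res.params` holds the genome-level abundances, `res.at_rank(rank)` the
pooled view at any rank, and `res.jackknife(...)` the resampling summaries.
`kmerdecon distance a.tsv b.tsv --rank genus` computes the Euclidean
distance between two report files (union of taxa, absent taxa counted as
zero), the standard way to compare profiles between runs or tools.

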