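"""Canonical k-mer space, counting, and ensemble profiling."""

import gzip
import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kmerdecon import (
    KmerSpace,
    canonical_index,
    count_sequence,
    profile_reads,
    revcomp,
)
from kmerdecon.fastx import read_jellyfish_dump
from kmerdecon.kmers import iter_count_reads

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)
read_sets = st.lists(dna, min_size=0, max_size=12)


def brute_force_dimension(k: int) -> int:
    """Count canonical classes by enumerating every k-mer string."""
    seen = set()
    for tup in itertools.product("ACGT", repeat=k):
        kmer = "".join(tup)
        seen.add(min(kmer, revcomp(kmer)))
    return len(seen)


class TestKmerSpace:
    @pytest.mark.parametrize(
        "k,m", [(6, 2080), (7, 8192), (8, 32896)]
    )
    def test_dimension_closed_form(self, k, m):
        assert KmerSpace(k).m == m

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_dimension_matches_enumeration(self, k):
        space = KmerSpace(k)
        expected = (4**k + 4 ** (k // 2)) // 2 if k % 2 == 0 else 4**k // 2
        assert space.m == brute_force_dimension(k) == expected

    def test_rejects_bad_k(self):
        with pytest.raises(ValueError):
            KmerSpace(0)
        with pytest.raises(ValueError):
            KmerSpace(14)

    def test_index_is_lexicographic_over_canonicals(self):
        space = KmerSpace(3)
        reps = [space.kmer_at(i) for i in range(space.m)]
        assert reps == sorted(reps)
        assert all(r <= revcomp(r) for r in reps)


class TestCanonicalIndex:
    def test_known_classes(self, space7):
        assert canonical_index("AAAAAAA", space7) == 0
        assert canonical_index("TTTTTTT", space7) == 0
        assert canonical_index("aaaaaaa", space7) == 0  # case-insensitive

    def test_ambiguous_base_is_miss(self, space7):
        assert canonical_index("AANAAAA", space7) is None
        assert canonical_index("AAUAAAA", space7) is None  # DNA only

    def test_length_mismatch_raises(self, space7):
        with pytest.raises(ValueError, match="length"):
            canonical_index("ACGT", space7)

    def test_palindrome_maps_to_itself(self):
        space = KmerSpace(4)
        assert revcomp("ACGT") == "ACGT"
        assert canonical_index("ACGT", space) == canonical_index(
            revcomp("ACGT"), space
        )

    @given(st.text(alphabet="ACGT", min_size=5, max_size=5))
    def test_strand_classes_coincide(self, kmer):
        space = KmerSpace(5)
        assert canonical_index(kmer, space) == canonical_index(
            revcomp(kmer), space
        )


class TestCountSequence:
    def test_overlapping_windows_one_class(self, space7):
        counts = np.zeros(space7.m, dtype=np.int64)
        count_sequence("AAAAAAAA", space7, counts)
        assert counts[0] == 2
        assert counts.sum() == 2

    def test_short_sequence_contributes_nothing(self, space7):
        counts = np.zeros(space7.m, dtype=np.int64)
        count_sequence("ACGTAC", space7, counts)
        assert counts.sum() == 0

    def test_total_windows(self, space7):
        rng = np.random.default_rng(7)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        counts = np.zeros(space7.m, dtype=np.int64)
        count_sequence(seq, space7, counts)
        assert counts.sum() == 300 - 6

    def test_ambiguous_base_voids_only_touching_windows(self, space7):
        # an N at position 10 of a 30-mer kills exactly the 7 windows
        # covering it
        rng = np.random.default_rng(8)
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 30)))
        seq[10] = "N"
        counts = np.zeros(space7.m, dtype=np.int64)
        count_sequence("".join(seq), space7, counts)
        assert counts.sum() == (30 - 6) - 7

    def test_shape_mismatch_raises(self, space7):
        with pytest.raises(ValueError, match="shape"):
            count_sequence("AAAAAAA", space7, np.zeros(3, dtype=np.int64))


class TestProfileReads:
    def test_single_read_unit_mass(self, space7):
        vec = profile_reads(["AAAAAAA"], space7)
        assert vec.frequencies[0] == 1.0
        assert vec.frequencies.sum() == 1.0
        assert vec.total_kmers == 1 and vec.n_reads == 1

    def test_strand_symmetric_pair_identical(self, space7):
        a = profile_reads(["AAAAAAA"], space7)
        b = profile_reads(["AAAAAAA", "TTTTTTT"], space7)
        assert np.array_equal(a.frequencies, b.frequencies)

    @given(read_sets)
    def test_reverse_complement_invariance(self, reads):
        space = KmerSpace(5)
        fwd = profile_reads(reads, space) if any(
            len(r) >= 5 for r in reads
        ) else None
        if fwd is None:
            return
        rev = profile_reads([revcomp(r) for r in reads], space)
        assert np.array_equal(fwd.frequencies, rev.frequencies)

    @given(read_sets)
    def test_order_invariance(self, reads):
        space = KmerSpace(5)
        c1, t1, _ = iter_count_reads(reads, space)
        c2, t2, _ = iter_count_reads(list(reversed(reads)), space)
        assert t1 == t2
        assert np.array_equal(c1, c2)

    @given(read_sets, read_sets)
    def test_count_concatenation(self, r1, r2):
        space = KmerSpace(5)
        c1, t1, _ = iter_count_reads(r1, space)
        c2, t2, _ = iter_count_reads(r2, space)
        c12, t12, _ = iter_count_reads(r1 + r2, space)
        assert t12 == t1 + t2
        assert np.array_equal(c12, c1 + c2)

    def test_empty_input_degenerate_with_warning(self, space7):
        with pytest.warns(UserWarning, match="no usable k-mers"):
            vec = profile_reads(["ACG", "NNNNNNNN"], space7)
        assert vec.is_degenerate
        assert vec.frequencies.sum() == 0.0

    def test_read_sample_approximates_genome_profile(self, space7):
        """10k error-free reads reproduce the source genome's composition."""
        from kmerdecon.simulate import SimulationSpec, generate_genomes, \
            generate_reads

        spec = SimulationSpec(
            n_genomes=1, genome_length=20_000, proportions=(1.0,),
            n_reads=10_000, read_length=100, error_rate=0.0, seed=11,
        )
        genome = generate_genomes(spec)[0]
        reads, _ = generate_reads(spec, [genome])
        from_reads = profile_reads(reads, space7)
        from_genome = profile_reads([genome], space7)
        dist = np.linalg.norm(
            from_reads.frequencies - from_genome.frequencies
        )
        assert dist < 0.01


class TestFastxInput:
    def test_fasta_fastq_gzip_all_agree(self, tmp_path, space7):
        reads = ["ACGTACGTACGT", "TTTTTTTTT", "GGGGCCCCAAAA"]
        fa = tmp_path / "r.fasta"
        fa.write_text(
            "".join(f">r{i}\n{s[:6]}\n{s[6:]}\n" for i, s in enumerate(reads))
        )
        fq = tmp_path / "r.fastq"
        fq.write_text(
            "".join(
                f"@r{i}\n{s}\n+\n{'I' * len(s)}\n"
                for i, s in enumerate(reads)
            )
        )
        fqgz = tmp_path / "r.fastq.gz"
        with gzip.open(fqgz, "wt") as fh:
            fh.write(fq.read_text())
        ref = profile_reads(reads, space7)
        for path in (fa, fq, fqgz):
            got = profile_reads(str(path), space7)
            assert np.array_equal(got.frequencies, ref.frequencies)
            assert got.n_reads == 3

    def test_unknown_format_rejected(self, tmp_path, space7):
        from kmerdecon.errors import FastxFormatError

        bad = tmp_path / "bad.txt"
        bad.write_text("ACGTACGT\n")
        with pytest.raises(FastxFormatError, match="format"):
            profile_reads(str(bad), space7)

    def test_malformed_fastq_names_record(self, tmp_path, space7):
        from kmerdecon.errors import FastxFormatError

        fq = tmp_path / "trunc.fastq"
        fq.write_text("@r1\nACGTACGT\n+\nIIIIIIII\n@r2\nACGT\n+\nII\n")
        with pytest.raises(FastxFormatError, match="record 2"):
            profile_reads(str(fq), space7)

    def test_jellyfish_dump_adapter(self, tmp_path, space7):
        # dump with a k-mer and its reverse complement: same class
        dump = tmp_path / "dump.txt"
        dump.write_text("AAAAAAA 3\nTTTTTTT 2\nACGTACG 5\n")
        counts = read_jellyfish_dump(dump, space7)
        assert counts[0] == 5
        acg = canonical_index("ACGTACG", space7)
        assert counts[acg] == 5
        assert counts.sum() == 10
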