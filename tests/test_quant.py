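import numpy as np
import pytest

from crossclean import (
    ReadSet,
    SampleAssembly,
    SuspectTable,
    build_kmer_index,
    build_metatranscriptome,
    compute_tpm,
    find_suspects,
    quantify_all,
)
from crossclean._kmers import revcomp
from crossclean.errors import ConfigurationError, ConsistencyError
from crossclean.quant import assign_reads
from crossclean.simulate import AbundanceProfile, simulate_reads

from .conftest import random_dna


def _meta(*samples):
    return build_metatranscriptome(
        [SampleAssembly.from_records(sid, recs) for sid, recs in samples]
    )


class TestKmerIndex:
    def test_single_31nt_transcript_single_kmer(self, rng):
        seq = random_dna(rng, 31)
        meta = _meta(("A", [("t", seq)]), ("B", [("u", random_dna(rng, 31))]))
        idx = build_kmer_index(meta, k=31)
        assert len(idx) == 2  # one canonical k-mer per entry

    def test_revcomp_entries_share_canonical_kmers(self):
        meta = _meta(("A", [("t", "A" * 35)]), ("B", [("u", "T" * 35)]))
        idx = build_kmer_index(meta, k=31)
        assert len(idx) == 1
        assert set(idx.entries_of(int(idx.kmers[0]))) == {0, 1}

    @pytest.mark.parametrize(
        "n_pos,expected",
        [(10, 0), (35, 5)],  # N-free windows of a 40-nt sequence, k=31
    )
    def test_n_windows_excluded(self, rng, n_pos, expected):
        seq = list(random_dna(rng, 40))
        seq[n_pos] = "N"
        seq = "".join(seq)
        # enumerate: window starts s in [0, 9]; valid iff N outside [s, s+31)
        n_free = sum(1 for s in range(10) if not (s <= n_pos < s + 31))
        assert n_free == expected
        meta = _meta(("A", [("t", seq)]), ("B", [("u", "ACGT" * 10)]))
        idx = build_kmer_index(meta, k=31)
        from crossclean._kmers import canonical_kmers, encode

        canon, valid = canonical_kmers(encode(seq), 31)
        assert int(valid.sum()) == expected

    def test_even_k_rejected(self, rng):
        meta = _meta(("A", [("t", random_dna(rng, 40))]), ("B", [("u", random_dna(rng, 40))]))
        with pytest.raises(ConfigurationError):
            build_kmer_index(meta, k=30)


class TestAssignReads:
    def _setup(self, rng):
        s1 = random_dna(rng, 200)
        s2 = random_dna(rng, 200)
        meta = _meta(("A", [("t1", s1)]), ("B", [("t2", s2)]))
        return s1, s2, meta, build_kmer_index(meta, k=31)

    def test_unique_read_full_count(self, rng):
        s1, _s2, _meta, idx = self._setup(rng)
        reads = ReadSet.in_memory("A", [(s1[50:150],)])
        counts, stats = assign_reads(reads, idx)
        assert counts.tolist() == [1.0, 0.0]
        assert stats.n_assigned == 1

    def test_tie_between_identical_entries_split_equally(self, rng):
        seq = random_dna(rng, 200)
        meta = _meta(("A", [("t1", seq)]), ("B", [("t2", seq)]))
        idx = build_kmer_index(meta, k=31)
        counts, _ = assign_reads(ReadSet.in_memory("A", [(seq[20:120],)]), idx)
        assert counts.tolist() == [0.5, 0.5]

    def test_unmatched_read_unmapped(self, rng):
        _s1, _s2, _meta, idx = self._setup(rng)
        counts, stats = assign_reads(ReadSet.in_memory("A", [(random_dna(rng, 100),)]), idx)
        assert counts.sum() == 0.0
        assert stats.n_unmapped == 1

    def test_paired_kmers_pooled(self, rng):
        s1, _s2, _meta, idx = self._setup(rng)
        unit = (s1[:100], revcomp(s1[100:200]))
        counts, _ = assign_reads(ReadSet.in_memory("A", [unit]), idx)
        assert counts.tolist() == [1.0, 0.0]

    def test_doubling_reads_leaves_tpm_unchanged(self, rng):
        s1, s2, meta, idx = self._setup(rng)
        units = [(s1[10:110],), (s1[60:160],), (s2[5:105],)]
        c1, _ = assign_reads(ReadSet.in_memory("A", units), idx)
        c2, _ = assign_reads(ReadSet.in_memory("A", units * 2), idx)
        t1 = compute_tpm(c1, meta.lengths)
        t2 = compute_tpm(c2, meta.lengths)
        np.testing.assert_allclose(t1, t2, rtol=1e-12)


class TestComputeTpm:
    def test_length_normalisation(self):
        tpm = compute_tpm(np.array([10.0, 10.0]), np.array([1000, 2000]))
        np.testing.assert_allclose(tpm, [666666.6667, 333333.3333], atol=0.05)

    def test_single_transcript_is_one_million(self):
        assert compute_tpm(np.array([3.0]), np.array([500]))[0] == 1e6

    def test_all_zero_counts(self):
        assert compute_tpm(np.zeros(4), np.full(4, 100)).tolist() == [0.0] * 4

    def test_conservation(self, rng):
        counts = rng.random(50) * 100
        lengths = rng.integers(200, 3000, 50)
        assert compute_tpm(counts, lengths).sum() == pytest.approx(1e6, rel=1e-9)

    def test_identical_entries_equal_tpm(self, rng):
        seq = random_dna(rng, 300)
        meta = _meta(("A", [("t1", seq)]), ("B", [("t2", seq)]))
        idx = build_kmer_index(meta, k=31)
        units = [(seq[i : i + 100],) for i in range(0, 200, 10)]
        counts, _ = assign_reads(ReadSet.in_memory("A", units), idx)
        tpm = compute_tpm(counts, meta.lengths)
        assert tpm[0] == pytest.approx(tpm[1])

    def test_negative_count_rejected(self):
        with pytest.raises(ConsistencyError):
            compute_tpm(np.array([-1.0]), np.array([100]))


class TestQuantifyAll:
    def test_focal_positive_alien_zero(self, rng):
        seq = random_dna(rng, 300)
        a = SampleAssembly.from_records("A", [("t", seq)])
        b = SampleAssembly.from_records("B", [("t", seq)])
        suspects = find_suspects([a, b])
        reads = {
            "A": ReadSet.in_memory("A", [(seq[i : i + 100],) for i in range(0, 150, 15)]),
            "B": ReadSet.in_memory("B", []),
        }
        m = quantify_all([a, b], reads, suspects)
        assert m.values.at["A::t", "A"] > 0
        assert m.values.at["A::t", "B"] == 0.0

    def test_symmetry_under_sample_relabelling(self, rng):
        seqs = [random_dna(rng, 250) for _ in range(3)]
        units = [(s[40:140],) for s in seqs for _ in range(3)]
        a = SampleAssembly.from_records("A", [(f"t{i}", s) for i, s in enumerate(seqs)])
        b = SampleAssembly.from_records("B", [(f"t{i}", s) for i, s in enumerate(seqs)])
        suspects = find_suspects([a, b])
        reads = {
            "A": ReadSet.in_memory("A", units),
            "B": ReadSet.in_memory("B", units),
        }
        m = quantify_all([a, b], reads, suspects)
        for i in range(3):
            assert m.values.at[f"A::t{i}", "A"] == pytest.approx(
                m.values.at[f"B::t{i}", "B"]
            )
            assert m.values.at[f"A::t{i}", "B"] == pytest.approx(
                m.values.at[f"B::t{i}", "A"]
            )

    def test_full_column_sums_to_one_million(self, rng):
        seqs = [random_dna(rng, 400) for _ in range(4)]
        a = SampleAssembly.from_records("A", [(f"t{i}", s) for i, s in enumerate(seqs[:2])])
        b = SampleAssembly.from_records("B", [(f"t{i}", s) for i, s in enumerate(seqs[2:])])
        suspects = find_suspects([a, b])
        reads = {
            "A": ReadSet.in_memory("A", [(seqs[0][10:110],), (seqs[1][20:120],)]),
            "B": ReadSet.in_memory("B", [(seqs[2][30:130],)]),
        }
        m = quantify_all([a, b], reads, suspects)
        for col in ("A", "B"):
            assert m.full_tpm[col].sum() == pytest.approx(1e6, rel=1e-6)

    def test_missing_readset_rejected(self, rng):
        a = SampleAssembly.from_records("A", [("t", random_dna(rng, 100))])
        b = SampleAssembly.from_records("B", [("t", random_dna(rng, 100))])
        with pytest.raises(ConfigurationError):
            quantify_all([a, b], {"A": ReadSet.in_memory("A", [])}, SuspectTable())

    def test_abundance_ratio_recovered(self):
        """A transcript at 10 copies/million in A and 1000 in B shows the
        ~100x focal/alien TPM ratio after quantification of simulated reads."""
        g = np.random.default_rng(5)
        shared = random_dna(g, 1000)
        fillers_a = [random_dna(g, 1000) for _ in range(5)]
        fillers_b = [random_dna(g, 1000) for _ in range(5)]
        a = SampleAssembly.from_records(
            "A", [("shared", shared)] + [(f"fa{i}", s) for i, s in enumerate(fillers_a)]
        )
        b = SampleAssembly.from_records(
            "B", [("shared", shared)] + [(f"fb{i}", s) for i, s in enumerate(fillers_b)]
        )
        prof_a = AbundanceProfile(np.array([10.0] + [199998.0] * 5)).normalised()
        prof_b = AbundanceProfile(np.array([1000.0] + [199800.0] * 5)).normalised()
        reads = {
            "A": simulate_reads(a, prof_a, n_reads=100_000, seed=1),
            "B": simulate_reads(b, prof_b, n_reads=100_000, seed=2),
        }
        suspects = find_suspects([a, b])
        m = quantify_all([a, b], reads, suspects)
        nf = m.values.at["A::shared", "A"]
        na = m.values.at["A::shared", "B"]
        assert na / nf == pytest.approx(100.0, rel=0.45)
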