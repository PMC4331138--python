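import numpy as np
import pytest

from kmerq.fastq_io import Read
from kmerq.kmer_quality import (
    background_probs,
    background_word_prob,
    base_frequencies,
    build_profile,
    count_kmers,
    default_fallback,
    estimate_awp,
    estimate_aqp,
    index_to_word,
    pool_reverse_complement,
    quality_counts,
    substitution_credits,
    word_correct_prob,
    word_to_index,
)

from conftest import random_read
from oracles import oracle_counts, oracle_qcounts

Q40 = 40
PERFECT = 400  # 1 - 10^-40 == 1.0 exactly in double precision


def _read(seq, quals=None, rid="r"):
    if quals is None:
        quals = np.full(len(seq), Q40)
    elif np.isscalar(quals):
        quals = np.full(len(seq), quals)
    return Read(id=rid, sequence=seq, qualities=np.asarray(quals))


class TestCounting:
    def test_overlapping_occurrences(self):
        counts = count_kmers(_read("AAA"), 2)
        assert counts[word_to_index("AA")] == 2
        assert counts.sum() == 2

    def test_each_base_once(self):
        counts = count_kmers(_read("ACGT"), 1)
        assert counts.tolist() == [1, 1, 1, 1]

    def test_n_windows_skipped(self):
        counts = count_kmers(_read("ACNGT"), 2)
        # windows AC, CN, NG, GT -> only AC and GT valid
        assert counts.sum() == 2
        assert counts[word_to_index("AC")] == 1
        assert counts[word_to_index("GT")] == 1

    def test_k_longer_than_read_gives_empty_profile(self):
        assert count_kmers(_read("ACG"), 5).sum() == 0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_window_scan_oracle(self, rng, k):
        for i in range(25):
            read = random_read(rng, length=int(rng.integers(20, 220)), rid=f"r{i}", with_n=(i % 3 == 0))
            counts = count_kmers(read, k)
            expect = oracle_counts(read.sequence, k)
            got = {index_to_word(int(w), k): int(c) for w, c in enumerate(counts) if c}
            assert got == expect

    def test_word_index_round_trip(self):
        for w in ("A", "TGCA", "GGTACC"):
            assert index_to_word(word_to_index(w), len(w)) == w


class TestWordCorrectProb:
    def test_product_of_base_probs(self):
        read = _read("AC", [30, 30])
        assert word_correct_prob(read, 0, 2) == pytest.approx(0.999 ** 2, rel=1e-12)

    def test_zero_quality_base_zeroes_window(self):
        read = _read("ACG", [40, 0, 40])
        assert word_correct_prob(read, 0, 3) == 0.0

    def test_single_uncertain_base_dominates(self):
        # TGACCA with one base at 70% accuracy, the rest certain
        read = Read(id="r", sequence="TGACCA", qualities=np.array([PERFECT, PERFECT, 5, PERFECT, PERFECT, PERFECT]))
        p3 = 1 - 10 ** (-5 / 10)
        assert word_correct_prob(read, 0, 6) == pytest.approx(p3, rel=1e-12)

    def test_out_of_range_window_rejected(self):
        with pytest.raises(ValueError):
            word_correct_prob(_read("ACGT"), 3, 2)


class TestQualityCounts:
    def test_perfect_quality_equals_counts_exactly(self, rng):
        for i in range(10):
            read = random_read(rng, length=50, rid=f"r{i}")
            read.qualities[:] = PERFECT
            for k in (1, 2, 3):
                assert np.array_equal(quality_counts(read, k), count_kmers(read, k).astype(float))

    def test_sum_bounded_by_valid_windows(self, rng):
        for i in range(10):
            read = random_read(rng, length=80, rid=f"r{i}", with_n=True)
            for k in (2, 3):
                qc = quality_counts(read, k)
                assert qc.sum() <= count_kmers(read, k).sum() + 1e-12
                assert np.all(qc <= count_kmers(read, k) + 1e-12)

    def test_worked_redistribution_example(self):
        """Called base at 70% with read frequencies A=.2 C=.3 G=.3 T=.2:
        the missing 30% splits 11.25 / 11.25 / 7.5 over C, G, T."""
        credits = substitution_credits([1, 1, 0.7, 1, 1, 1], np.array([0.2, 0.3, 0.3, 0.2]), "TGACCA")
        assert credits["TGACCA"] == pytest.approx(0.7, abs=1e-15)
        assert credits["TGCCCA"] == pytest.approx(0.1125, abs=1e-15)
        assert credits["TGGCCA"] == pytest.approx(0.1125, abs=1e-15)
        assert credits["TGTCCA"] == pytest.approx(0.075, abs=1e-15)

    def test_redistributed_mass_bounded_per_occurrence(self):
        credits = substitution_credits([0.9, 0.8, 0.7], np.array([0.25, 0.25, 0.25, 0.25]), "ACG")
        neighbours = sum(v for w, v in credits.items() if w != "ACG")
        # each position credits (1 - p_j) * prod(others) <= 1 - prod(all)
        assert credits["ACG"] + neighbours <= 1.0 + (1.0 - credits["ACG"]) + 1e-12
        assert all(v >= 0 for v in credits.values())

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_redistribution_matches_brute_force_oracle(self, rng, k):
        for i in range(15):
            read = random_read(rng, length=int(rng.integers(15, 60)), rid=f"r{i}")
            qc = quality_counts(read, k, redistribute=True)
            expect = oracle_qcounts(read.sequence, read.qualities, k, redistribute=True)
            got = {index_to_word(int(w), k): v for w, v in enumerate(qc) if v > 0}
            assert set(got) == set(w for w, v in expect.items() if v > 0)
            for w, v in expect.items():
                assert got.get(w, 0.0) == pytest.approx(v, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_plain_quality_counts_match_oracle(self, rng, k):
        for i in range(15):
            read = random_read(rng, length=int(rng.integers(15, 60)), rid=f"r{i}", with_n=True)
            qc = quality_counts(read, k)
            expect = oracle_qcounts(read.sequence, read.qualities, k)
            for w, v in expect.items():
                assert qc[word_to_index(w)] == pytest.approx(v, rel=1e-9, abs=1e-12)


class TestBackground:
    def test_uniform_freqs(self):
        p = background_probs(np.full(4, 0.25), 2)
        assert np.allclose(p, 1 / 16)

    def test_degenerate_freqs(self):
        freqs = np.array([1.0, 0, 0, 0])
        assert background_word_prob(freqs, "AA") == 1.0
        assert background_word_prob(freqs, "AC") == 0.0

    def test_hand_product(self):
        freqs = np.array([0.2, 0.3, 0.3, 0.2])
        assert background_word_prob(freqs, "TGA") == pytest.approx(0.2 * 0.3 * 0.2, rel=1e-12)

    def test_vector_agrees_with_scalar(self):
        freqs = np.array([0.1, 0.2, 0.3, 0.4])
        vec = background_probs(freqs, 3)
        for idx in (0, 17, 63):
            assert vec[idx] == pytest.approx(background_word_prob(freqs, index_to_word(idx, 3)), rel=1e-12)

    def test_base_frequencies_ignore_n(self):
        freqs = base_frequencies("AANNCC")
        assert freqs.tolist() == [0.5, 0.5, 0.0, 0.0]


class TestEstimators:
    def test_awp_single_occurrence(self):
        read = Read(id="r", sequence="AC", qualities=np.array([10, PERFECT]))
        prof = build_profile(read, 2)
        e = estimate_awp([prof])
        assert e.values[word_to_index("AC")] == pytest.approx(0.9, rel=1e-12)

    def test_awp_averages_occurrences(self):
        # two occurrences of the same word with P=0.8 and P=0.6 -> 0.7
        q8 = -10 * np.log10(1 - 0.8)
        q6 = -10 * np.log10(1 - 0.6)
        r1 = Read(id="a", sequence="AC", qualities=np.array([round(q8 * 10), PERFECT]))
        r2 = Read(id="b", sequence="AC", qualities=np.array([round(q6 * 10), PERFECT]))
        # use exact probabilities by overriding qcounts via fractional-quality reads:
        # phred integers can't hit 0.8/0.6 exactly, so construct profiles directly
        p1 = build_profile(r1, 2)
        p2 = build_profile(r2, 2)
        p1.qcounts[word_to_index("AC")] = 0.8
        p2.qcounts[word_to_index("AC")] = 0.6
        e = estimate_awp([p1, p2])
        assert e.values[word_to_index("AC")] == pytest.approx(0.7, rel=1e-12)

    def test_awp_perfect_data_is_one(self, rng):
        profs = []
        for i in range(5):
            read = random_read(rng, length=40, rid=f"r{i}")
            read.qualities[:] = PERFECT
            profs.append(build_profile(read, 2))
        e = estimate_awp(profs)
        seen = ~np.isnan(e.values)
        assert np.all(e.values[seen] == 1.0)

    def test_awp_values_in_unit_interval(self, random_reads):
        profs = [build_profile(r, 2) for r in random_reads]
        e = estimate_awp(profs)
        vals = e.resolved()
        assert np.all((vals >= 0) & (vals <= 1))

    def test_aqp_constant_quality(self, rng):
        reads = [random_read(rng, length=30, rid=f"r{i}") for i in range(4)]
        for r in reads:
            r.qualities[:] = 30
        e = estimate_aqp(reads, 2)
        seen = ~np.isnan(e.values)
        assert np.allclose(e.values[seen], 0.999 ** 2, rtol=1e-12)

    def test_aqp_averages_per_position_qualities(self):
        r1 = Read(id="a", sequence="AC", qualities=np.array([20, 40]))
        r2 = Read(id="b", sequence="AC", qualities=np.array([40, 20]))
        e = estimate_aqp([r1, r2], 2)
        # Qbar = (30, 30) -> (1 - 1e-3)^2
        assert e.values[word_to_index("AC")] == pytest.approx(0.999 ** 2, rel=1e-12)

    def test_unobserved_word_gets_fallback(self):
        r = Read(id="a", sequence="AAAA", qualities=np.array([30, 30, 30, 30]))
        e = estimate_aqp([r], 2)
        resolved = e.resolved()
        assert np.isnan(e.values[word_to_index("CC")])
        assert resolved[word_to_index("CC")] == pytest.approx(e.fallback)
        assert e.fallback == pytest.approx(0.999 ** 2, rel=1e-12)

    def test_default_fallback_is_mean_correctness_to_the_k(self):
        r = Read(id="a", sequence="ACGT", qualities=np.array([10, 10, 10, 10]))
        assert default_fallback([r], 3) == pytest.approx(0.9 ** 3, rel=1e-12)

    def test_empty_collections_rejected(self):
        with pytest.raises(ValueError):
            estimate_awp([])
        with pytest.raises(ValueError):
            estimate_aqp([], 2)


def test_profiles_tsv_export_lists_nonzero_words():
    import io

    from kmerq.kmer_quality import profiles_to_tsv

    read = _read("AAAC", 30)
    prof = build_profile(read, 2)
    buf = io.StringIO()
    profiles_to_tsv([prof], buf)
    lines = buf.getvalue().strip().split("\n")
    assert lines[0] == "read_id\tword\tcount\tqcount"
    words = {line.split("\t")[1] for line in lines[1:]}
    assert words == {"AA", "AC"}
    aa = next(line for line in lines[1:] if "\tAA\t" in line)
    assert aa.split("\t")[2] == "2"


class TestReverseComplement:
    def test_pooling_moves_mass_to_canonical_word(self):
        read = _read("ACGT")
        prof = build_profile(read, 2, revcomp=True)
        # GT pools into its reverse complement AC; CG and GC are distinct words
        assert prof.counts[word_to_index("AC")] == 2
        assert prof.counts[word_to_index("GT")] == 0

    def test_palindrome_not_double_counted(self):
        v = np.zeros(16)
        v[word_to_index("AT")] = 3.0  # AT is its own reverse complement
        pooled = pool_reverse_complement(v, 2)
        assert pooled[word_to_index("AT")] == 3.0
        assert pooled.sum() == 3.0
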