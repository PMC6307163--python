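"""Natural-vector features, with brute-force and loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nvbarcode import (
    SequenceRecord,
    ablated_vector, brute_force_cov, count_mean_var, cov_pair, featurize,
    kmer_vector, natural_vector12, natural_vector18, positions_of,
    subset_avg_cov,
)
from nvbarcode.natvec import NV18_COLUMNS, NaturalVectorEncoder

from conftest import random_dna


def loop_moments(seq, k):
    """Independent one-line-loop oracle for (n_k, mu_k, D2_k)."""
    pos = [i for i, c in enumerate(seq, 1) if c == k]
    n = len(pos)
    if n == 0:
        return 0, 0.0, 0.0
    mu = sum(pos) / n
    return n, mu, sum((p - mu) ** 2 for p in pos) / (n * len(seq))


class TestMoments:
    def test_positions_worked_example(self):
        assert positions_of("ACGTAC", "A").tolist() == [1, 5]
        assert positions_of("ACGTAC", "C").tolist() == [2, 6]
        assert positions_of("AAAA", "T").size == 0

    def test_worked_example_means(self):
        cmv = count_mean_var("ACGTAC")
        assert cmv["A"][1] == 3.0 and cmv["C"][1] == 4.0

    def test_d2_against_loop_oracle(self):
        assert count_mean_var("ACGTAC")["A"][2] == pytest.approx(2 / 3)
        assert count_mean_var("AAAA")["A"] == (4, 2.5, pytest.approx(5 / 16))
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = random_dna(rng, int(rng.integers(1, 60)))
            for k in "ACGT":
                assert count_mean_var(seq)[k] == pytest.approx(loop_moments(seq, k))


class TestSubsetAveragedCovariance:
    def test_equal_size_single_subset(self):
        assert brute_force_cov([1, 5], [2, 6]) == pytest.approx(4.0)
        assert subset_avg_cov([1, 5], [2, 6]) == pytest.approx(4.0)

    def test_unequal_size_enumeration(self):
        # subsets of {3,4,5}: {3,4} -> 1/4, {3,5} -> 1/2, {4,5} -> 1/4; mean 1/3
        assert brute_force_cov([1, 2], [3, 4, 5]) == pytest.approx(1 / 3)
        assert subset_avg_cov([1, 2], [3, 4, 5]) == pytest.approx(1 / 3)

    def test_singleton_vanishes(self):
        assert brute_force_cov([3], [1, 9]) == 0.0
        assert subset_avg_cov([3], [1, 9]) == 0.0

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="subset_avg_cov"):
            brute_force_cov(list(range(1, 16)), list(range(20, 80)))

    def test_closed_form_matches_bruteforce_randomized(self, rng):
        for _ in range(60):
            n, m = rng.integers(1, 7, size=2)
            A = rng.choice(30, size=n, replace=False) + 1
            B = rng.choice(30, size=m, replace=False) + 1
            bf = brute_force_cov(A, B)
            cf = subset_avg_cov(A, B)
            assert cf == pytest.approx(bf, rel=1e-9, abs=1e-9)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_affine_behaviour(self, data):
        n = data.draw(st.integers(1, 6))
        m = data.draw(st.integers(1, 6))
        A = data.draw(st.lists(st.integers(1, 30), min_size=n, max_size=n,
                               unique=True))
        B = data.draw(st.lists(st.integers(1, 30), min_size=m, max_size=m,
                               unique=True))
        v = subset_avg_cov(A, B)
        assert subset_avg_cov(B, A) == pytest.approx(v, abs=1e-12)
        shifted = subset_avg_cov([a + 7 for a in A], [b + 7 for b in B])
        assert shifted == pytest.approx(v, rel=1e-9, abs=1e-12)
        scaled = subset_avg_cov([3 * a for a in A], [3 * b for b in B])
        assert scaled == pytest.approx(9 * v, rel=1e-9, abs=1e-12)


class TestCovPair:
    def test_worked_example(self):
        assert cov_pair("ACGTAC", "A", "C") == pytest.approx(2 / 3)

    def test_self_covariance_is_d2(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = random_dna(rng, int(rng.integers(4, 50)))
            for k in "ACGT":
                n, _, d2 = count_mean_var(seq)[k]
                if n >= 1:
                    assert cov_pair(seq, k, k) == pytest.approx(d2, abs=1e-12)

    def test_absent_and_singleton(self):
        assert cov_pair("ACGTAC", "A", "G") == 0.0  # G occurs once
        assert cov_pair("AAAA", "A", "T") == 0.0    # T absent


class TestVectors:
    def test_nv18_worked_example(self):
        expected = [2, 2, 1, 1, 3, 4, 3, 4, 2 / 3, 2 / 3, 0, 0,
                    2 / 3, 0, 0, 0, 0, 0]
        assert natural_vector18("ACGTAC") == pytest.approx(expected)

    def test_single_base(self):
        v = natural_vector18("A")
        assert v[0] == 1 and v[4] == 1
        assert np.all(v[np.r_[1:4, 5:18]] == 0)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_counts_sum_to_length(self, seq):
        v = natural_vector18(seq)
        assert v[:4].sum() == len(seq)

    def test_nv12_is_prefix_and_equals_covariance_ablation(self):
        seq = "ACGTACGGTTAC"
        assert natural_vector12(seq) == pytest.approx(natural_vector18(seq)[:12])
        assert ablated_vector(seq, "covariance") == pytest.approx(
            natural_vector12(seq))

    @pytest.mark.parametrize("drop,size,head", [
        ("number", 14, [3, 4, 3, 4]),          # starts with the mean block
        ("mean_position", 14, [2, 2, 1, 1]),   # counts then variations
        ("normalized_variation", 14, [2, 2, 1, 1]),
        ("covariance", 12, [2, 2, 1, 1]),
    ])
    def test_ablations(self, drop, size, head):
        v = ablated_vector("ACGTAC", drop)
        assert v.size == size
        assert v[:4] == pytest.approx(head)

    def test_unknown_ablation(self):
        with pytest.raises(ValueError):
            ablated_vector("ACGT", "momentum")


class TestKmer:
    def test_k1_equals_count_block(self):
        assert kmer_vector("ACGTAC", 1).tolist() == [2, 2, 1, 1]

    def test_dimer_counts(self):
        v = kmer_vector("AAAA", 2)
        assert v[0] == 3 and v.sum() == 3

    @given(st.text(alphabet="ACGT", min_size=5, max_size=60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_counts_conserved(self, seq):
        assert kmer_vector(seq, 5).sum() == len(seq) - 4

    def test_too_short(self):
        with pytest.raises(ValueError):
            kmer_vector("ACG", 5)


class TestFeaturize:
    def test_shape_and_columns(self):
        recs = [SequenceRecord(f"s{i}", "ACGTAC") for i in range(3)]
        fm = featurize(recs, "nv18")
        assert fm.shape == (3, 18)
        assert tuple(fm.columns) == NV18_COLUMNS

    def test_identical_sequences_identical_rows(self):
        recs = [SequenceRecord("a", "ACGTACGT"), SequenceRecord("b", "ACGTACGT")]
        fm = featurize(recs)
        assert np.array_equal(fm.loc["a"].to_numpy(), fm.loc["b"].to_numpy())

    def test_empty_input(self):
        fm = featurize([], "nv18")
        assert fm.shape == (0, 18)

    def test_kmer_method_width(self):
        fm = featurize([SequenceRecord("a", "ACGTACGTAC")], "kmer:2")
        assert fm.shape == (1, 16)
        assert fm.columns[0] == "AA"

    def test_error_carries_record_id(self):
        with pytest.raises(ValueError, match="tiny"):
            featurize([SequenceRecord("tiny", "ACG")], "kmer:5")

    def test_deterministic_across_runs(self, rng):
        recs = [SequenceRecord(f"s{i}", random_dna(rng, 50)) for i in range(5)]
        a = featurize(recs).to_numpy()
        b = featurize(recs).to_numpy()
        assert np.array_equal(a, b)

    def test_sklearn_transformer_interface(self):
        enc = NaturalVectorEncoder(method="nv12")
        X = enc.fit_transform(["ACGTAC", "AAAA"])
        assert X.shape == (2, 12)
        assert enc.get_params() == {"method": "nv12"}
        assert list(enc.get_feature_names_out())[:2] == ["n_A", "n_C"]
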