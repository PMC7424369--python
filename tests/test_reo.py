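import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from oracles import binom_upper_tail_exact, naive_pair_summaries
from reokit.reo import (
    _bh_discrete,
    binomial_stability_p,
    compare_stable_pairs,
    stable_pairs,
    summarize_pairs,
)
from conftest import group_samples


class TestBinomialStabilityP:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (10, 10, 2.0**-10),
            (0, 10, 1.0),
            (5, 10, 638 / 1024),  # exhaustive term-by-term sum
        ],
    )
    def test_closed_forms(self, k, n, expected):
        assert binomial_stability_p(k, n) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_exact_rational_sum_up_to_n_20(self):
        for n in range(1, 21):
            for k in range(n + 1):
                exact = float(binom_upper_tail_exact(k, n))
                assert binomial_stability_p(k, n) == pytest.approx(exact, abs=1e-12)

    @given(n=st.integers(1, 500), k=st.integers(0, 500))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_non_increasing_in_k(self, n, k):
        k = min(k, n)
        if k > 0:
            assert binomial_stability_p(k, n) <= binomial_stability_p(k - 1, n) + 1e-15

    def test_numerically_stable_at_large_n(self):
        p_far = binomial_stability_p(6000, 10000)
        p_mid = binomial_stability_p(5000, 10000)
        assert np.isfinite(p_far) and 0.0 <= p_far < p_mid <= 1.0
        assert p_far < 1e-80  # deep tail still resolved, no overflow error

    @pytest.mark.parametrize("k,n", [(5, 4), (0, 0), (-1, 5)])
    def test_invalid_inputs_rejected(self, k, n):
        with pytest.raises(ValueError):
            binomial_stability_p(k, n)


class TestSummarizePairs:
    def test_tie_excluded_from_informative_count(self):
        matrix = pd.DataFrame(
            {"s1": [5.0, 1.0], "s2": [4.0, 2.0], "s3": [3.0, 3.0]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        (summary,) = list(summarize_pairs(matrix))
        assert (summary.gene_a, summary.gene_b) == ("gA", "gB")
        assert (summary.n_gt, summary.n_lt, summary.n_tie) == (2, 0, 1)
        assert (summary.n, summary.k) == (2, 2)

    def test_emits_all_pairs(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(4, 3)),
            index=[f"g{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(3)],
        )
        assert len(list(summarize_pairs(matrix))) == 6

    def test_matches_naive_double_loop(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(50, 10)),
            index=[f"g{i:02d}" for i in range(50)],
            columns=[f"s{i}" for i in range(10)],
        )
        expected = naive_pair_summaries(matrix)
        got = {
            (s.gene_a, s.gene_b): (s.n_gt, s.n_lt, s.n_tie)
            for s in summarize_pairs(matrix)
        }
        assert got == expected

    def test_blocked_streaming_equals_single_block(self, rng):
        matrix = pd.DataFrame(
            rng.integers(0, 5, size=(20, 6)).astype(float),  # many ties
            index=[f"g{i:02d}" for i in range(20)],
            columns=[f"s{i}" for i in range(6)],
        )
        small = list(summarize_pairs(matrix, block_size=7))
        big = list(summarize_pairs(matrix, block_size=10**6))
        assert small == big

    def test_too_few_genes_or_samples(self, tiny_matrix):
        with pytest.raises(ValueError):
            list(summarize_pairs(tiny_matrix.iloc[:1]))
        with pytest.raises(ValueError):
            list(summarize_pairs(tiny_matrix, samples=["s1"]))


class TestStablePairs:
    def test_shared_total_order_makes_every_pair_stable(self, rng):
        # 30 genes, 20 samples, all sharing one strict ordering
        base = np.arange(30, dtype=float)[:, None]
        noise = rng.uniform(0, 0.4, size=(30, 20))  # too small to flip any pair
        matrix = pd.DataFrame(
            base + noise,
            index=[f"g{i:02d}" for i in range(30)],
            columns=[f"s{i}" for i in range(20)],
        )
        result = stable_pairs(matrix, alpha=0.05)
        assert len(result) == 435
        assert (result.k == 20).all() and (result.n == 20).all()
        # canonical gene order is lexicographic = numeric here, so a < b
        # always means lower base value: direction a_lt_b everywhere
        assert (result.direction == -1).all()

    def test_discrete_bh_equals_naive_on_full_vector(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(10, 10)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(10)],
        )
        result = stable_pairs(matrix, alpha=0.05)
        summaries = list(summarize_pairs(matrix))
        p_full = np.array(
            [binomial_stability_p(s.k, s.n) if s.n > 0 else 1.0 for s in summaries]
        )
        naive_fdr = multipletests(p_full, method="fdr_bh")[1]
        got = _bh_discrete(p_full, len(p_full))
        np.testing.assert_array_equal(got, naive_fdr)
        # and the retained set matches the naive threshold rule
        naive_keep = {
            (s.gene_a, s.gene_b)
            for s, q in zip(summaries, naive_fdr)
            if q < 0.05 and s.n > 0
        }
        frame = result.to_frame()
        assert set(zip(frame.gene_a, frame.gene_b)) == naive_keep

    def test_weak_pair_among_strong_ones_excluded(self):
        # k=6/n=10 has raw p = 0.377 > alpha, so no BH cutoff can admit it
        p_weak = binomial_stability_p(6, 10)
        p = np.concatenate([np.full(1000, 2.0**-20), [p_weak]])
        fdr = _bh_discrete(p, p.size)
        assert fdr[-1] > 0.05
        assert (fdr[:-1] < 0.05).all()

    def test_monotone_transform_invariance(self, smoking_like):
        matrix, meta, _ = smoking_like
        samples = group_samples(meta, "smoker")
        base = stable_pairs(matrix, samples).to_frame()
        logged = stable_pairs(np.log(matrix), samples).to_frame()
        affine = stable_pairs(2.0 * matrix + 1.0, samples).to_frame()
        pd.testing.assert_frame_equal(base, logged)
        pd.testing.assert_frame_equal(base, affine)


class TestCompareStablePairs:
    def test_identical_sets_have_zero_reversal_ratio(self, smoking_like):
        matrix, meta, _ = smoking_like
        s1 = stable_pairs(matrix, group_samples(meta, "nonsmoker"))
        comp = compare_stable_pairs(s1, s1)
        assert comp.m == len(s1)
        assert comp.k_reversal == 0 and comp.reversal_ratio == 0.0

    def test_symmetric_in_arguments(self, smoking_like):
        matrix, meta, _ = smoking_like
        s1 = stable_pairs(matrix, group_samples(meta, "nonsmoker"))
        s2 = stable_pairs(matrix, group_samples(meta, "smoker"))
        fwd = compare_stable_pairs(s1, s2)
        rev = compare_stable_pairs(s2, s1)
        assert (fwd.m, fwd.k_reversal) == (rev.m, rev.k_reversal)

    def test_reversals_match_brute_force_scan(self, smoking_like):
        """Reversal count equals a naive direction check over every common pair."""
        matrix, meta, _ = smoking_like
        ns = group_samples(meta, "nonsmoker")
        sm = group_samples(meta, "smoker")
        s1 = stable_pairs(matrix, ns)
        s2 = stable_pairs(matrix, sm)
        comp = compare_stable_pairs(s1, s2)
        v1 = matrix[ns]
        v2 = matrix[sm]
        count = 0
        for a, b, d1, d2 in comp.reversal_pairs():
            # recheck directions straight from the data
            maj1 = np.sign((v1.loc[a] > v1.loc[b]).sum() - (v1.loc[a] < v1.loc[b]).sum())
            maj2 = np.sign((v2.loc[a] > v2.loc[b]).sum() - (v2.loc[a] < v2.loc[b]).sum())
            assert (maj1, maj2) == (d1, d2)
            count += 1
        assert count == comp.k_reversal
        assert comp.concordant + comp.k_reversal == comp.m

    def test_empty_overlap_gives_undefined_ratio(self, tiny_matrix):
        s = stable_pairs(tiny_matrix, alpha=0.05)
        empty = stable_pairs(tiny_matrix, alpha=1e-9)
        assert len(empty) == 0
        comp = compare_stable_pairs(s, empty)
        assert comp.m == 0 and comp.reversal_ratio is None

    def test_mismatched_universe_rejected(self, tiny_matrix, rng):
        other = pd.DataFrame(
            rng.normal(size=(3, 4)),
            index=["x1", "x2", "x3"],
            columns=tiny_matrix.columns,
        )
        with pytest.raises(ValueError, match="universe"):
            compare_stable_pairs(stable_pairs(tiny_matrix), stable_pairs(other))

    def test_two_reversals_in_thousand_common_pairs(self):
        """Direct k/m arithmetic: m=1000, k=2 -> ratio 0.002 via array surgery."""
        from reokit.reo import PairComparison

        comp = PairComparison(
            gene_ids=np.array([f"g{i}" for i in range(200)]),
            m=1000,
            k_reversal=2,
            pair_a=np.zeros(0, dtype=int),
            pair_b=np.zeros(0, dtype=int),
            direction_1=np.zeros(0, dtype=int),
            direction_2=np.zeros(0, dtype=int),
        )
        assert comp.reversal_ratio == pytest.approx(0.002)
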