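"""IndVal components, permutation test, and BH FDR against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seasonscan.indval import (adjust_fdr_bh, indval_components, indval_test,
                               permutation_test)
from seasonscan.otu_io import OtuTable
from seasonscan.partition import Partition
from .conftest import random_table


def naive_indval(counts, labels, variant):
    """Independent per-taxon/per-cluster double-loop oracle."""
    k = labels.max() + 1
    n_taxa = counts.shape[0]
    A = np.zeros((n_taxa, k))
    B = np.zeros((n_taxa, k))
    for t in range(n_taxa):
        means = []
        for c in range(k):
            cols = [j for j in range(counts.shape[1]) if labels[j] == c]
            means.append(sum(counts[t, j] for j in cols) / len(cols))
            B[t, c] = sum(1 for j in cols if counts[t, j] > 0) / len(cols)
        tot = sum(means)
        for c in range(k):
            A[t, c] = means[c] / tot if tot > 0 else 0.0
    iv = A * B
    if variant == "group_equalized":
        iv = np.sqrt(iv)
    return A, B, iv


def make_partition(labels):
    labels = np.asarray(labels)
    k = labels.max() + 1
    return Partition(k=k, labels=labels, sizes=np.bincount(labels, minlength=k),
                     inertia=0.0)


class TestComponents:
    def test_perfect_indicator_scores_one(self):
        counts = np.array([[4, 7, 0, 0]])
        t = OtuTable(counts, ["t"], ["a", "b", "c", "d"])
        A, B, iv = indval_components(t, np.array([0, 0, 1, 1]))
        assert A[0, 0] == 1 and B[0, 0] == 1 and iv[0, 0] == 1

    def test_even_taxon_scores_one_over_g(self):
        counts = np.array([[2, 2, 2, 2, 2, 2]])
        t = OtuTable(counts, ["t"], list("abcdef"))
        A, B, iv = indval_components(t, np.array([0, 0, 1, 1, 2, 2]),
                                     variant="classic")
        np.testing.assert_allclose(A[0], 1 / 3)
        np.testing.assert_allclose(B[0], 1.0)
        np.testing.assert_allclose(iv[0], 1 / 3)

    def test_two_cluster_toy_matches_hand_computation(self):
        # cluster 0 samples: (3,1),(0,2),(5,0); cluster 1: (0,4),(1,0),(2,2)
        counts = np.array([[3, 0, 5, 0, 1, 2],
                           [1, 2, 0, 4, 0, 2]])
        t = OtuTable(counts, ["t1", "t2"], list("abcdef"))
        labels = np.array([0, 0, 0, 1, 1, 1])
        A, B, iv = indval_components(t, labels, variant="classic")
        # taxon 1: cluster means 8/3 and 1 -> A = (8/11, 3/11); presence 2/3 both
        np.testing.assert_allclose(A[0], [8 / 11, 3 / 11])
        np.testing.assert_allclose(B[0], [2 / 3, 2 / 3])
        np.testing.assert_allclose(iv[0], [16 / 33, 2 / 11])
        # taxon 2: cluster means 1 and 2 -> A = (1/3, 2/3); presence 2/3 both
        np.testing.assert_allclose(A[1], [1 / 3, 2 / 3])
        np.testing.assert_allclose(iv[1], [2 / 9, 4 / 9])

    @pytest.mark.parametrize("variant", ["classic", "group_equalized"])
    def test_vectorized_matches_naive_loop(self, variant):
        rng = np.random.default_rng(17)
        for _ in range(20):
            t = random_table(rng, n_taxa=10, n_samples=8, lam=2)
            k = int(rng.integers(2, 5))
            labels = np.array(list(range(k)) + list(rng.integers(0, k, 8 - k)))
            A, B, iv = indval_components(t, labels, variant)
            A0, B0, iv0 = naive_indval(t.counts, labels, variant)
            np.testing.assert_allclose(A, A0, atol=1e-12)
            np.testing.assert_allclose(B, B0, atol=1e-12)
            np.testing.assert_allclose(iv, iv0, atol=1e-12)

    def test_all_zero_taxon_gets_zero_indval(self):
        t = OtuTable(np.array([[0, 0], [1, 2]]), ["z", "t"], ["a", "b"])
        A, B, iv = indval_components(t, np.array([0, 1]))
        np.testing.assert_array_equal(iv[0], 0.0)

    def test_indval_invariant_under_cluster_relabeling(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, 6, 9, lam=4)
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        _, _, iv = indval_components(t, labels)
        relab = np.array([2, 0, 1])[labels]  # permute cluster names
        _, _, iv2 = indval_components(t, relab)
        np.testing.assert_allclose(np.sort(iv, axis=1), np.sort(iv2, axis=1),
                                   atol=1e-12)
        np.testing.assert_allclose(iv.max(axis=1), iv2.max(axis=1), atol=1e-12)

    def test_fidelity_invariant_under_monotone_count_transform(self):
        rng = np.random.default_rng(8)
        t = random_table(rng, 7, 8, lam=1.5)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        _, B, _ = indval_components(t, labels)
        squared = OtuTable(t.counts ** 2, t.taxon_ids, t.sample_ids)
        _, B2, _ = indval_components(squared, labels)
        np.testing.assert_array_equal(B, B2)


class TestPermutation:
    def test_constant_taxon_has_p_one(self):
        counts = np.vstack([np.full(8, 3), np.arange(8)])
        t = OtuTable(counts, ["const", "var"], [f"s{i}" for i in range(8)])
        p = permutation_test(t, np.array([0, 0, 0, 0, 1, 1, 1, 1]),
                             n_perm=99, seed=0)
        assert p[0] == 1.0

    def test_perfect_indicator_reaches_minimum_p(self):
        counts = np.zeros((1, 20), dtype=int)
        counts[0, :10] = 5
        t = OtuTable(counts, ["t"], [f"s{i}" for i in range(20)])
        labels = np.array([0] * 10 + [1] * 10)
        p = permutation_test(t, labels, n_perm=999, seed=1)
        # minimum attainable p is 1/(n_perm+1); ties with equally extreme
        # permutations can lift it slightly
        assert p[0] <= 5 / 1000

    def test_p_against_exhaustive_enumeration_small_design(self):
        # 4+4 samples, statistic = max IndVal; enumerate all 8!/(4!4!)=70
        # cluster assignments for the exact null exceedance probability
        from itertools import combinations

        counts = np.array([[9, 7, 8, 6, 0, 1, 0, 0]])
        t = OtuTable(counts, ["t"], [f"s{i}" for i in range(8)])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])

        def max_iv(assign):
            lab = np.array(assign)
            _, _, iv = indval_components(t, lab)
            return iv.max()

        obs = max_iv(labels)
        exceed = 0
        total = 0
        for members in combinations(range(8), 4):
            lab = np.ones(8, dtype=int)
            lab[list(members)] = 0
            total += 1
            if max_iv(lab) >= obs - 1e-12:
                exceed += 1
        exact = exceed / total
        p = permutation_test(t, labels, n_perm=1999, seed=2)
        # permutation p estimates the enumeration value (2/70 here: the true
        # split and its mirror)
        assert exact == pytest.approx(2 / 70)
        assert abs(p[0] - exact) < 3 * np.sqrt(exact * (1 - exact) / 1999) + 1e-3

    def test_same_seed_reproduces_p_values(self, default_survey):
        table = default_survey[0]
        labels = np.arange(table.n_samples) % 3
        p1 = permutation_test(table, labels, n_perm=99, seed=5)
        p2 = permutation_test(table, labels, n_perm=99, seed=5)
        np.testing.assert_array_equal(p1, p2)

    def test_per_taxon_reallocation_variant_runs(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, 5, 12)
        labels = np.arange(12) % 3
        p = permutation_test(t, labels, n_perm=99, seed=0,
                             reallocation="per_taxon")
        assert ((p > 0) & (p <= 1)).all()

    def test_p_values_live_on_the_permutation_grid(self):
        rng = np.random.default_rng(2)
        t = random_table(rng, 30, 12)
        labels = np.arange(12) % 4
        p = permutation_test(t, labels, n_perm=199, seed=3)
        grid = np.round(p * 200)
        np.testing.assert_allclose(p * 200, grid, atol=1e-9)
        assert (grid >= 1).all() and (grid <= 200).all()


def bh_stepup_oracle(p, alpha):
    """Hand-coded BH step-up: independent of the implementation route."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    # adjusted values: running minimum from the largest rank down
    q_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = q_sorted
    # step-up rejection: largest i with p_(i) <= i*alpha/m
    thresh = 0
    for i in range(m):
        if sorted_p[i] <= (i + 1) * alpha / m:
            thresh = i + 1
    reject = np.zeros(m, bool)
    reject[order[:thresh]] = True
    return q, reject


class TestBH:
    def test_single_p_reduces_to_raw_threshold(self):
        q, sig = adjust_fdr_bh(np.array([0.04]), 0.05)
        assert sig[0] and q[0] == pytest.approx(0.04)

    def test_worked_example_two_of_four_significant(self):
        # step-up thresholds at alpha=0.05, m=4: 0.0125, 0.025, 0.0375, 0.05;
        # 0.04 > 0.0375, so only the first two survive
        q, sig = adjust_fdr_bh(np.array([0.01, 0.02, 0.04, 0.80]), 0.05)
        assert list(sig) == [True, True, False, False]
        assert q[2] == pytest.approx(0.04 * 4 / 3)

    def test_all_ones_nothing_significant(self):
        q, sig = adjust_fdr_bh(np.ones(5), 0.05)
        assert not sig.any()
        np.testing.assert_allclose(q, 1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_stepup_oracle(self, ps):
        p = np.array(ps)
        q, sig = adjust_fdr_bh(p, 0.05)
        q0, sig0 = bh_stepup_oracle(p, 0.05)
        np.testing.assert_allclose(q, q0, atol=1e-12)
        np.testing.assert_array_equal(sig, sig0)

    def test_q_monotone_in_p_and_dominates_bonferroni(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(1e-6, 1, 50)
        q, sig = adjust_fdr_bh(p, 0.05)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        bonf = p * p.size <= 0.05
        assert (sig | ~bonf).all()  # Bonferroni set is a subset of BH set


class TestFullIndval:
    def test_significance_flags_consistent_with_q(self, default_survey):
        table = default_survey[0]
        from seasonscan.otu_io import filter_min_count, rarefy
        from seasonscan.partition import kmeans_partition
        from seasonscan.transform import hellinger_transform

        rt = rarefy(filter_min_count(table, 5), seed=0)
        part = kmeans_partition(hellinger_transform(rt), 6, seed=0)
        res = indval_test(rt, part, n_perm=99, seed=0)
        assert (res.significant == (res.q_value <= 0.05) & ~res.all_zero).all()
        idx = np.arange(res.stat.size)
        np.testing.assert_allclose(res.stat, res.indval[idx, res.best_cluster])
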