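"""Fold construction, ranking metrics against oracles, and the Wilcoxon test."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from cgardp.evaluation import (
    confusion_at_threshold,
    make_folds,
    paired_wilcoxon,
    pr_auc,
    recall_at_k,
    roc_auc,
)


def auc_pairwise_oracle(scores, labels):
    """Mann-Whitney by explicit pairwise comparison, ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def wilcoxon_signflip_oracle(a, b):
    """Exact one-sided p-value by enumerating all 2^n sign assignments."""
    d = a - b
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


class TestMakeFolds:
    def test_exact_division(self, tiny_net):
        net = tiny_net
        plan = make_folds(net, n_folds=5, seed=0)
        sizes = [int((plan.fold_of == f).sum()) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == len(plan.positives)

    def test_folds_partition_positives(self, tiny_net):
        plan = make_folds(tiny_net, 4, seed=1)
        seen = set()
        for f in range(4):
            fold_pairs = {tuple(p) for p in plan.test_positives(f)}
            assert seen.isdisjoint(fold_pairs)
            seen |= fold_pairs
        assert seen == {tuple(p) for p in np.argwhere(tiny_net.A == 1)}

    def test_negatives_disjoint_and_unknown(self, tiny_net):
        plan = make_folds(tiny_net, 3, seed=2)
        seen = set()
        for f in range(3):
            negs = {tuple(p) for p in plan.negatives[f]}
            assert seen.isdisjoint(negs)
            seen |= negs
            for i, j in negs:
                assert tiny_net.A[i, j] == 0

    def test_same_seed_same_plan(self, tiny_net):
        a = make_folds(tiny_net, 5, seed=3)
        b = make_folds(tiny_net, 5, seed=3)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)
        for x, y in zip(a.negatives, b.negatives):
            np.testing.assert_array_equal(x, y)

    def test_insufficient_positives_rejected(self, worked_example):
        with pytest.raises(ValueError):
            make_folds(worked_example, n_folds=5, seed=0)


class TestConfusion:
    def test_hand_counted_example(self):
        out = confusion_at_threshold(
            np.array([0.9, 0.8, 0.3]), np.array([1, 0, 1]), 0.5
        )
        assert (out["TP"], out["FP"], out["TN"], out["FN"]) == (1, 1, 0, 1)
        assert out["precision"] == 0.5 and out["recall"] == 0.5

    def test_threshold_below_everything(self):
        out = confusion_at_threshold(np.array([0.2, 0.7]), np.array([1, 0]), 0.0)
        assert out["recall"] == 1.0 and out["FPR"] == 1.0

    def test_threshold_above_everything(self):
        out = confusion_at_threshold(np.array([0.2, 0.7]), np.array([1, 0]), 0.99)
        assert out["TP"] == 0 and out["FP"] == 0 and out["precision"] == 0.0


class TestRankingAucs:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels) == 1.0
        assert pr_auc(scores, labels) == 1.0

    def test_three_item_example(self):
        # one concordant positive-negative pair of two -> AUC 0.5
        assert roc_auc(np.array([0.9, 0.8, 0.3]), np.array([1, 0, 1])) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_roc_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        scores = rng.integers(0, 8, size=n) / 7.0  # coarse grid forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            auc_pairwise_oracle(scores, labels), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_aucs_match_sklearn_reference(self, seed):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 50))
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-9
        )
        assert pr_auc(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-9
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))
        with pytest.raises(ValueError):
            pr_auc(np.array([0.1, 0.2]), np.array([0, 0]))


class TestRecallAtK:
    def test_half_recovered_in_top_two(self):
        assert recall_at_k({"r1": np.array([1, 0, 1, 0])}, [2]) == {2: 0.5}

    def test_k_beyond_length_gives_one(self):
        assert recall_at_k({"r1": np.array([0, 1])}, [10]) == {10: 1.0}

    def test_mean_over_drugs(self):
        curve = recall_at_k(
            {"a": np.array([1, 0, 1, 0, 1, 0, 0, 1, 1]),  # 2 of 5 in top 4
             "b": np.array([1, 1, 0, 1, 0])},             # 3 of 3 in top 4
            [4],
        )
        assert curve[4] == pytest.approx((2 / 5 + 3 / 3) / 2)

    def test_nondecreasing_in_k(self, rng):
        ranked = (rng.random(30) < 0.3).astype(int)
        ranked[0] = 1
        curve = recall_at_k({"r": ranked}, list(range(1, 31)))
        vals = [curve[k] for k in range(1, 31)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 1.0

    def test_no_positive_drug_rejected(self):
        with pytest.raises(ValueError):
            recall_at_k({"r": np.zeros(4, int)}, [2])


class TestPairedWilcoxon:
    def test_constant_shift_n8(self):
        a = np.arange(8, dtype=float)
        b = a - 1.0
        # all 8 ranks positive: only the all-positive assignment reaches W+
        assert paired_wilcoxon(a, b) == pytest.approx(1 / 256)

    def test_identical_samples_rejected(self):
        a = np.ones(8)
        with pytest.raises(ValueError):
            paired_wilcoxon(a, a.copy())

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_signflip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        assert paired_wilcoxon(a, b) == pytest.approx(
            wilcoxon_signflip_oracle(a, b), abs=1e-12
        )

    def test_matches_scipy_exact(self, rng):
        from scipy.stats import wilcoxon

        a, b = rng.normal(size=15), rng.normal(size=15)
        ours = paired_wilcoxon(a, b)
        ref = wilcoxon(a, b, alternative="greater", mode="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_tie_branch_matches_scipy_approx(self, rng):
        from scipy.stats import wilcoxon

        a = rng.integers(0, 5, size=40).astype(float)
        b = rng.integers(0, 5, size=40).astype(float)
        d = a - b
        if (d != 0).sum() < 5:
            a[:6] += 1.0
        ours = paired_wilcoxon(a, b)
        ref = wilcoxon(
            a, b, alternative="greater", mode="approx", correction=False,
            zero_method="wilcox",
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)
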