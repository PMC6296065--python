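import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from pasnet.evaluation import (
    f1_positive,
    repeated_cv,
    roc_auc,
    wilcoxon_signed_rank,
)


def pair_count_auc(scores, y):
    """Brute-force Mann–Whitney AUC over all positive–negative pairs."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_wilcoxon_p(d):
    """Exact two-sided p by enumerating every sign pattern."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    w_all = np.array(
        [sum(r for r, s in zip(ranks, signs) if s)
         for signs in itertools.product([False, True], repeat=len(d))]
    )
    le = (w_all <= obs + 1e-9).mean()
    ge = (w_all >= obs - 1e-9).mean()
    return min(1.0, 2 * min(le, ge))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        _, auc = roc_auc(np.full(10, 0.5), np.array([1] * 4 + [0] * 6))
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_exhaustive_pair_counting(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 51))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        # discretized scores exercise tie handling
        scores = np.round(rng.normal(size=n), 1)
        _, auc = roc_auc(scores, y)
        assert auc == pytest.approx(pair_count_auc(scores, y))

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        scores = rng.normal(size=30)
        _, a1 = roc_auc(scores, y)
        _, a2 = roc_auc(np.exp(3 * scores), y)
        assert a1 == pytest.approx(a2)

    def test_negated_scores_complement(self, rng):
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        scores = rng.normal(size=25)  # continuous, ties absent
        _, a1 = roc_auc(scores, y)
        _, a2 = roc_auc(-scores, y)
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestF1:
    def test_hand_counts(self):
        # TP=3, FP=1, FN=2 → PPV=0.75, TPR=0.6, F1=0.6667
        y = np.array([1, 1, 1, 1, 1, 0, 0])
        pred = np.array([1, 1, 1, 0, 0, 1, 0])
        assert f1_positive(pred, y) == pytest.approx(2 * 0.45 / 1.35)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0])
        assert f1_positive(y, y) == 1.0

    def test_degenerate_no_positives_returns_zero(self):
        y = np.array([0, 0, 1])
        pred = np.array([0, 0, 0])
        assert f1_positive(pred, y) == 0.0

    @pytest.mark.parametrize("tp,fp,fn,tn", [(3, 1, 2, 4), (5, 0, 0, 5),
                                             (0, 3, 4, 3), (1, 1, 1, 1)])
    def test_matches_formula_on_enumerated_confusions(self, tp, fp, fn, tn):
        y = np.array([1] * (tp + fn) + [0] * (fp + tn))
        pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        ppv = tp / (tp + fp) if tp + fp else 0.0
        tpr = tp / (tp + fn) if tp + fn else 0.0
        expect = 2 * ppv * tpr / (ppv + tpr) if ppv + tpr else 0.0
        assert f1_positive(pred, y) == pytest.approx(expect)


class TestWilcoxon:
    def test_all_positive_n6_is_extreme(self):
        W, p = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5, 6]))
        assert W == 0.0
        assert p == pytest.approx(2 / 64)

    def test_sign_flip_symmetry(self, rng):
        d = rng.normal(size=10)
        d[d == 0] = 0.1
        _, p1 = wilcoxon_signed_rank(d)
        _, p2 = wilcoxon_signed_rank(-d)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_exact_p_matches_sign_enumeration_small_n(self, n):
        rng = np.random.default_rng(n)
        for _ in range(8):
            d = np.round(rng.normal(size=n), 1)
            d[d == 0] = 0.05
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(enumerate_wilcoxon_p(d))

    @pytest.mark.parametrize("trial", range(50))
    def test_exact_p_matches_enumeration_mid_n(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(9, 13))
        d = np.round(rng.normal(size=n), 1)
        d[d == 0] = 0.05
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(enumerate_wilcoxon_p(d))

    def test_agrees_with_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(9)
        d = rng.permutation(np.arange(1, 13)) * np.where(rng.random(12) < 0.4, -1, 1)
        d = d.astype(float)
        W, p = wilcoxon_signed_rank(d)
        res = scipy_wilcoxon(d, method="exact")
        assert W == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(17)
        d = rng.normal(0.3, 1.0, 40)
        d[d == 0] = 0.1
        _, p = wilcoxon_signed_rank(d)
        res = scipy_wilcoxon(d, method="approx", correction=True)
        assert p == pytest.approx(res.pvalue, rel=0.05)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(5))


class TestRepeatedCV:
    def _quick_estimator(self, A):
        from pasnet.estimator import PASNetClassifier

        return PASNetClassifier(
            adjacency=A, hidden_size=4, learning_rate=1e-2,
            max_epochs=15, patience=10**9,
        )

    def test_bookkeeping_and_partition(self):
        from conftest import load_sim, small_design

        X, y, A, _ = load_sim(small_design())
        report = repeated_cv(self._quick_estimator(A), X, y, k=3, repeats=2, seed=0)
        assert len(report.table) == 6
        assert set(report.table["repeat"]) == {0, 1}
        assert report.table.groupby("repeat")["n_test"].sum().eq(len(y)).all()
        assert ((report.table["auc"] >= 0) & (report.table["auc"] <= 1)).all()

    def test_fold_standardization_ignores_test_samples(self):
        # an extreme-valued test sample must not move training statistics
        from pasnet.data import standardize_fold

        rng = np.random.default_rng(0)
        train = rng.normal(size=(20, 3))
        test = rng.normal(size=(5, 3))
        test_extreme = test.copy()
        test_extreme[0] = 1e6
        Ztr1, _ = standardize_fold(train, test)
        Ztr2, Zte2 = standardize_fold(train, test_extreme)
        np.testing.assert_array_equal(Ztr1, Ztr2)
        assert np.abs(Zte2[0]).min() > 1e4  # scaled by train stats only

    def test_seed_reproducibility(self):
        from conftest import load_sim, small_design

        X, y, A, _ = load_sim(small_design())
        est = self._quick_estimator(A)
        r1 = repeated_cv(est, X, y, k=2, repeats=1, seed=4)
        r2 = repeated_cv(est, X, y, k=2, repeats=1, seed=4)
        np.testing.assert_array_equal(r1.auc_values, r2.auc_values)

    def test_compare_refuses_mismatched_length(self):
        from conftest import load_sim, small_design

        X, y, A, _ = load_sim(small_design())
        report = repeated_cv(self._quick_estimator(A), X, y, k=2, repeats=1, seed=1)
        with pytest.raises(ValueError, match="paired"):
            report.compare(np.ones(7))
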