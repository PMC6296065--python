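"""Evaluation protocol: repeated stratified CV, ROC/AUC, F1, Wilcoxon.

The protocol mirrors the survival-classification setting: stratified
k-fold cross-validation repeated with fresh fold seeds, per-gene
standardization computed on each training fold only, samples scored by
the positive-class (long-term survival) posterior, AUC from the ROC
sweep and F1 for the positive class at a 0.5 posterior threshold.
Paired model comparison uses a two-sided Wilcoxon signed-rank test over
the per-(repeat, fold) metric pairs, exact for small numbers of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import clone
from sklearn.metrics import f1_score, roc_auc_score, roc_curve

from .data import standardize_fold, stratified_folds

__all__ = [
    "CVReport",
    "roc_auc",
    "f1_positive",
    "wilcoxon_signed_rank",
    "repeated_cv",
]


def roc_auc(scores, y) -> tuple[list[tuple[float, float]], float]:
    """ROC points (threshold sweep) and AUC for binary labels.

    The trapezoidal area over the ROC sweep equals the Mann–Whitney
    pair statistic (concordant + half of tied pairs, over n₊·n₋).
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(y, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(roc_auc_score(y, scores))


def f1_positive(predictions, y) -> float:
    """F1 of the positive class: 2·PPV·TPR/(PPV+TPR); 0 when undefined."""
    return float(f1_score(y, predictions, pos_label=1, zero_division=0))


def wilcoxon_signed_rank(a, b=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    ``b`` omitted means ``a`` already holds the differences.  Zero
    differences are discarded; ranks of |d| are tie-averaged.  The
    statistic is ``W = min(W⁺, W⁻)``.  The p-value is exact (full
    distribution of W⁺ over all sign assignments, ties included) for up
    to 25 nonzero pairs, and a normal approximation with tie and
    continuity corrections beyond that.
    """
    d = np.asarray(a, dtype=float) - (0.0 if b is None else np.asarray(b, dtype=float))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    W = min(w_pos, w_neg)

    if n <= 25:
        # doubled ranks are integers even with tie-averaging; build the
        # exact distribution of 2·W⁺ by polynomial convolution
        r2 = np.rint(2 * ranks).astype(int)
        counts = np.zeros(int(r2.sum()) + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: len(counts) - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(np.rint(2 * w_pos))
        cdf_le = float(counts[: w2 + 1].sum())
        cdf_ge = float(counts[w2:].sum())
        p = min(1.0, 2.0 * min(cdf_le, cdf_ge))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, t = np.unique(ranks, return_counts=True)
        var -= (t**3 - t).sum() / 48.0
        dev = w_pos - mean
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return W, p


@dataclass
class CVReport:
    """Per-(repeat, fold) metrics plus ROC points for plotting."""

    table: pd.DataFrame  # columns: repeat, fold, auc, f1, n_test
    roc_points: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        return self.table[["auc", "f1"]].agg(["mean", "std"])

    @property
    def auc_values(self) -> np.ndarray:
        """Per-(repeat, fold) AUCs in protocol order — the pairing unit
        for signed-rank model comparison."""
        return self.table.sort_values(["repeat", "fold"])["auc"].to_numpy()

    def compare(self, other_aucs) -> tuple[float, float]:
        other = np.asarray(other_aucs, dtype=float)
        if len(other) != len(self.table):
            raise ValueError(
                f"paired comparison needs {len(self.table)} scores, got {len(other)}"
            )
        return wilcoxon_signed_rank(self.auc_values, other)

    def write_tsv(self, path: str | PathLike, model: str = "pasnet") -> None:
        long = self.table.melt(
            id_vars=["repeat", "fold"],
            value_vars=["auc", "f1"],
            var_name="metric",
            value_name="value",
        )
        long.insert(2, "model", model)
        long.to_csv(path, sep="\t", index=False)


def repeated_cv(
    estimator,
    X,
    y,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """Repeated stratified k-fold CV with fold-wise standardization.

    Folds are re-drawn with a fresh seed on every repeat.  Each training
    fold is z-scored with its own statistics, which also scale the test
    fold — test samples never influence scaling.  Test samples are
    scored by the positive-class posterior; F1 uses the given posterior
    threshold.  The estimator is cloned per fold with a derived
    ``random_state``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    ss = np.random.SeedSequence(seed)
    rows = []
    roc_points = {}
    for rep in range(repeats):
        fold_seed, est_base = (int(s) for s in ss.generate_state(2) % (2**31))
        folds = stratified_folds(y, k, fold_seed)
        all_idx = np.arange(len(y))
        for fold_id, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            Ztr, Zte = standardize_fold(X[train_idx], X[test_idx])
            est = clone(estimator)
            est.set_params(random_state=(est_base + fold_id) % (2**31))
            est.fit(Ztr, y[train_idx])
            scores = est.predict_proba(Zte)[:, 1]
            points, auc = roc_auc(scores, y[test_idx])
            f1 = f1_positive((scores > threshold).astype(int), y[test_idx])
            rows.append(
                {"repeat": rep, "fold": fold_id, "auc": auc, "f1": f1,
                 "n_test": len(test_idx)}
            )
            roc_points[(rep, fold_id)] = points
    return CVReport(pd.DataFrame(rows), roc_points)
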