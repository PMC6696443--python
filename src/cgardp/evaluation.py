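"""Five-fold cross-validation and per-drug ranking evaluation.

Known associations are split randomly into near-equal positive folds, with
matched-count negative folds sampled disjointly from unknown pairs.  Each
round trains on four fifths (with held-out positives removed from the
association matrix, hence from pair features and path evidence) and ranks
each drug's held-out candidates.  Reported metrics are computed within
each drug's candidate ranking and macro-averaged: ROC AUC (pairwise rank
statistic, ties counted half), area under the precision-recall curve
(step integration over all score thresholds), and average recall among the
top-k candidates over a configurable k grid.  A paired one-sided Wilcoxon
signed-rank test compares per-drug metrics between two methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .netio import HeteroNetwork

__all__ = [
    "FoldPlan",
    "EvalReport",
    "make_folds",
    "confusion_at_threshold",
    "roc_auc",
    "pr_auc",
    "recall_at_k",
    "paired_wilcoxon",
    "cross_validate",
    "compare_reports",
]


@dataclass
class FoldPlan:
    """Random partition of positives (and matched negatives) into folds."""

    positives: np.ndarray  # (n_pos, 2)
    fold_of: np.ndarray  # (n_pos,) in [0, n_folds)
    negatives: list[np.ndarray]  # per fold: (n_f, 2), disjoint across folds
    n_folds: int
    seed: int

    def test_positives(self, fold: int) -> np.ndarray:
        return self.positives[self.fold_of == fold]

    def train_positives(self, fold: int) -> np.ndarray:
        return self.positives[self.fold_of != fold]

    def train_negatives(self, fold: int) -> np.ndarray:
        others = [self.negatives[f] for f in range(self.n_folds) if f != fold]
        return np.vstack(others)


def make_folds(net: HeteroNetwork, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded near-equal partition of positives plus matched negative folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    positives = np.argwhere(net.A == 1)
    n_pos = len(positives)
    if n_pos < n_folds:
        raise ValueError(f"need at least {n_folds} positives, have {n_pos}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n_pos, dtype=int)
    order = rng.permutation(n_pos)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        fold_of[chunk] = f
    unknown = np.argwhere(net.A == 0)
    if len(unknown) < n_pos:
        raise ValueError("not enough unknown pairs to match the positives")
    neg_take = rng.choice(len(unknown), size=n_pos, replace=False)
    negatives = []
    start = 0
    for f in range(n_folds):
        size = int((fold_of == f).sum())
        negatives.append(unknown[neg_take[start : start + size]])
        start += size
    return FoldPlan(positives, fold_of, negatives, n_folds, seed)


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, theta: float
) -> dict[str, float]:
    """Counts and rates for the rule "positive iff score > theta"."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = scores > theta
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "TPR": tpr, "FPR": fpr, "precision": precision, "recall": tpr,
    }


def _check_two_class(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metric undefined: need at least one positive and one negative")
    return n_pos, n_neg


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the normalized Mann-Whitney rank statistic (ties half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos, n_neg = _check_two_class(labels)
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by threshold-step integration.

    Equal scores are grouped into one threshold step, so the result is
    invariant to orderings within ties.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos, _ = _check_two_class(labels)
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    # indices where a threshold group ends (last occurrence of each score)
    boundary = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    cum_tp = np.cumsum(l)[boundary]
    n_pred = boundary + 1
    precision = cum_tp / n_pred
    recall = cum_tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def recall_at_k(
    per_drug_rankings: dict[str, np.ndarray], k_grid: list[int]
) -> dict[int, float]:
    """Mean over drugs of (test positives in top k) / (test positives)."""
    if not per_drug_rankings:
        raise ValueError("no rankings given")
    curve = {}
    per_drug = {}
    for drug, ranked in per_drug_rankings.items():
        ranked = np.asarray(ranked, int)
        if len(ranked) == 0:
            raise ValueError(f"empty ranking for drug {drug!r}")
        total = ranked.sum()
        if total == 0:
            raise ValueError(f"drug {drug!r} has no test positives")
        per_drug[drug] = ranked
    for k in k_grid:
        if k < 1:
            raise ValueError("k must be positive")
        vals = [r[:k].sum() / r.sum() for r in per_drug.values()]
        curve[int(k)] = float(np.mean(vals))
    return curve


def _exact_wplus_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under the sign-flip null by subset-sum counting.

    Average ranks under ties are multiples of 1/2, so doubling makes every
    rank an integer and the distribution follows from a subset-sum DP.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total - r + 1].copy()
    tail = counts[int(np.ceil(2 * w_obs - 1e-9)) :].sum()
    return float(tail / 2.0 ** len(ranks))


def paired_wilcoxon(metric_a: np.ndarray, metric_b: np.ndarray) -> float:
    """One-sided paired Wilcoxon signed-rank p-value (alternative a > b).

    Zero differences are dropped.  For n <= 25 the exact sign-flip null
    distribution is used (ties handled through doubled average ranks);
    beyond that a normal approximation with tie correction (no continuity
    correction, the standard large-sample form).
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test degenerate")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_wplus_sf(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    from scipy.stats import norm

    z = (w_plus - mean) / np.sqrt(var)
    return float(norm.sf(z))


@dataclass
class EvalReport:
    """Aggregated cross-validation results."""

    per_drug: pd.DataFrame  # columns: fold, drug, n_pos, n_candidates, auc, aupr
    macro_auc: float
    macro_aupr: float
    recall_curve: dict[int, float]
    n_folds: int
    seed: int
    wilcoxon: dict[str, float] | None = None
    scores: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "macro_auc": round(self.macro_auc, 12),
            "macro_aupr": round(self.macro_aupr, 12),
            "recall_curve": {str(k): round(v, 12) for k, v in self.recall_curve.items()},
            "n_folds": self.n_folds,
            "seed": self.seed,
            "wilcoxon": self.wilcoxon,
            "per_drug": [
                {
                    "fold": int(r.fold),
                    "drug": r.drug,
                    "n_pos": int(r.n_pos),
                    "n_candidates": int(r.n_candidates),
                    "auc": round(float(r.auc), 12),
                    "aupr": round(float(r.aupr), 12),
                }
                for r in self.per_drug.itertuples(index=False)
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def cross_validate(
    net: HeteroNetwork,
    clf=None,
    n_folds: int = 5,
    seed: int = 0,
    k_grid: tuple[int, ...] = (30, 60, 90, 120),
    candidate_mode: str = "all_unknown",
    keep_scores: bool = False,
) -> EvalReport:
    """Per-drug ranking evaluation under seeded n-fold cross-validation.

    ``clf`` is an (unfitted) estimator prototype; it is re-instantiated
    per fold with a fold-derived random state.  ``candidate_mode`` selects
    each drug's test candidates: its held-out positives plus either all
    its unknown diseases not used as training negatives ("all_unknown")
    or only its held-out sampled negatives ("sampled").
    """
    from .estimator import CGARDPClassifier

    if clf is None:
        clf = CGARDPClassifier()
    if candidate_mode not in ("all_unknown", "sampled"):
        raise ValueError("candidate_mode must be 'all_unknown' or 'sampled'")
    plan = make_folds(net, n_folds, seed)
    k_grid = [int(k) for k in k_grid]
    rows = []
    score_rows = []
    rankings: dict[tuple[int, str], np.ndarray] = {}
    proto = clf.get_params()
    for fold in range(n_folds):
        test_pos = plan.test_positives(fold)
        train_pos = plan.train_positives(fold)
        train_neg = plan.train_negatives(fold)
        A_train = net.A.copy()
        A_train[test_pos[:, 0], test_pos[:, 1]] = 0.0
        # leakage guard: no held-out association may remain visible
        assert (A_train[test_pos[:, 0], test_pos[:, 1]] == 0).all()
        fold_net = net.copy_with_associations(A_train)
        fold_seed = (seed * 1_000_003 + fold) % (2**31)
        fold_clf = type(clf)(**proto).set_params(random_state=fold_seed)
        pairs = np.vstack([train_pos, train_neg])
        labels = np.concatenate(
            [np.ones(len(train_pos), int), np.zeros(len(train_neg), int)]
        )
        fold_clf.fit(pairs, labels, network=fold_net)

        neg_used = {(int(i), int(j)) for i, j in train_neg}
        drugs_in_fold = np.unique(test_pos[:, 0])
        cand_pairs = []
        cand_labels = []
        cand_drug = []
        for i in drugs_in_fold:
            pos_j = test_pos[test_pos[:, 0] == i][:, 1]
            if candidate_mode == "all_unknown":
                unknown_j = np.where(net.A[i] == 0)[0]
                neg_j = np.array(
                    [j for j in unknown_j if (int(i), int(j)) not in neg_used], dtype=int
                )
            else:
                fold_neg = plan.negatives[fold]
                neg_j = fold_neg[fold_neg[:, 0] == i][:, 1]
            if len(neg_j) == 0:
                continue
            for j in pos_j:
                cand_pairs.append((i, j))
                cand_labels.append(1)
                cand_drug.append(i)
            for j in neg_j:
                cand_pairs.append((i, j))
                cand_labels.append(0)
                cand_drug.append(i)
        cand_pairs = np.asarray(cand_pairs, int)
        cand_labels = np.asarray(cand_labels, int)
        cand_drug = np.asarray(cand_drug, int)
        scores = fold_clf.predict_proba(cand_pairs)[:, 1]
        for i in np.unique(cand_drug):
            m = cand_drug == i
            sc, lb, js = scores[m], cand_labels[m], cand_pairs[m][:, 1]
            if lb.sum() == 0 or (lb == 0).sum() == 0:
                continue
            drug_id = net.drug_ids[int(i)]
            # stable ranking: score desc, disease id asc
            dis_ids = [net.disease_ids[int(j)] for j in js]
            order = sorted(range(len(sc)), key=lambda t: (-sc[t], dis_ids[t]))
            rankings[(fold, drug_id)] = lb[order]
            rows.append(
                {
                    "fold": fold,
                    "drug": drug_id,
                    "n_pos": int(lb.sum()),
                    "n_candidates": int(len(lb)),
                    "auc": roc_auc(sc, lb),
                    "aupr": pr_auc(sc, lb),
                }
            )
            if keep_scores:
                for t in range(len(sc)):
                    score_rows.append(
                        (drug_id, dis_ids[t], float(sc[t]), int(lb[t]), fold)
                    )
    per_drug = pd.DataFrame(rows)
    curve = recall_at_k(
        {f"{f}:{d}": r for (f, d), r in rankings.items()}, k_grid
    )
    report = EvalReport(
        per_drug=per_drug,
        macro_auc=float(per_drug["auc"].mean()),
        macro_aupr=float(per_drug["aupr"].mean()),
        recall_curve=curve,
        n_folds=n_folds,
        seed=seed,
        scores=pd.DataFrame(
            score_rows, columns=["drug", "disease", "score", "label", "fold"]
        )
        if keep_scores
        else None,
    )
    return report


def compare_reports(report_a: EvalReport, report_b: EvalReport) -> dict[str, float]:
    """Paired one-sided Wilcoxon (a > b) on per-drug AUC and AUPR.

    Entries are aligned on (fold, drug); both reports must come from the
    same fold plan.
    """
    a = report_a.per_drug.set_index(["fold", "drug"])
    b = report_b.per_drug.set_index(["fold", "drug"])
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("reports share no (fold, drug) entries")
    out = {}
    for metric in ("auc", "aupr"):
        out[f"p_{metric}"] = paired_wilcoxon(
            a.loc[common, metric].to_numpy(), b.loc[common, metric].to_numpy()
        )
    return out
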