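"""Cross-validated evaluation of association rankings.

Known associations are split into k near-equal folds; for each fold the
whole pipeline -- composite similarities (including the association-based
kernel), walk budgets, walks -- is recomputed from the masked training
matrix only, so no information from held-out pairs leaks into scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from birwalk.birw import PipelineConfig, dr_ibrw
from birwalk.net_core import AssociationMatrix, FeatureMatrix

METRICS = ("auroc", "aupr", "micro_f1", "macro_f1", "precision", "recall")


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint near-equal partition of the known (drug, disease) index pairs."""

    k: int
    seed: int
    folds: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self) -> None:
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most one")


@dataclass(frozen=True)
class MetricReport:
    per_fold: pd.DataFrame  # one row per fold, one column per metric
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)


def make_folds(assoc: AssociationMatrix, k: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded shuffle of positive pairs followed by round-robin assignment."""
    rows, cols = np.nonzero(assoc.values)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    if len(pairs) < k:
        raise ValueError(f"need at least {k} known associations, have {len(pairs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds: list[list[tuple[int, int]]] = [[] for _ in range(k)]
    for position, pair_idx in enumerate(order.tolist()):
        folds[position % k].append(pairs[pair_idx])
    return FoldPlan(k=k, seed=seed, folds=tuple(tuple(f) for f in folds))


def mask_fold(assoc: AssociationMatrix, fold: tuple[tuple[int, int], ...]) -> AssociationMatrix:
    """Training matrix with the fold's positives zeroed out."""
    values = assoc.values.copy()
    for i, j in fold:
        if values[i, j] != 1:
            raise ValueError(f"fold pair ({i}, {j}) is not a known association")
        values[i, j] = 0
    if values.sum() == 0:
        raise ValueError("fold removes every association from the network")
    return AssociationMatrix(
        drug_index=assoc.drug_index, disease_index=assoc.disease_index, values=values
    )


def score_fold(
    features_drug: FeatureMatrix,
    features_disease: FeatureMatrix,
    assoc: AssociationMatrix,
    fold: tuple[tuple[int, int], ...],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and labels over held-out positives plus all unknown pairs.

    Training positives are never included in the evaluation set.
    """
    training = mask_fold(assoc, fold)
    result = dr_ibrw(features_drug, features_disease, training, config)
    f = result.scores.values
    pos_scores = np.array([f[i, j] for i, j in fold])
    neg_mask = assoc.values == 0
    neg_scores = f[neg_mask]
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate(
        [np.ones(pos_scores.size, dtype=int), np.zeros(neg_scores.size, dtype=int)]
    )
    return scores, labels


def auroc_rank_sum(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC with half credit for ties."""
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _tie_group_counts(scores: np.ndarray, labels: np.ndarray):
    """Cumulative TP/FP at each distinct descending score cut-point."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = np.asarray(labels, dtype=int)[order]
    boundaries = np.nonzero(np.diff(s))[0]
    last = np.concatenate([boundaries, [s.size - 1]])
    tp = np.cumsum(y)[last]
    fp = np.cumsum(1 - y)[last]
    thresholds = s[last]
    return thresholds, tp, fp


def aupr_step(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve via the step integral."""
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("AUPR requires both classes")
    _, tp, fp = _tie_group_counts(scores, labels)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def ranking_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """The six ranking/threshold metrics for one fold.

    Threshold-dependent metrics are computed at the observed cut-point
    that maximises the positive-class F1 (reported as micro_f1);
    macro_f1 is the unweighted mean of the positive- and negative-class
    F1 at that same threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ranking metrics require both classes")

    thresholds, tp, fp = _tie_group_counts(scores, labels)
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(divide="ignore", invalid="ignore"):
        f1_pos = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    best = int(np.argmax(f1_pos))  # ties resolved toward the larger threshold

    tp_b, fp_b, fn_b, tn_b = tp[best], fp[best], fn[best], tn[best]
    precision = tp_b / (tp_b + fp_b) if tp_b + fp_b > 0 else 0.0
    recall = tp_b / n_pos
    micro_f1 = float(f1_pos[best])
    f1_neg = 2 * tn_b / (2 * tn_b + fn_b + fp_b) if 2 * tn_b + fn_b + fp_b > 0 else 0.0
    macro_f1 = (micro_f1 + f1_neg) / 2.0

    return {
        "auroc": auroc_rank_sum(scores, labels),
        "aupr": aupr_step(scores, labels),
        "micro_f1": micro_f1,
        "macro_f1": float(macro_f1),
        "precision": float(precision),
        "recall": float(recall),
        "threshold": float(thresholds[best]),
    }


def cross_validate(
    features_drug: FeatureMatrix,
    features_disease: FeatureMatrix,
    assoc: AssociationMatrix,
    config: PipelineConfig = PipelineConfig(),
    k: int = 10,
    seed: int = 0,
) -> MetricReport:
    """k-fold cross-validation; per-fold metric rows plus mean and standard deviation."""
    plan = make_folds(assoc, k=k, seed=seed)
    rows = []
    for fold_idx, fold in enumerate(plan.folds):
        scores, labels = score_fold(features_drug, features_disease, assoc, fold, config)
        row = ranking_metrics(scores, labels)
        row["fold"] = fold_idx
        rows.append(row)
    per_fold = pd.DataFrame(rows).set_index("fold")
    mean = {m: float(per_fold[m].mean()) for m in METRICS}
    sd = {m: float(per_fold[m].std(ddof=0)) for m in METRICS}
    return MetricReport(per_fold=per_fold, mean=mean, sd=sd)
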