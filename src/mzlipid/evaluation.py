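"""Performance metrics, tie-aware rank aggregation, and model comparison.

Four metrics drive model selection: accuracy, ROC AUC, and PR AUC computed
twice — once with the non-lipid class as positive and once with the lipid
class as positive.  Under class imbalance (lipids are the minority among
identified metabolites) the per-class PR AUC is the more informative pair.

Models are compared by ranking each metric across models (higher value ->
smaller rank, ties receiving the average of the tied positions), summing the
four ranks per model, and ranking the rank sums the same way.  The k models
with the smallest rank sums are selected for downstream application.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .curation import LABEL_LIPID

__all__ = [
    "MetricSet",
    "ConfusionCounts",
    "score_predictions",
    "roc_auc",
    "pr_auc",
    "rank_models",
    "select_top_k",
    "confusion",
    "variable_importance",
    "evaluate_on_validation",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("accuracy", "roc_auc", "pr_auc_nonlipid", "pr_auc_lipid")


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, ROC AUC, and the two per-class PR AUCs, all in [0, 1]."""

    accuracy: float
    roc_auc: float
    pr_auc_nonlipid: float
    pr_auc_lipid: float

    def __post_init__(self) -> None:
        for name in METRIC_COLUMNS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_COLUMNS}


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with lipid as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def lipid_recall(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def nonlipid_recall(self) -> float:
        return self.tn / (self.tn + self.fp)


def _as_binary(truth) -> np.ndarray:
    """Labels -> 1 for lipid, 0 for non-lipid; accepts strings or 0/1."""
    arr = np.asarray(truth)
    if arr.dtype.kind in "USO":
        return (arr == LABEL_LIPID).astype(int)
    return arr.astype(int)


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the rank statistic (Mann-Whitney form, tie-corrected).

    Equals trapezoidal integration of the ROC curve over all thresholds;
    tied scores contribute half-credit through midranks.
    """
    y = _as_binary(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC undefined: truth contains a single class")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(y_true: np.ndarray, scores: np.ndarray, positive: int = 1) -> float:
    """Area under the precision-recall curve for one class.

    Thresholds descend through the unique scores of the chosen class'
    probability (tied scores are processed as one block).  Precision is
    replaced by its non-increasing envelope over recall (the interpolated
    precision at recall >= r), and the area is the step-wise sum of
    envelope precision times recall increment.
    """
    y = _as_binary(y_true)
    s = np.asarray(scores, dtype=float)
    if positive == 0:
        y = 1 - y
        s = 1.0 - s
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("PR AUC undefined: truth contains a single class")

    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # threshold block boundaries: last index of each tied-score run
    boundary = np.nonzero(np.diff(s_sorted))[0]
    cut = np.append(boundary, len(s_sorted) - 1)
    tp = np.cumsum(y_sorted)[cut]
    n_pred = cut + 1.0
    precision = tp / n_pred
    recall = tp / n_pos
    # non-increasing precision envelope, from the high-recall end backwards
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    recall_prev = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - recall_prev) * envelope))


def score_predictions(truth, scores, threshold: float = 0.5) -> MetricSet:
    """All four metrics from lipid-probability scores.

    ``scores`` are probabilities of the lipid class; class predictions for
    accuracy use the 0.5 threshold.  Raises if truth is single-class (the
    AUCs are undefined there).
    """
    y = _as_binary(truth)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("truth and scores must have equal length")
    if y.min() == y.max():
        raise ValueError("metrics undefined: truth contains a single class")
    acc = float(np.mean((s >= threshold).astype(int) == y))
    return MetricSet(
        accuracy=acc,
        roc_auc=roc_auc(y, s),
        pr_auc_nonlipid=pr_auc(y, s, positive=0),
        pr_auc_lipid=pr_auc(y, s, positive=1),
    )


def rank_models(metrics: Mapping[str, MetricSet]) -> pd.DataFrame:
    """Build the rank table: per-metric ranks, rank sum, final rank.

    Higher metric values get smaller ranks; ties take the average of the
    tied positions in every column including the final rank.  Each metric's
    ranks therefore sum to n(n+1)/2.  Rows are returned in ascending final
    rank (ties keeping insertion order).
    """
    if len(metrics) < 2:
        raise ValueError("ranking needs at least two models")
    models = list(metrics.keys())
    df = pd.DataFrame(
        {name: [getattr(metrics[m], name) for m in models] for name in METRIC_COLUMNS},
        index=pd.Index(models, name="model"),
    )
    for name in METRIC_COLUMNS:
        df[f"{name}_rank"] = rankdata(-df[name].to_numpy(), method="average")
    rank_cols = [f"{name}_rank" for name in METRIC_COLUMNS]
    df["rank_sum"] = df[rank_cols].sum(axis=1)
    df["final_rank"] = rankdata(df["rank_sum"].to_numpy(), method="average")
    return df.sort_values("final_rank", kind="stable")


def select_top_k(rank_table: pd.DataFrame, k: int) -> list[str]:
    """Models with the k smallest rank sums, ascending.

    Ties at the selection boundary break by accuracy rank, then by the
    table's row order (declaration order).
    """
    if k > len(rank_table):
        raise ValueError(f"k={k} exceeds the number of models ({len(rank_table)})")
    order = sorted(
        range(len(rank_table)),
        key=lambda i: (
            rank_table["rank_sum"].iloc[i],
            rank_table["accuracy_rank"].iloc[i],
            i,
        ),
    )
    return [rank_table.index[i] for i in order[:k]]


def confusion(truth, predicted) -> ConfusionCounts:
    """2x2 confusion counts, lipid positive; inputs are labels, not scores."""
    y = _as_binary(truth)
    p = _as_binary(predicted)
    if len(y) != len(p):
        raise ValueError("truth and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def variable_importance(model, predictor_names: Sequence[str]) -> Optional[dict[str, float]]:
    """Per-predictor importance, or None where the family has no notion of it.

    Tree, forest and boosted families expose impurity-based importances
    (already normalized to sum 1); penalized logistic models report absolute
    standardized coefficients.  Nearest-neighbor, SVM and naive Bayes return
    None.
    """
    from .models import FittedModel  # local import: avoid cycle

    if isinstance(model, FittedModel):
        return model.importance(predictor_names)
    est = model
    if hasattr(est, "feature_importances_"):
        vals = np.asarray(est.feature_importances_, dtype=float)
        total = vals.sum()
        if total > 0:
            vals = vals / total
        return dict(zip(predictor_names, vals.tolist()))
    return None


def evaluate_on_validation(top_models, X_val: np.ndarray, y_val) -> dict[str, dict]:
    """Apply already-fitted models to an external labelled set. No refitting.

    ``top_models`` maps model name -> fitted ComboResult (or any object with
    ``predict_lipid_probability(X)`` and a fitted transform).  Returns per
    model a dict with 'metrics' (MetricSet) and 'confusion' (ConfusionCounts).
    """
    X_val = np.asarray(X_val, dtype=float)
    if len(X_val) == 0:
        raise ValueError("validation set is empty")
    out: dict[str, dict] = {}
    for name, combo in top_models.items():
        scores = combo.predict_lipid_probability(X_val)
        preds = (scores >= 0.5).astype(int)
        out[name] = {
            "metrics": score_predictions(y_val, scores),
            "confusion": confusion(y_val, preds),
        }
    return out
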