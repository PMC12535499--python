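"""Tie-aware rank aggregation over a printed per-model metrics table.

Given only the four testing-set metrics per model (accuracy, ROC AUC, and
the two per-class PR AUCs), rank_models reproduces a full comparison: each
metric ranked across models with average ranks for ties, rank sums, and
final ranks.  The ten metric quadruples below come from an external
evaluation; the aggregation itself is recomputed here.
"""

from mzlipid import MetricSet, rank_models, select_top_k

metrics = {
    "decision_tree": MetricSet(0.865, 0.771, 0.936, 0.511),
    "trimmed_decision_tree": MetricSet(0.865, 0.727, 0.929, 0.443),
    "random_forest": MetricSet(0.838, 0.782, 0.920, 0.619),
    "knn": MetricSet(0.811, 0.809, 0.935, 0.595),
    "elastic_net": MetricSet(0.838, 0.692, 0.849, 0.643),
    "ridge": MetricSet(0.851, 0.690, 0.848, 0.644),
    "lasso": MetricSet(0.838, 0.691, 0.849, 0.643),
    "svm": MetricSet(0.851, 0.672, 0.837, 0.651),
    "naive_bayes": MetricSet(0.797, 0.686, 0.863, 0.646),
    "boosted_tree": MetricSet(0.824, 0.673, 0.848, 0.649),
}

table = rank_models(metrics)
cols = ["accuracy_rank", "roc_auc_rank", "pr_auc_nonlipid_rank",
        "pr_auc_lipid_rank", "rank_sum", "final_rank"]
print(table[cols].to_string())

print("\nnote the fractional ranks: tied metric values share the average of")
print("their positions (e.g. two models tied for ranks 1-2 both get 1.5).")
print(f"\ntop 4 by rank sum: {', '.join(select_top_k(table, 4))}")
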