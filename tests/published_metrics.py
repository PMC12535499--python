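"""The published per-model testing-set metrics used as rank-aggregation input.

These four metric values per model are fixed input data (printed results
of an external evaluation); the package's job is to reproduce the
per-metric ranks, rank sums and final ranks from them exactly.
"""

from mzlipid import MetricSet

# model -> (accuracy, roc_auc, pr_auc_nonlipid, pr_auc_lipid)
PUBLISHED_METRICS = {
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

# model -> (final_rank, rank_sum, acc_rank, roc_rank, pr_no_rank, pr_yes_rank)
PUBLISHED_RANKS = {
    "decision_tree": (1.0, 14.5, 1.5, 3.0, 1.0, 9.0),
    "trimmed_decision_tree": (2.0, 18.5, 1.5, 4.0, 3.0, 10.0),
    "random_forest": (3.0, 19.0, 6.0, 2.0, 4.0, 7.0),
    "knn": (4.0, 20.0, 9.0, 1.0, 2.0, 8.0),
    "elastic_net": (5.5, 23.0, 6.0, 5.0, 6.5, 5.5),
    "ridge": (5.5, 23.0, 3.5, 7.0, 8.5, 4.0),
    "lasso": (7.0, 24.0, 6.0, 6.0, 6.5, 5.5),
    "svm": (8.0, 24.5, 3.5, 10.0, 10.0, 1.0),
    "naive_bayes": (9.0, 26.0, 10.0, 8.0, 5.0, 3.0),
    "boosted_tree": (10.0, 27.5, 8.0, 9.0, 8.5, 2.0),
}

PUBLISHED_TOP4 = {"decision_tree", "trimmed_decision_tree", "random_forest", "knn"}
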