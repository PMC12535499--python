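import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from mzlipid import (
    MetricSet,
    confusion,
    pr_auc,
    rank_models,
    roc_auc,
    score_predictions,
    select_top_k,
)

from published_metrics import PUBLISHED_METRICS, PUBLISHED_RANKS, PUBLISHED_TOP4


def brute_force_roc_auc(y, s):
    """Trapezoidal ROC area over every threshold, O(n^2) oracle."""
    thresholds = np.concatenate(([np.inf], np.sort(np.unique(s))[::-1], [-np.inf]))
    pts = []
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    for thr in thresholds:
        pred = s >= thr
        tpr = np.sum(pred & (y == 1)) / n_pos
        fpr = np.sum(pred & (y == 0)) / n_neg
        pts.append((fpr, tpr))
    pts = sorted(set(pts))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


class TestRocAuc:
    def test_perfect_and_inverted(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert roc_auc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0

    def test_all_tied_scores_give_half(self):
        y = np.array([0, 1, 0, 1])
        assert roc_auc(y, np.full(4, 0.5)) == pytest.approx(0.5)

    def test_matches_brute_force_trapezoid_on_random_instances(self, rng):
        for trial in range(30):
            n = int(rng.integers(5, 51))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            # quantized scores force ties
            s = np.round(rng.random(n), 1)
            assert roc_auc(y, s) == pytest.approx(brute_force_roc_auc(y, s), abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1
        s = rng.random(200)
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(4, dtype=int), np.linspace(0, 1, 4))


class TestPrAuc:
    def test_perfect_separation_gives_one(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        assert pr_auc(y, s, positive=1) == pytest.approx(1.0)
        assert pr_auc(y, s, positive=0) == pytest.approx(1.0)

    def test_envelope_dominates_average_precision(self, rng):
        # the interpolated-precision estimator upper-bounds sklearn's
        # step-wise average precision on the same predictions
        for _ in range(20):
            y = rng.integers(0, 2, size=60)
            y[0], y[1] = 0, 1
            s = np.round(rng.random(60), 2)
            ours = pr_auc(y, s, positive=1)
            ap = average_precision_score(y, s)
            assert ours >= ap - 1e-12
            assert ours <= 1.0

    def test_nonlipid_direction_is_the_flipped_problem(self, rng):
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(40), 2)
        assert pr_auc(y, s, positive=0) == pytest.approx(
            pr_auc(1 - y, 1.0 - s, positive=1), abs=1e-12
        )

    def test_tied_scores_processed_as_one_block(self):
        y = np.array([1, 0, 1, 0])
        s = np.array([0.5, 0.5, 0.5, 0.5])
        # single threshold block: precision = prevalence at recall 1
        assert pr_auc(y, s, positive=1) == pytest.approx(0.5)


class TestScoreAndConfusion:
    def test_score_predictions_thresholds_at_half(self):
        y = np.array(["lipid", "non_lipid", "lipid", "non_lipid"])
        s = np.array([0.9, 0.4, 0.5, 0.6])
        m = score_predictions(y, s)
        assert m.accuracy == pytest.approx(0.75)  # 0.5 counts as lipid

    def test_confusion_counts_and_derived_rates(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        p = np.array([1, 1, 0, 0, 0, 0, 1])
        cm = confusion(y, p)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 1, 3, 1)
        assert cm.accuracy == pytest.approx(5 / 7)
        assert cm.lipid_recall == pytest.approx(2 / 3)
        assert cm.nonlipid_recall == pytest.approx(3 / 4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_predictions(np.array([0, 1]), np.array([0.5]))


class TestRanking:
    def test_each_metric_rank_column_sums_to_triangular_number(self):
        table = rank_models(PUBLISHED_METRICS)
        n = len(table)
        for col in ("accuracy_rank", "roc_auc_rank", "pr_auc_nonlipid_rank", "pr_auc_lipid_rank"):
            assert table[col].sum() == pytest.approx(n * (n + 1) / 2)

    def test_reproduces_published_rank_table(self):
        table = rank_models(PUBLISHED_METRICS)
        for model, (final, rsum, acc_r, roc_r, pr0_r, pr1_r) in PUBLISHED_RANKS.items():
            row = table.loc[model]
            assert row["final_rank"] == pytest.approx(final), model
            assert row["rank_sum"] == pytest.approx(rsum), model
            assert row["accuracy_rank"] == pytest.approx(acc_r), model
            assert row["roc_auc_rank"] == pytest.approx(roc_r), model
            assert row["pr_auc_nonlipid_rank"] == pytest.approx(pr0_r), model
            assert row["pr_auc_lipid_rank"] == pytest.approx(pr1_r), model

    def test_rows_sorted_by_final_rank(self):
        table = rank_models(PUBLISHED_METRICS)
        assert list(table["final_rank"]) == sorted(table["final_rank"])
        assert table.index[0] == "decision_tree"

    def test_select_top_k(self):
        table = rank_models(PUBLISHED_METRICS)
        assert set(select_top_k(table, 4)) == PUBLISHED_TOP4

    def test_identical_metrics_all_tie(self):
        same = MetricSet(0.8, 0.7, 0.9, 0.5)
        table = rank_models({"a": same, "b": same, "c": same})
        assert list(table["final_rank"]) == [2.0, 2.0, 2.0]
        assert list(table["rank_sum"]) == [8.0, 8.0, 8.0]

    def test_fewer_than_two_models_rejected(self):
        with pytest.raises(ValueError):
            rank_models({"only": MetricSet(0.8, 0.7, 0.9, 0.5)})

    def test_k_larger_than_table_rejected(self):
        table = rank_models(PUBLISHED_METRICS)
        with pytest.raises(ValueError):
            select_top_k(table, 11)
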