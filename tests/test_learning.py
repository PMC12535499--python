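import numpy as np
import pytest

from mzlipid import (
    FAMILIES,
    FittedModel,
    apply_condition,
    balance_classes,
    default_grids,
    enumerate_conditions,
    grid_points,
    make_split,
    run_grid,
    stable_seed,
    tune_model,
)
from mzlipid.learning import PreprocessorCondition


def two_cluster_data(rng, n0=60, n1=30, gap=6.0):
    """Linearly separable two-column data: minority class 1 at low x0."""
    X0 = rng.normal([gap, 0.0], 1.0, size=(n0, 2))
    X1 = rng.normal([0.0, 0.0], 1.0, size=(n1, 2))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return X, y


class TestConditions:
    def test_exactly_twelve_canonical_conditions(self):
        conditions = enumerate_conditions()
        assert len(conditions) == 12
        assert len({c.name for c in conditions}) == 12
        assert conditions[0].name == "basic" and conditions[0].steps == ()

    def test_normalize_and_scale_never_cooccur(self):
        for c in enumerate_conditions():
            assert not ("normalize" in c.steps and "scale" in c.steps)
        with pytest.raises(ValueError):
            PreprocessorCondition("bad", ("normalize", "scale"))

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError):
            PreprocessorCondition("bad", ("whiten",))

    def test_grid_cardinality_is_120(self):
        assert len(enumerate_conditions()) * len(FAMILIES) == 120


class TestBalanceClasses:
    def test_reaches_parity_and_preserves_originals(self, rng):
        X, y = two_cluster_data(rng)
        Xb, yb = balance_classes(X, y, rng=rng)
        assert int(yb.sum()) == len(yb) - int(yb.sum())
        assert np.array_equal(Xb[: len(X)], X)
        assert np.array_equal(yb[: len(y)], y)

    def test_synthetics_lie_in_minority_convex_hull_per_coordinate(self, rng):
        X, y = two_cluster_data(rng)
        Xb, yb = balance_classes(X, y, rng=rng)
        synth = Xb[len(X):]
        minority = X[y == 1]
        assert np.all(synth.min(axis=0) >= minority.min(axis=0) - 1e-12)
        assert np.all(synth.max(axis=0) <= minority.max(axis=0) + 1e-12)
        assert np.all(yb[len(y):] == 1)

    def test_already_balanced_returned_unchanged(self, rng):
        X, y = two_cluster_data(rng, n0=20, n1=20)
        Xb, yb = balance_classes(X, y, rng=rng)
        assert Xb is X and yb is y

    def test_single_minority_example_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            balance_classes(X, y, rng=rng)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            balance_classes(rng.normal(size=(4, 2)), np.zeros(4, dtype=int), rng=rng)

    def test_deterministic_under_seed(self, rng):
        X, y = two_cluster_data(rng)
        Xa, _ = balance_classes(X, y, rng=np.random.default_rng(7))
        Xb, _ = balance_classes(X, y, rng=np.random.default_rng(7))
        assert np.array_equal(Xa, Xb)


class TestApplyCondition:
    def test_normalize_state_comes_from_training_only(self, rng):
        X, y = two_cluster_data(rng)
        X_eval = rng.normal(size=(10, 2)) + 100.0  # far outside training
        cond = PreprocessorCondition("normalize", ("normalize",))
        Xt, yt, Xe, state = apply_condition(cond, X, y, X_eval=X_eval, rng=rng)
        assert np.allclose(Xt.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Xt.std(axis=0, ddof=1), 1.0, atol=1e-9)
        # eval transformed with training statistics, not its own
        assert np.allclose(Xe, (X_eval - state.center) / state.scale)
        assert Xe.mean() > 10  # would be ~0 if eval statistics had leaked

    def test_scale_divides_without_centering(self, rng):
        X, y = two_cluster_data(rng)
        cond = PreprocessorCondition("scale", ("scale",))
        Xt, _, _, state = apply_condition(cond, X, y, rng=rng)
        assert state.center is None
        assert np.allclose(Xt, X / X.std(axis=0, ddof=1))

    def test_reduce_drops_later_of_a_correlated_pair(self, rng):
        x0 = rng.normal(size=200)
        X = np.column_stack([x0, x0 * 2.0 + rng.normal(scale=1e-6, size=200)])
        y = (x0 > 0).astype(int)
        cond = PreprocessorCondition("reduce", ("reduce",))
        _, _, _, state = apply_condition(cond, X, y, rng=rng)
        assert state.keep_columns == [0]

    def test_reduce_keeps_uncorrelated_columns(self, rng):
        X, y = two_cluster_data(rng)
        cond = PreprocessorCondition("reduce", ("reduce",))
        _, _, _, state = apply_condition(cond, X, y, rng=rng)
        assert state.keep_columns == [0, 1]

    def test_balance_only_augments_training(self, rng):
        X, y = two_cluster_data(rng)
        X_eval = rng.normal(size=(8, 2))
        cond = PreprocessorCondition("balance", ("balance",))
        Xt, yt, Xe, _ = apply_condition(cond, X, y, X_eval=X_eval, rng=rng)
        assert len(Xt) == 120 and len(Xe) == 8
        assert np.array_equal(Xe, X_eval)

    def test_step_order_reduce_then_balance_then_standardize(self, rng):
        X, y = two_cluster_data(rng)
        cond = PreprocessorCondition(
            "reduce+balance+normalize", ("reduce", "balance", "normalize")
        )
        Xt, yt, _, state = apply_condition(cond, X, y, rng=rng)
        assert Xt.shape == (120, len(state.keep_columns))
        assert np.allclose(Xt.mean(axis=0), 0.0, atol=1e-9)

    def test_zero_variance_predictor_warns_and_passes_through(self, rng):
        X = np.column_stack([np.full(20, 3.0), rng.normal(size=20)])
        y = np.array([0, 1] * 10)
        cond = PreprocessorCondition("normalize", ("normalize",))
        with pytest.warns(UserWarning, match="zero-variance"):
            Xt, _, _, _ = apply_condition(cond, X, y, rng=rng)
        assert np.allclose(Xt[:, 0], 3.0)


class TestSplit:
    def test_published_split_sizes_226_plus_68(self):
        y = np.array([0] * 226 + [1] * 68)
        plan = make_split(y, test_fraction=0.25, n_folds=10, seed=11)
        y_test = y[plan.test_indices]
        assert len(plan.test_indices) == 74
        assert int(y_test.sum()) == 17
        assert len(y_test) - int(y_test.sum()) == 57
        assert len(plan.train_indices) == 220

    def test_half_up_rounding_per_class(self):
        # 10 * 0.25 = 2.5 -> 3 test examples for a 10-example class
        y = np.array([0] * 10 + [1] * 10)
        plan = make_split(y, test_fraction=0.25, n_folds=3, seed=0)
        y_test = y[plan.test_indices]
        assert int((y_test == 0).sum()) == 3 and int((y_test == 1).sum()) == 3

    def test_partition_is_exact_and_disjoint(self):
        y = np.array([0] * 40 + [1] * 20)
        plan = make_split(y, n_folds=5, seed=3)
        all_idx = np.sort(np.concatenate([plan.train_indices, plan.test_indices]))
        assert np.array_equal(all_idx, np.arange(60))

    def test_folds_are_stratified_within_one_example(self):
        y = np.array([0] * 160 + [1] * 40)
        plan = make_split(y, n_folds=10, seed=5)
        y_train = y[plan.train_indices]
        for f in range(1, plan.n_folds + 1):
            in_fold = plan.fold_assignments == f
            n1 = int(y_train[in_fold].sum())
            n0 = int(in_fold.sum()) - n1
            assert abs(n1 - 3) <= 1 and abs(n0 - 12) <= 1

    def test_deterministic_and_seed_sensitive(self):
        y = np.array([0] * 40 + [1] * 20)
        a = make_split(y, seed=1, n_folds=5)
        b = make_split(y, seed=1, n_folds=5)
        c = make_split(y, seed=2, n_folds=5)
        assert np.array_equal(a.test_indices, b.test_indices)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)
        assert not np.array_equal(a.test_indices, c.test_indices)

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError):
            make_split(np.array([0] * 30 + [1] * 3))

    def test_too_few_training_examples_for_folds_rejected(self):
        y = np.array([0] * 40 + [1] * 8)
        with pytest.raises(ValueError, match="folds"):
            make_split(y, n_folds=10, seed=0)


class TestModels:
    def test_every_family_fits_and_emits_probabilities(self, rng):
        X, y = two_cluster_data(rng, n0=80, n1=60)
        for family in FAMILIES:
            params = grid_points(default_grids()[family])[0]
            if family == "naive_bayes":
                params = {"var_smoothing": 1e-9}
            m = FittedModel.fit(family, params, X, y, seed=stable_seed(0, family))
            p = m.predict_lipid_probability(X)
            assert p.shape == (len(X),)
            assert np.all((p >= 0.0) & (p <= 1.0)), family
            acc = float(np.mean(m.predict_label(X) == y))
            assert acc >= 0.9, f"{family} training accuracy {acc}"

    def test_importance_surface_by_family(self, rng):
        X, y = two_cluster_data(rng, n0=80, n1=60)
        grids = default_grids()
        for family in FAMILIES:
            params = grid_points(grids[family])[0]
            if family == "naive_bayes":
                params = {"var_smoothing": 1e-9}
            m = FittedModel.fit(family, params, X, y, seed=1)
            imp = m.importance(["a", "b"])
            if family in ("knn", "svm", "naive_bayes"):
                assert imp is None
            else:
                assert set(imp) == {"a", "b"}
                assert all(v >= 0 for v in imp.values())

    def test_stable_seed_is_deterministic_and_label_sensitive(self):
        assert stable_seed(5, "a", 1) == stable_seed(5, "a", 1)
        assert stable_seed(5, "a") != stable_seed(5, "b")
        assert stable_seed(5, "a") != stable_seed(6, "a")
        assert 0 <= stable_seed(123456789, "x") < 2**31

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown model family"):
            FittedModel.fit("perceptron", {}, np.zeros((4, 2)), np.array([0, 1, 0, 1]), seed=0)


class TestTuning:
    def test_tune_model_separable_reaches_high_cv_accuracy(self, rng):
        X, y = two_cluster_data(rng, n0=60, n1=40)
        plan = make_split(y, test_fraction=0.25, n_folds=5, seed=0)
        cond = enumerate_conditions()[0]
        combo = tune_model(
            "decision_tree",
            cond,
            X[plan.train_indices],
            y[plan.train_indices],
            plan.fold_assignments,
            seed=0,
            grid={"ccp_alpha": [0.001], "max_depth": [2, 4], "min_samples_leaf": [2]},
        )
        assert combo.cv_accuracy > 0.9
        assert combo.tuned_values["max_depth"] in (2, 4)
        assert np.all(np.isin(combo.predict_label(X), [0, 1]))

    def test_tuning_is_deterministic(self, rng):
        X, y = two_cluster_data(rng, n0=60, n1=40)
        plan = make_split(y, test_fraction=0.25, n_folds=5, seed=0)
        cond = enumerate_conditions()[4]  # balance
        kwargs = dict(
            grid={"n_neighbors": [3, 5]},
        )
        a = tune_model("knn", cond, X[plan.train_indices], y[plan.train_indices],
                       plan.fold_assignments, seed=9, **kwargs)
        b = tune_model("knn", cond, X[plan.train_indices], y[plan.train_indices],
                       plan.fold_assignments, seed=9, **kwargs)
        assert a.cv_accuracy == b.cv_accuracy
        assert a.tuned_values == b.tuned_values
        X_probe = rng.normal(size=(20, 2))
        assert np.array_equal(
            a.predict_lipid_probability(X_probe), b.predict_lipid_probability(X_probe)
        )

    def test_fit_failures_scored_zero_with_warning(self, rng):
        X, y = two_cluster_data(rng, n0=30, n1=20)
        plan = make_split(y, test_fraction=0.25, n_folds=5, seed=0)
        bad_grid = {"ccp_alpha": [-5.0], "max_depth": [2], "min_samples_leaf": [2]}
        with pytest.warns(UserWarning, match="scored 0"):
            with pytest.raises(Exception):
                # every grid point fails, so the refit fails too; the
                # warning must still have been emitted for each fold
                tune_model(
                    "decision_tree", enumerate_conditions()[0],
                    X[plan.train_indices], y[plan.train_indices],
                    plan.fold_assignments, seed=0, grid=bad_grid,
                )

    def test_empty_grid_rejected(self, rng):
        X, y = two_cluster_data(rng, n0=30, n1=20)
        plan = make_split(y, test_fraction=0.25, n_folds=5, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            tune_model(
                "knn", enumerate_conditions()[0],
                X[plan.train_indices], y[plan.train_indices],
                plan.fold_assignments, seed=0, grid={},
            )


class TestRunGrid:
    def test_families_times_conditions_results(self, rng):
        X, y = two_cluster_data(rng, n0=60, n1=40)
        plan = make_split(y, test_fraction=0.25, n_folds=5, seed=0)
        conditions = enumerate_conditions()[:3]
        results, best = run_grid(
            X[plan.train_indices], y[plan.train_indices], plan.fold_assignments,
            seed=0,
            families=("knn", "naive_bayes"),
            conditions=conditions,
            grids={"knn": {"n_neighbors": [3]}, "naive_bayes": {"var_smoothing": [1e-9]}},
        )
        assert len(results) == 6
        assert set(best) == {"knn", "naive_bayes"}
        seen = [(r.family, r.condition.name) for r in results]
        assert len(set(seen)) == 6

    def test_best_by_family_first_wins_ties(self, rng):
        X, y = two_cluster_data(rng, n0=60, n1=40, gap=12.0)  # trivially separable
        plan = make_split(y, test_fraction=0.25, n_folds=5, seed=0)
        conditions = enumerate_conditions()[:3]
        results, best = run_grid(
            X[plan.train_indices], y[plan.train_indices], plan.fold_assignments,
            seed=0, families=("knn",), conditions=conditions,
            grids={"knn": {"n_neighbors": [3]}},
        )
        accs = [r.cv_accuracy for r in results]
        first_max = accs.index(max(accs))
        assert best["knn"].condition.name == conditions[first_max].name

    def test_unknown_family_rejected(self, rng):
        X, y = two_cluster_data(rng, n0=30, n1=20)
        plan = make_split(y, test_fraction=0.25, n_folds=5, seed=0)
        with pytest.raises(ValueError, match="unknown model family"):
            run_grid(
                X[plan.train_indices], y[plan.train_indices],
                plan.fold_assignments, seed=0, families=("mlp",),
            )
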