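"""Model selection on a reduced grid: preprocessors x families x CV.

The full framework crosses 12 preprocessing conditions with 10 model
families (120 combinations, a few minutes of compute).  This example keeps
the workflow identical but restricts it to 3 conditions x 4 families so it
finishes in seconds: stratified 75/25 split, per-fold preprocessing,
grid-tuned 5-fold CV, held-out scoring, and tie-aware rank aggregation.
"""

from mzlipid import GradientProgram, enumerate_conditions, generate, run_pipeline, scenario

program = GradientProgram()
table, taxonomy, _ = generate(scenario("default", n_features=3000, seed=7), program)

result = run_pipeline(
    table,
    taxonomy,
    program,
    seed=7,
    families=("decision_tree", "knn", "naive_bayes", "lasso"),
    conditions=enumerate_conditions()[:3],  # basic, reduce, normalize
    n_folds=5,
    top_k=2,
)

print("best condition and CV accuracy per family:")
for family, combo in result.best_by_family.items():
    print(f"  {family:<14} {combo.condition.name:<10} CV {combo.cv_accuracy:.3f} "
          f"tuned {combo.tuned_values}")

print("\nheld-out test rank table:")
cols = ["accuracy", "roc_auc", "pr_auc_nonlipid", "pr_auc_lipid", "rank_sum", "final_rank"]
print(result.rank_table[cols].round(3).to_string())

print(f"\nselected top models: {', '.join(result.top_models)}")
best = result.top_models[0]
cm = result.test_confusions[best]
print(f"{best} test confusion: tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn}")
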