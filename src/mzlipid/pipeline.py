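"""End-to-end orchestration: curated table in, ranked models out.

The sequence mirrors the framework's workflow: annotate the gradient
composition, curate and label, split 75/25 stratified, evaluate the 120
model x preprocessor grid by 10-fold CV on the training partition, score
each family's best combination on the held-out test partition, rank the
families across the four metrics, select the top k, and — when a
validation table is supplied — apply the selected models to it as fitted
(no refit, no re-tuning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .curation import LABEL_LIPID, CurationReport, LabeledExample, curate
from .evaluation import (
    ConfusionCounts,
    MetricSet,
    confusion,
    evaluate_on_validation,
    rank_models,
    score_predictions,
    select_top_k,
)
from .gradient import GradientProgram, annotate_gradient
from .io import FeatureTable, TaxonomyMap
from .learning import ComboResult, SplitPlan, make_split, run_grid
from .models import FAMILIES, PREDICTOR_NAMES

logger = logging.getLogger("mzlipid")

__all__ = ["PipelineResult", "examples_to_arrays", "run_pipeline"]


def examples_to_arrays(examples: Sequence[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    """Labeled examples -> (X, y) with columns (gradient_pct_a, mz), y=1 lipid."""
    X = np.array([[ex.gradient_pct_a, ex.mz] for ex in examples], dtype=float)
    y = np.array([1 if ex.label == LABEL_LIPID else 0 for ex in examples], dtype=int)
    return X, y


@dataclass
class PipelineResult:
    """Everything a run produces, ready for reporting or persistence."""

    curation_report: CurationReport
    split: SplitPlan
    combos: list[ComboResult]
    best_by_family: dict[str, ComboResult]
    test_metrics: dict[str, MetricSet]
    rank_table: pd.DataFrame
    top_models: list[str]
    test_confusions: dict[str, ConfusionCounts]
    importances: dict[str, Optional[dict[str, float]]]
    validation: Optional[dict[str, dict]] = None
    validation_report: Optional[CurationReport] = None

    def combo_frame(self) -> pd.DataFrame:
        import json

        return pd.DataFrame(
            {
                "family": [c.family for c in self.combos],
                "condition": [c.condition.name for c in self.combos],
                "cv_accuracy": [c.cv_accuracy for c in self.combos],
                "tuned_values": [json.dumps(c.tuned_values) for c in self.combos],
            }
        )


def run_pipeline(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    program: GradientProgram,
    seed: int,
    validation_table: Optional[FeatureTable] = None,
    validation_taxonomy: Optional[TaxonomyMap] = None,
    rt_low: float = 1.0,
    rt_high: float = 14.0,
    preferred_polarity: str = "negative",
    lipid_class: Optional[str] = None,
    test_fraction: float = 0.25,
    n_folds: int = 10,
    families: Sequence[str] = FAMILIES,
    conditions=None,
    grids: Optional[Mapping] = None,
    k_neighbors: int = 5,
    reduce_threshold: float = 0.9,
    top_k: int = 4,
) -> PipelineResult:
    """Run the full framework on one (discovery) table.

    ``validation_table``, when given, is curated with the same rules and the
    selected models are applied to it without refitting.
    """
    from .curation import DEFAULT_LIPID_CLASS

    lipid_class = lipid_class or DEFAULT_LIPID_CLASS
    curation_kwargs = dict(
        rt_low=rt_low,
        rt_high=rt_high,
        preferred_polarity=preferred_polarity,
        lipid_class=lipid_class,
    )

    logger.info("annotating gradient composition for %d features", len(table))
    annotated = annotate_gradient(table, program)
    examples, report = curate(annotated, taxonomy, **curation_kwargs)
    for line in report.summary_lines():
        logger.info("curation: %s", line)
    X, y = examples_to_arrays(examples)

    split = make_split(y, test_fraction=test_fraction, n_folds=n_folds, seed=seed)
    logger.info(
        "split: %d train / %d test (%d lipid in test)",
        len(split.train_indices),
        len(split.test_indices),
        int(y[split.test_indices].sum()),
    )
    X_train, y_train = X[split.train_indices], y[split.train_indices]
    X_test, y_test = X[split.test_indices], y[split.test_indices]

    combos, best_by_family = run_grid(
        X_train,
        y_train,
        split.fold_assignments,
        seed=seed,
        families=families,
        conditions=conditions,
        grids=grids,
        k_neighbors=k_neighbors,
        reduce_threshold=reduce_threshold,
        progress=lambda c: logger.info(
            "tuned %s / %s: CV accuracy %.3f", c.family, c.condition.name, c.cv_accuracy
        ),
    )

    test_metrics: dict[str, MetricSet] = {}
    test_confusions: dict[str, ConfusionCounts] = {}
    importances: dict[str, Optional[dict[str, float]]] = {}
    for family in families:
        combo = best_by_family[family]
        scores = combo.predict_lipid_probability(X_test)
        test_metrics[family] = score_predictions(y_test, scores)
        test_confusions[family] = confusion(y_test, (scores >= 0.5).astype(int))
        importances[family] = combo.model.importance(
            [PREDICTOR_NAMES[i] for i in combo.state.keep_columns]
        )

    rank_table = rank_models(test_metrics)
    top = select_top_k(rank_table, top_k)
    logger.info("top-%d models by rank sum: %s", top_k, ", ".join(top))

    validation = None
    validation_report = None
    if validation_table is not None:
        val_tax = validation_taxonomy if validation_taxonomy is not None else taxonomy
        val_annotated = annotate_gradient(validation_table, program)
        val_examples, validation_report = curate(val_annotated, val_tax, **curation_kwargs)
        X_val, y_val = examples_to_arrays(val_examples)
        lo, hi = X_train.min(axis=0), X_train.max(axis=0)
        n_outside = int(np.sum((X_val < lo) | (X_val > hi)))
        if n_outside:
            logger.warning(
                "%d validation predictor values fall outside the training range",
                n_outside,
            )
        validation = evaluate_on_validation(
            {name: best_by_family[name] for name in top}, X_val, y_val
        )

    return PipelineResult(
        curation_report=report,
        split=split,
        combos=combos,
        best_by_family=best_by_family,
        test_metrics=test_metrics,
        rank_table=rank_table,
        top_models=top,
        test_confusions=test_confusions,
        importances=importances,
        validation=validation,
        validation_report=validation_report,
    )
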