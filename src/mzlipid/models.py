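"""The ten model families and their default tuning grids.

Every family exposes the same minimal contract through :class:`FittedModel`:
``fit`` on (n, p) predictor arrays with 0/1 outcomes (1 = lipid) and
``predict_lipid_probability`` returning the lipid-class probability; class
predictions threshold that probability at 0.5.

Notes on individual families:

* ``trimmed_decision_tree`` is a restrained tree: depth capped at 4 and
  cost-complexity pruned, tuning only the pruning strength and leaf size,
  while the plain ``decision_tree`` tunes depth, pruning and leaf size over
  a wider grid.  The restrained variant trades lipid recall for less
  overfitting.
* The penalized logistic family (lasso / ridge / elastic_net) standardizes
  predictors internally before fitting, the way glmnet does, so the penalty
  acts on comparable scales regardless of which preprocessor condition is
  active; reported coefficients are therefore already standardized.
* SVM probabilities come from the estimator's internal Platt-style
  calibration, fitted on whatever (fold-internal) data ``fit`` receives.
* Grids are finite and ordered; tuning walks them in the documented order
  and breaks ties by taking the first maximum.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import xgboost as xgb
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FAMILIES",
    "PREDICTOR_NAMES",
    "default_grids",
    "grid_points",
    "build_estimator",
    "FittedModel",
    "stable_seed",
]

# Canonical predictor order used everywhere downstream: the gradient
# composition (%A at elution) is the primary predictor, m/z the second.
PREDICTOR_NAMES = ("gradient_pct_a", "mz")

FAMILIES = (
    "naive_bayes",
    "decision_tree",
    "trimmed_decision_tree",
    "svm",
    "random_forest",
    "boosted_tree",
    "lasso",
    "ridge",
    "elastic_net",
    "knn",
)

_PENALTIES = [float(x) for x in np.logspace(-4, 0, 10)]
_CCP_ALPHAS = [float(x) for x in np.logspace(-4, -1, 5)]


def default_grids() -> dict[str, dict[str, list]]:
    """Ordered default hyperparameter grids, fully overridable via config."""
    return {
        "naive_bayes": {"var_smoothing": [0.0, 1e-9, 1e-6]},
        "decision_tree": {
            "ccp_alpha": list(_CCP_ALPHAS),
            "max_depth": [2, 4, 8, 16],
            "min_samples_leaf": [2, 10, 20],
        },
        "trimmed_decision_tree": {
            "ccp_alpha": list(_CCP_ALPHAS),
            "min_samples_leaf": [2, 10, 20],
        },
        "svm": {"C": [0.1, 1.0, 10.0]},
        "random_forest": {
            "max_features": [1, 2],
            "min_samples_leaf": [2, 10, 20],
        },
        "boosted_tree": {
            "n_estimators": [100, 500],
            "learning_rate": [0.01, 0.1, 0.3],
            "max_depth": [2, 4, 6],
        },
        "lasso": {"penalty_strength": list(_PENALTIES)},
        "ridge": {"penalty_strength": list(_PENALTIES)},
        "elastic_net": {
            "penalty_strength": list(_PENALTIES),
            "l1_ratio": [0.25, 0.5, 0.75],
        },
        "knn": {"n_neighbors": [3, 5, 9, 15, 25]},
    }


def grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    """Expand an ordered grid into the documented evaluation order."""
    points: list[dict] = [{}]
    for param, values in grid.items():
        points = [{**pt, param: v} for pt in points for v in values]
    return points


class _ProbabilityForest:
    """Random forest of regression trees on the 0/1 outcome.

    Fitting regression trees to the binary outcome and averaging leaf means
    yields class-probability predictions (the probability-forest approach).
    Squared-error hessians are 1 per row, so ``min_child_weight`` enforces
    an exact minimum leaf sample count, and ``colsample_bynode`` draws the
    candidate predictors per split.  Rows are subsampled at the bootstrap
    rate (0.632, without replacement) per tree.
    """

    def __init__(self, n_estimators: int, max_features: int, min_samples_leaf: int, seed: int):
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self._n_estimators = n_estimators
        self._seed = seed
        self._booster = None
        self._n_features = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ProbabilityForest":
        y = np.asarray(y, dtype=float)
        self.classes_ = np.array([0, 1])
        if y.min() == y.max():
            raise ValueError("probability forest needs both classes present")
        self._n_features = X.shape[1]
        self._booster = xgb.XGBRFRegressor(
            n_estimators=self._n_estimators,
            max_depth=12,
            min_child_weight=self.min_samples_leaf,
            colsample_bynode=self.max_features / X.shape[1],
            subsample=0.632,
            reg_lambda=0.0,
            tree_method="hist",
            n_jobs=1,
            random_state=self._seed,
            verbosity=0,
        )
        self._booster.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = np.clip(self._booster.predict(X), 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    @property
    def feature_importances_(self) -> np.ndarray:
        vals = np.asarray(self._booster.feature_importances_, dtype=float)
        if vals.sum() == 0:
            return vals
        return vals / vals.sum()


def _logistic(params: dict, l1_ratio: Optional[float], seed: int) -> Pipeline:
    lam = params["penalty_strength"]
    # C is the inverse regularization strength; lam == 0 is excluded by grid
    common = dict(C=1.0 / lam, max_iter=10000, random_state=seed)
    if l1_ratio is None:
        est = LogisticRegression(l1_ratio=0.0, solver="lbfgs", **common)
    elif l1_ratio == 1.0:
        est = LogisticRegression(l1_ratio=1.0, solver="liblinear", **common)
    else:
        est = LogisticRegression(l1_ratio=l1_ratio, solver="saga", tol=1e-4, **common)
    return Pipeline([("standardize", StandardScaler()), ("logit", est)])


def build_estimator(family: str, params: Mapping, seed: int):
    """Instantiate an unfitted estimator for one family and grid point."""
    p = dict(params)
    if family == "naive_bayes":
        return GaussianNB(var_smoothing=p["var_smoothing"])
    if family == "decision_tree":
        return DecisionTreeClassifier(
            ccp_alpha=p["ccp_alpha"],
            max_depth=p["max_depth"],
            min_samples_leaf=p["min_samples_leaf"],
            random_state=seed,
        )
    if family == "trimmed_decision_tree":
        return DecisionTreeClassifier(
            ccp_alpha=p["ccp_alpha"],
            max_depth=4,
            min_samples_leaf=p["min_samples_leaf"],
            random_state=seed,
        )
    if family == "svm":
        # Platt-style sigmoid calibration fitted by internal CV on whatever
        # (fold-internal) training data the estimator receives
        return CalibratedClassifierCV(
            SVC(C=p["C"], kernel="rbf", gamma="scale", random_state=seed),
            method="sigmoid",
            cv=5,
            ensemble=False,
        )
    if family == "random_forest":
        # probability forest: 500 regression trees on the 0/1 outcome,
        # bagged rows, per-split candidate-predictor sampling, exact
        # min-leaf sample counts (unit hessians under squared error)
        return _ProbabilityForest(
            n_estimators=500,
            max_features=p["max_features"],
            min_samples_leaf=p["min_samples_leaf"],
            seed=seed,
        )
    if family == "boosted_tree":
        return xgb.XGBClassifier(
            n_estimators=p["n_estimators"],
            learning_rate=p["learning_rate"],
            max_depth=p["max_depth"],
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
    if family == "lasso":
        return _logistic(p, l1_ratio=1.0, seed=seed)
    if family == "ridge":
        return _logistic(p, l1_ratio=None, seed=seed)
    if family == "elastic_net":
        return _logistic(p, l1_ratio=p["l1_ratio"], seed=seed)
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=p["n_neighbors"])
    raise ValueError(f"unknown model family {family!r}; known: {', '.join(FAMILIES)}")


_IMPORTANCE_FAMILIES = {
    "decision_tree",
    "trimmed_decision_tree",
    "random_forest",
    "boosted_tree",
}
_COEF_FAMILIES = {"lasso", "ridge", "elastic_net"}


@dataclass
class FittedModel:
    """A fitted estimator from one family, with the uniform scoring surface."""

    family: str
    estimator: object
    params: dict = field(default_factory=dict)

    @classmethod
    def fit(cls, family: str, params: Mapping, X: np.ndarray, y: np.ndarray, seed: int):
        est = build_estimator(family, params, seed)
        est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return cls(family=family, estimator=est, params=dict(params))

    def predict_lipid_probability(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_) if not isinstance(
            self.estimator, Pipeline
        ) else list(self.estimator[-1].classes_)
        if 1 not in classes:  # degenerate fit on single-class data
            return np.zeros(len(X))
        return proba[:, classes.index(1)]

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_lipid_probability(X) >= 0.5).astype(int)

    def importance(self, predictor_names: Sequence[str]) -> Optional[dict[str, float]]:
        """Normalized impurity importances, |standardized coefficients|, or None."""
        if self.family in _IMPORTANCE_FAMILIES:
            vals = np.asarray(self.estimator.feature_importances_, dtype=float)
            total = vals.sum()
            if total > 0:
                vals = vals / total
            return dict(zip(predictor_names, vals.tolist()))
        if self.family in _COEF_FAMILIES:
            logit = self.estimator[-1]
            vals = np.abs(np.asarray(logit.coef_, dtype=float).ravel())
            return dict(zip(predictor_names, vals.tolist()))
        return None


def stable_seed(base_seed: int, *labels) -> int:
    """Deterministic 31-bit child seed from a base seed and string/int labels."""
    h = base_seed & 0x7FFFFFFF
    for label in labels:
        h = zlib.crc32(str(label).encode(), h) & 0x7FFFFFFF
    return h
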