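"""Comparator classifiers targeted at balanced accuracy.

Two compensatory benchmarks against which the fast-and-frugal trees are
judged:

* an **unconstrained decision tree** (CART-style recursive partitioning) in
  which misclassified positives are weighted by the ratio of negative to
  positive training cases, so that impurity splitting chases balanced rather
  than unweighted accuracy.  Tree growth is delegated to
  :class:`sklearn.tree.DecisionTreeClassifier`; the contract of this module is
  the weight ratio and the two growth parameters (minimum splitting size 20,
  cost-complexity parameter 0.00001), which are passed through verbatim.

* a **base-rate-thresholded logistic regression**: an unpenalised
  maximum-likelihood fit on the same cues, with the probability cut for
  calling a case positive set to the positive base rate observed in the
  training set (rather than 0.5).  With a ~25% positive class, cutting at the
  base rate trades specificity for sensitivity and thereby targets balanced
  accuracy.  A probability exactly at the threshold counts as positive.

Ordinal cues enter the regression as their numeric codes; binary cues as 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .cohort import CohortTable
from .metrics import PerfStats, perf_from_predictions

__all__ = [
    "WeightedTreeParams",
    "WeightedTreeModel",
    "WeightedTreeResults",
    "BaseRateLogitModel",
    "BaseRateLogitResults",
]


def _training_arrays(cohort: CohortTable, cues: Sequence[str]):
    cohort.require_outcome()
    X = cohort.data[list(cues)]
    if X.isna().to_numpy().any():
        raise ValueError("training data contain missing values; impute first")
    y = cohort.outcome
    if y.min() == y.max():
        raise ValueError("training outcome contains a single class")
    return X.to_numpy(dtype=float), y


def _predict_frame(table: CohortTable | pd.DataFrame, cues: Sequence[str]) -> np.ndarray:
    frame = table.data if isinstance(table, CohortTable) else table
    missing = [c for c in cues if c not in frame.columns]
    if missing:
        raise ValueError(f"table is missing model cues {missing}")
    X = frame[list(cues)]
    if len(X) and X.isna().to_numpy().any():
        raise ValueError("prediction data contain missing values; impute first")
    return X.to_numpy(dtype=float)


@dataclass(frozen=True)
class WeightedTreeParams:
    """Growth settings of the weighted unconstrained tree."""

    min_split: int = 20
    complexity: float = 0.00001

    def __post_init__(self) -> None:
        if self.min_split < 2:
            raise ValueError("min_split must be >= 2")
        if self.complexity < 0:
            raise ValueError("complexity must be >= 0")


class WeightedTreeModel:
    """Misclassification-weighted recursive-partitioning comparator."""

    def __init__(self, cohort: CohortTable, params: WeightedTreeParams | None = None,
                 cues: Sequence[str] | None = None, random_state: int = 0) -> None:
        self.cohort = cohort
        self.params = params or WeightedTreeParams()
        self.cues = list(cues) if cues is not None else cohort.cue_names
        self.random_state = random_state

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "WeightedTreeModel":
        return cls(CohortTable(frame), **kwargs)

    def fit(self) -> "WeightedTreeResults":
        X, y = _training_arrays(self.cohort, self.cues)
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        positive_weight = n_neg / n_pos
        clf = DecisionTreeClassifier(
            min_samples_split=self.params.min_split,
            ccp_alpha=self.params.complexity,
            class_weight={0: 1.0, 1: positive_weight},
            random_state=self.random_state,
        )
        clf.fit(X, y)
        return WeightedTreeResults(self, clf, positive_weight)


class WeightedTreeResults:
    """Fitted weighted tree; prediction takes the weighted-majority leaf class."""

    def __init__(self, model: WeightedTreeModel, clf: DecisionTreeClassifier,
                 positive_weight: float) -> None:
        self.model = model
        self.clf = clf
        self.positive_weight = positive_weight
        self.cues = model.cues

    def predict(self, table: CohortTable | pd.DataFrame) -> np.ndarray:
        X = _predict_frame(table, self.cues)
        if len(X) == 0:
            return np.zeros(0, dtype=np.int64)
        return self.clf.predict(X).astype(np.int64)

    def evaluate(self, table: CohortTable) -> PerfStats:
        table.require_outcome()
        return perf_from_predictions(table.outcome, self.predict(table))

    def to_json(self) -> str:
        t = self.clf.tree_
        doc = {
            "kind": "weighted_tree",
            "cues": self.cues,
            "positive_weight": self.positive_weight,
            "params": {"min_split": self.model.params.min_split,
                       "complexity": self.model.params.complexity},
            "nodes": {
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "value": t.value.tolist(),
            },
        }
        return json.dumps(doc)

    def summary(self) -> str:
        return (f"Weighted unconstrained tree: {self.clf.tree_.node_count} nodes, "
                f"depth {self.clf.get_depth()}, positive weight "
                f"{self.positive_weight:.3f}")


class BaseRateLogitModel:
    """Logistic-regression comparator thresholded at the training base rate."""

    def __init__(self, cohort: CohortTable, cues: Sequence[str] | None = None,
                 max_iter: int = 5000) -> None:
        self.cohort = cohort
        self.cues = list(cues) if cues is not None else cohort.cue_names
        self.max_iter = max_iter

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "BaseRateLogitModel":
        return cls(CohortTable(frame), **kwargs)

    def fit(self) -> "BaseRateLogitResults":
        self.cohort.require_outcome()
        y = self.cohort.outcome
        if y.min() == y.max():
            raise ValueError("training outcome contains a single class")
        threshold = float(y.mean())
        if not self.cues:
            # intercept-only model: every predicted probability is the base
            # rate, which equals the threshold, so every case is positive
            intercept = float(np.log(threshold / (1.0 - threshold)))
            params = pd.Series(dtype=float)
            return BaseRateLogitResults(self, params, intercept, threshold, clf=None)
        X, y = _training_arrays(self.cohort, self.cues)
        # standardise internally for optimiser conditioning (cue scales span
        # minutes to 0/1 flags), then map the estimates back; the ML solution
        # is unchanged by this affine reparameterisation
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        # C=inf disables the ridge penalty: plain maximum-likelihood fit
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=self.max_iter)
        clf.fit(Z, y)
        beta = clf.coef_[0] / sd
        intercept = float(clf.intercept_[0] - np.sum(clf.coef_[0] * mu / sd))
        params = pd.Series(beta, index=self.cues)
        return BaseRateLogitResults(self, params, intercept, threshold, clf=clf)


class BaseRateLogitResults:
    """Fitted logistic model: coefficients, base-rate threshold, predictions."""

    def __init__(self, model: BaseRateLogitModel | None, params: pd.Series,
                 intercept: float, threshold: float, clf=None) -> None:
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")
        self.model = model
        self.params = params
        self.intercept = intercept
        self.threshold = threshold
        self.cues = list(params.index)
        self._clf = clf

    def predict_proba(self, table: CohortTable | pd.DataFrame) -> np.ndarray:
        if not self.cues:
            frame = table.data if isinstance(table, CohortTable) else table
            p = 1.0 / (1.0 + np.exp(-self.intercept))
            return np.full(len(frame), p)
        X = _predict_frame(table, self.cues)
        if len(X) == 0:
            return np.zeros(0)
        eta = X @ self.params.to_numpy() + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, table: CohortTable | pd.DataFrame,
                threshold: float | None = None) -> np.ndarray:
        """Positive iff predicted probability >= threshold (ties positive)."""
        cut = self.threshold if threshold is None else threshold
        if not self.cues:
            # intercept-only: probability reproduces the base rate exactly
            frame = table.data if isinstance(table, CohortTable) else table
            p = self.threshold if threshold is None else 1.0 / (1.0 + np.exp(-self.intercept))
            return (np.full(len(frame), p) >= cut).astype(np.int64)
        return (self.predict_proba(table) >= cut).astype(np.int64)

    def evaluate(self, table: CohortTable) -> PerfStats:
        table.require_outcome()
        return perf_from_predictions(table.outcome, self.predict(table))

    def to_json(self) -> str:
        return json.dumps({
            "kind": "base_rate_logit",
            "intercept": self.intercept,
            "coefficients": {c: float(v) for c, v in self.params.items()},
            "threshold": self.threshold,
        })

    def summary(self) -> str:
        lines = ["Base-rate-thresholded logistic regression",
                 "=" * 50,
                 f"threshold (training base rate): {self.threshold:.4f}",
                 f"{'intercept':<28s}{self.intercept:12.4f}"]
        for cue, beta in self.params.items():
            lines.append(f"{cue:<28s}{beta:12.4f}")
        return "\n".join(lines)
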