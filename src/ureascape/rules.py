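"""Interpretable activity rules from a depth-capped decision tree.

A decision tree (Gini impurity, maximum depth 10) is fit on the descriptor
matrix against the binary activity class. The tree is *not* a predictor for
new compounds; it is a scaffold for extracting conjunctive IF-THEN rules
("anchors"): each root-to-leaf path is simplified and then greedily pruned,
dropping conditions one at a time as long as the rule's empirical precision
on the dataset stays at or above a threshold (default 0.80). The surviving
minimal conjunctions are reported with their coverage counts and precision,
exactly the (N_actives, N_inactives, N, precision %) bookkeeping used when
such rules are tabulated.

Feature relevance is quantified with Friedman's one-vs-all H statistic,
which measures how much of the model's response to a feature is
non-additive (interacting with the remaining features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from ._utils import pct
from .profiling import COUNT_DESCRIPTORS

PRECISION_THRESHOLD = 0.80
MAX_DEPTH = 10
INTERACTION_ROW_CAP = 500


@dataclass(frozen=True)
class Condition:
    """One descriptor-threshold condition of a conjunctive rule."""

    feature: str
    comparator: str  # one of "=", ">", "<="
    threshold: float

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        if self.comparator == "=":
            return values == self.threshold
        if self.comparator == ">":
            return values > self.threshold
        if self.comparator == "<=":
            return values <= self.threshold
        raise ValueError(f"unknown comparator {self.comparator!r}")

    def __str__(self) -> str:
        t = self.threshold
        t_repr = int(t) if float(t).is_integer() else round(t, 3)
        return f"{self.feature} {self.comparator} {t_repr}"


@dataclass(frozen=True)
class ConjunctiveRule:
    """An IF-THEN activity rule with its dataset-level metrics."""

    conditions: tuple[Condition, ...]
    predicted_class: str
    n_active: int
    n_inactive: int
    n_total: int
    precision_pct: float

    def __str__(self) -> str:
        cond = "; ".join(str(c) for c in self.conditions)
        return f"IF {cond} THEN {self.predicted_class}"

    def covers(self, X: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(X), dtype=bool)
        for c in self.conditions:
            mask &= c.evaluate(X[c.feature].to_numpy())
        return mask


@dataclass
class TreeModel:
    """A fitted activity tree. Descriptive only — not a deployed predictor."""

    tree: DecisionTreeClassifier
    feature_names: list[str]
    classes: list[str]
    training_accuracy: float

    def predict_active_probability(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        proba = self.tree.predict_proba(np.asarray(X, dtype=np.float64))
        return proba[:, self.classes.index("active")]


def train_activity_tree(
    X: pd.DataFrame,
    y: Sequence[str],
    max_depth: int = MAX_DEPTH,
    seed: int = 0,
) -> TreeModel:
    """Fit a depth-capped Gini decision tree on descriptors vs activity class.

    Deterministic given the seed and input order (feature ties break by
    column order via the seeded splitter). Requires both classes present.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("activity tree needs both classes present")
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, random_state=seed
    )
    tree.fit(X.to_numpy(dtype=np.float64), y)
    acc = float(tree.score(X.to_numpy(dtype=np.float64), y))
    return TreeModel(
        tree=tree,
        feature_names=list(X.columns),
        classes=[str(c) for c in tree.classes_],
        training_accuracy=acc,
    )


# ---------------------------------------------------------------------------
# rule extraction

def _render(feature: str, comparator: str, threshold: float) -> Condition:
    """Render a raw tree split on an integer count descriptor in count terms.

    A split like ``fr_NH1 <= 0.5`` on a non-negative count reads ``= 0``;
    ``> 0.5`` reads ``> 0``; general thresholds floor to the nearest count.
    """
    if feature in COUNT_DESCRIPTORS:
        floor = math.floor(threshold)
        if comparator == "<=":
            return Condition(feature, "=", 0.0) if floor <= 0 else Condition(feature, "<=", float(floor))
        return Condition(feature, ">", float(floor))
    return Condition(feature, comparator, float(threshold))


def _leaf_paths(model: TreeModel) -> list[tuple[list[tuple[str, str, float]], int]]:
    """(raw path conditions, leaf node id) for every leaf, left-to-right."""
    t = model.tree.tree_
    paths = []

    def walk(node: int, conds: list[tuple[str, str, float]]):
        if t.children_left[node] == -1:
            paths.append((list(conds), node))
            return
        feat = model.feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [(feat, "<=", thr)])
        walk(t.children_right[node], conds + [(feat, ">", thr)])

    walk(0, [])
    return paths


def _simplify(raw: list[tuple[str, str, float]]) -> list[tuple[str, str, float]]:
    """Keep only the tightest bound per (feature, direction)."""
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    order: list[tuple[str, str]] = []
    for feat, cmp_, thr in raw:
        bounds = upper if cmp_ == "<=" else lower
        if feat not in bounds:
            order.append((feat, cmp_))
            bounds[feat] = thr
        else:
            bounds[feat] = min(bounds[feat], thr) if cmp_ == "<=" else max(bounds[feat], thr)
    return [
        (feat, cmp_, (upper if cmp_ == "<=" else lower)[feat]) for feat, cmp_ in order
    ]


def _precision(conditions: Sequence[Condition], X: pd.DataFrame, y: np.ndarray, predicted: str):
    mask = np.ones(len(X), dtype=bool)
    for c in conditions:
        mask &= c.evaluate(X[c.feature].to_numpy())
    n_total = int(mask.sum())
    if n_total == 0:
        return 0.0, 0, 0, 0
    n_active = int((y[mask] == "active").sum())
    n_inactive = n_total - n_active
    n_pred = n_active if predicted == "active" else n_inactive
    return n_pred / n_total, n_active, n_inactive, n_total


def extract_rules(
    model: TreeModel,
    X: pd.DataFrame,
    y: Sequence[str],
    precision_threshold: float = PRECISION_THRESHOLD,
) -> list[ConjunctiveRule]:
    """Anchor-style conjunctive rules from a fitted tree.

    Every populated leaf's path becomes a candidate rule predicting the
    leaf's majority class. Conditions are greedily dropped (one at a time,
    keeping the drop that best preserves coverage) while the rule's
    empirical precision on ``(X, y)`` stays >= ``precision_threshold``.
    Candidates that never reach the threshold are discarded; duplicates are
    merged; output is ranked by coverage (then precision, then rule text).
    """
    y = np.asarray(y)
    t = model.tree.tree_
    seen: dict[tuple, ConjunctiveRule] = {}
    for raw_path, leaf in _leaf_paths(model):
        counts = t.value[leaf][0]
        if counts.sum() == 0 or not raw_path:
            continue
        predicted = model.classes[int(np.argmax(counts))]
        conditions = [_render(*c) for c in _simplify(raw_path)]
        prec, *_ = _precision(conditions, X, y, predicted)
        if prec < precision_threshold:
            continue
        # greedy pruning: drop the condition whose removal keeps precision
        # above threshold with the largest resulting coverage
        improved = True
        while improved and len(conditions) > 1:
            improved = False
            best: tuple[int, int] | None = None  # (coverage, -index)
            for i in range(len(conditions)):
                trial = conditions[:i] + conditions[i + 1 :]
                p, _, _, n_tot = _precision(trial, X, y, predicted)
                if p >= precision_threshold and (best is None or n_tot > best[0]):
                    best = (n_tot, i)
            if best is not None:
                conditions.pop(best[1])
                improved = True
        prec, n_act, n_inact, n_tot = _precision(conditions, X, y, predicted)
        rule = ConjunctiveRule(
            conditions=tuple(conditions),
            predicted_class=predicted,
            n_active=n_act,
            n_inactive=n_inact,
            n_total=n_tot,
            precision_pct=rule_precision_pct(
                n_act if predicted == "active" else n_inact, n_tot
            ),
        )
        key = (frozenset(conditions), predicted)
        seen.setdefault(key, rule)
    return sorted(
        seen.values(),
        key=lambda r: (-r.n_total, -r.precision_pct, str(r)),
    )


def rule_precision_pct(n_predicted_class: int, n_total: int) -> float:
    """Precision % = 100 * covered-in-predicted-class / covered, one decimal."""
    if n_total == 0:
        raise ValueError("precision undefined for zero coverage")
    return pct(n_predicted_class, n_total)


def rule_metrics(
    rule: ConjunctiveRule, X: pd.DataFrame, y: Sequence[str]
) -> tuple[int, int, int, float | None]:
    """(n_active, n_inactive, n_total, precision %) of a rule on a dataset.

    Precision is None (flagged undefined) when the rule covers nothing.
    """
    y = np.asarray(y)
    _, n_act, n_inact, n_tot = _precision(list(rule.conditions), X, y, rule.predicted_class)
    if n_tot == 0:
        return 0, 0, 0, None
    n_pred = n_act if rule.predicted_class == "active" else n_inact
    return n_act, n_inact, n_tot, rule_precision_pct(n_pred, n_tot)


def rules_to_frame(rules: Sequence[ConjunctiveRule]) -> pd.DataFrame:
    """Serialize rules to the rules-CSV schema."""
    return pd.DataFrame(
        [
            {
                "rule_id": i + 1,
                "conditions": "; ".join(str(c) for c in r.conditions),
                "predicted_class": r.predicted_class,
                "n_active": r.n_active,
                "n_inactive": r.n_inactive,
                "n_total": r.n_total,
                "precision_pct": r.precision_pct,
            }
            for i, r in enumerate(rules)
        ],
        columns=[
            "rule_id",
            "conditions",
            "predicted_class",
            "n_active",
            "n_inactive",
            "n_total",
            "precision_pct",
        ],
    )


# ---------------------------------------------------------------------------
# feature interaction

def feature_interaction(
    model: TreeModel | Callable[[np.ndarray], np.ndarray],
    X: pd.DataFrame,
    feature: str,
    max_rows: int = INTERACTION_ROW_CAP,
    seed: int = 0,
) -> float:
    """Friedman's one-vs-all H statistic for one feature, in [0, 1].

    H is the variance of the difference between the model's full partial
    dependence and its additive decomposition into a feature-j term plus a
    rest term, normalized by the variance of the full partial dependence.
    0 means the feature acts purely additively; values near 1 mean its
    effect is dominated by interactions. Constant predictions define H = 0.
    Partial dependences are estimated empirically on at most ``max_rows``
    rows (seeded subsample).
    """
    if isinstance(model, TreeModel):
        predict = model.predict_active_probability
    else:
        predict = model
    if feature not in X.columns:
        raise KeyError(f"unknown feature {feature!r}")
    Xv = X.to_numpy(dtype=np.float64)
    if len(Xv) > max_rows:
        rng = np.random.default_rng(seed)
        Xv = Xv[rng.choice(len(Xv), size=max_rows, replace=False)]
    n = len(Xv)
    j = list(X.columns).index(feature)
    # M[a, b] = f(feature j from row a, all other features from row b)
    M = np.empty((n, n), dtype=np.float64)
    for a in range(n):
        grid = Xv.copy()
        grid[:, j] = Xv[a, j]
        M[a, :] = np.asarray(predict(pd.DataFrame(grid, columns=X.columns)), dtype=np.float64)
    full = np.diag(M)
    pd_j = M.mean(axis=1)
    pd_rest = M.mean(axis=0)
    full_c = full - full.mean()
    pd_j_c = pd_j - pd_j.mean()
    pd_rest_c = pd_rest - pd_rest.mean()
    denom = float(np.sum(full_c**2))
    if denom == 0.0:
        return 0.0
    h2 = float(np.sum((full_c - pd_j_c - pd_rest_c) ** 2)) / denom
    return float(np.clip(h2, 0.0, 1.0))


def interaction_table(
    model: TreeModel,
    X: pd.DataFrame,
    features: Sequence[str] | None = None,
    max_rows: int = INTERACTION_ROW_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature one-vs-all H, sorted descending."""
    features = list(features) if features is not None else list(X.columns)
    rows = [
        {"feature": f, "h_statistic": feature_interaction(model, X, f, max_rows, seed)}
        for f in features
    ]
    return (
        pd.DataFrame(rows, columns=["feature", "h_statistic"])
        .sort_values(["h_statistic", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
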