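"""Bottom-up aggregative rule induction.

The learner emulates an aggregative Boolean-function-synthesis rule
inducer: for each output class it repeatedly seeds a maximally specific
premise on an uncovered instance and weakens it one step at a time (drop a
condition, admit one more nominal value, extend an interval to the
adjacent cutpoint), always taking the step with the largest gain in
true positives among those keeping the training error E(r) within the
allowed budget (0% by default).  When no step gains coverage, conditions
whose removal is free are dropped to minimise the premise length, the rule
is emitted, and seeding continues until every class instance is covered.

Ordered attributes are discretized first (class-driven cutpoint placement
with a minimum between-class proportion distance), and induced interval
endpoints are restricted to those cutpoints.

The estimator :class:`RuleInductionClassifier` wraps the procedure in the
scikit-learn fit/predict protocol; :func:`induce_classifier` is a thin
functional wrapper over it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .rules import Classifier, Condition, Rule, member, normalize_conditions
from .schema import AttributeSchema, CohortDataset, nominal, ordered


@dataclass(frozen=True)
class InductionConfig:
    """Learner settings (defaults mirror the study configuration)."""

    max_training_error: float = 0.0
    minimize_conditions: bool = True
    cover_all: bool = True
    min_class_distance: float = 0.20

    def __post_init__(self):
        if not 0.0 <= self.max_training_error <= 1.0:
            raise ValueError("max_training_error must lie in [0, 1]")
        if not 0.0 < self.min_class_distance < 1.0:
            raise ValueError("min_class_distance must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_attribute(
    dataset: CohortDataset,
    attribute: str,
    min_class_distance: float = 0.20,
) -> list[float]:
    """Class-driven cutpoints for one ordered attribute.

    Candidate cutpoints sit at midpoints between consecutive distinct
    values whose class composition differs; adjacent intervals are then
    merged (weakest boundary first) until the class-proportion difference
    across every retained cutpoint is at least ``min_class_distance``.
    A constant or uninformative attribute yields no cutpoints.
    """
    attr = dataset.attribute(attribute)
    if attr.kind != "ordered":
        raise ValueError(f"{attribute!r} is not an ordered attribute")
    x = dataset.frame[attribute].to_numpy(dtype=float)
    y = dataset.outcome.astype(str).to_numpy()
    classes = dataset.classes
    values = np.unique(x)
    if len(values) < 2:
        return []

    # per distinct value: class count vector
    counts = np.zeros((len(values), len(classes)), dtype=float)
    for ci, cls in enumerate(classes):
        vals, n = np.unique(x[y == cls], return_counts=True)
        counts[np.searchsorted(values, vals), ci] = n

    # intervals as (start, end) index ranges over distinct values
    props = counts / counts.sum(axis=1, keepdims=True)
    boundaries = [i for i in range(len(values) - 1)
                  if not np.allclose(props[i], props[i + 1])]
    segments = _segments(boundaries, len(values))

    def gap(left: tuple, right: tuple) -> float:
        lc = counts[left[0]:left[1] + 1].sum(axis=0)
        rc = counts[right[0]:right[1] + 1].sum(axis=0)
        return float(np.max(np.abs(lc / lc.sum() - rc / rc.sum())))

    while len(segments) > 1:
        gaps = [gap(segments[k], segments[k + 1]) for k in range(len(segments) - 1)]
        k = int(np.argmin(gaps))
        if gaps[k] >= min_class_distance:
            break
        segments[k] = (segments[k][0], segments[k + 1][1])
        del segments[k + 1]

    return [
        float((values[segments[k][1]] + values[segments[k + 1][0]]) / 2.0)
        for k in range(len(segments) - 1)
    ]


def _segments(boundaries: list[int], n: int) -> list[tuple[int, int]]:
    segs, start = [], 0
    for b in boundaries:
        segs.append((start, b))
        start = b + 1
    segs.append((start, n - 1))
    return segs


# ---------------------------------------------------------------------------
# Greedy covering engine
# ---------------------------------------------------------------------------

class _Search:
    """Per-dataset working state for the greedy generalizer."""

    def __init__(self, dataset: CohortDataset, config: InductionConfig):
        self.dataset = dataset
        self.config = config
        self.n = dataset.n
        self.columns: dict[str, np.ndarray] = {}
        self.domains: dict[str, tuple] = {}
        self.bounds: dict[str, list[float]] = {}
        for attr in dataset.schema:
            if attr.kind == "nominal":
                self.columns[attr.name] = dataset.frame[attr.name].to_numpy()
                self.domains[attr.name] = attr.values
            else:
                self.columns[attr.name] = dataset.frame[attr.name].to_numpy(float)
                cuts = discretize_attribute(
                    dataset, attr.name, config.min_class_distance
                )
                self.bounds[attr.name] = [-np.inf, *cuts, np.inf]

    # premise: dict attr -> set of values (nominal) | [lo_idx, hi_idx] (ordered)

    def seed_premise(self, row: pd.Series) -> dict:
        premise = {}
        for attr in self.dataset.schema:
            if attr.kind == "nominal":
                premise[attr.name] = {row[attr.name]}
            else:
                b = self.bounds[attr.name]
                if len(b) == 2:  # uninformative: single full-range bin
                    continue
                v = float(row[attr.name])
                i = int(np.searchsorted(np.asarray(b[1:-1]), v, side="left"))
                premise[attr.name] = [i, i + 1]
        return premise

    def cond_mask(self, name: str, state) -> np.ndarray:
        col = self.columns[name]
        if isinstance(state, set):
            return np.isin(col, list(state))
        b = self.bounds[name]
        return (col > b[state[0]]) & (col <= b[state[1]])

    def premise_mask(self, premise: dict, skip: str | None = None) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        for name, state in premise.items():
            if name != skip:
                mask &= self.cond_mask(name, state)
        return mask

    def candidates(self, premise: dict):
        """Single generalization steps in deterministic preference order:
        condition drops first (schema order), then member-set growth /
        interval extension."""
        names = [a.name for a in self.dataset.schema if a.name in premise]
        for name in names:
            yield ("drop", name, None)
        for name in names:
            state = premise[name]
            if isinstance(state, set):
                for v in self.domains[name]:
                    if v not in state:
                        yield ("add", name, v)
            else:
                if state[0] > 0:
                    yield ("lo", name, state[0] - 1)
                if state[1] < len(self.bounds[name]) - 1:
                    yield ("hi", name, state[1] + 1)

    def apply(self, premise: dict, step) -> dict:
        kind, name, arg = step
        new = {k: (set(v) if isinstance(v, set) else list(v))
               for k, v in premise.items()}
        if kind == "drop":
            del new[name]
        elif kind == "add":
            new[name].add(arg)
        elif kind == "lo":
            new[name][0] = arg
        else:
            new[name][1] = arg
        # a full-range interval or full member set is no condition at all
        if name in new:
            state = new[name]
            if isinstance(state, set):
                if state == set(self.domains[name]):
                    del new[name]
            elif state[0] == 0 and state[1] == len(self.bounds[name]) - 1:
                del new[name]
        return new

    def grow(self, premise: dict, y_mask: np.ndarray, fp_limit: float) -> dict:
        """Greedy TP-maximising generalization at bounded error."""
        mask = self.premise_mask(premise)
        tp = int(np.sum(mask & y_mask))
        while True:
            best = None
            for step in self.candidates(premise):
                kind, name, arg = step
                other = self.premise_mask(premise, skip=name)
                if kind == "drop":
                    cand_mask = other
                else:
                    state = premise[name]
                    if isinstance(state, set):
                        new_state = state | {arg}
                    else:
                        new_state = [arg, state[1]] if kind == "lo" \
                            else [state[0], arg]
                    cand_mask = other & self.cond_mask(name, new_state)
                cand_tp = int(np.sum(cand_mask & y_mask))
                cand_fp = int(np.sum(cand_mask & ~y_mask))
                if cand_fp <= fp_limit and cand_tp > tp \
                        and (best is None or cand_tp > best[0]):
                    best = (cand_tp, step)
            if best is None:
                return premise
            tp, step = best
            premise = self.apply(premise, step)

    def minimise(self, premise: dict, y_mask: np.ndarray, fp_limit: float) -> dict:
        """Drop every condition whose removal keeps the error admissible."""
        changed = True
        while changed:
            changed = False
            for name in [a.name for a in self.dataset.schema if a.name in premise]:
                other = self.premise_mask(premise, skip=name)
                if int(np.sum(other & ~y_mask)) <= fp_limit:
                    del premise[name]
                    changed = True
        return premise

    def to_conditions(self, premise: dict) -> tuple[Condition, ...]:
        conds = []
        for name, state in premise.items():
            if isinstance(state, set):
                conds.append(member(name, state))
            else:
                b = self.bounds[name]
                conds.append(Condition(name, "ordered",
                                       lo=b[state[0]], hi=b[state[1]]))
        return normalize_conditions(conds)


def _induce(dataset: CohortDataset, config: InductionConfig) -> Classifier:
    if dataset.n < 1:
        raise ValueError("cannot induce rules on an empty cohort")
    search = _Search(dataset, config)
    y = dataset.outcome.astype(str).to_numpy()
    rules: list[Rule] = []
    contradictions: list[tuple] = []
    counter = 0

    for cls in dataset.classes:
        y_mask = y == cls
        neg_total = int(np.sum(~y_mask))
        fp_limit = config.max_training_error * neg_total + 1e-9
        covered = np.zeros(dataset.n, dtype=bool)
        while True:
            uncovered = y_mask & ~covered
            if not uncovered.any():
                break
            seed_pos = int(np.flatnonzero(uncovered)[0])
            row = dataset.frame.iloc[seed_pos]
            premise = search.seed_premise(row)
            seed_mask = search.premise_mask(premise)
            seed_fp = int(np.sum(seed_mask & ~y_mask))
            if seed_fp > fp_limit:
                # identical (discretized) profile holds both labels: zero
                # training error is unreachable on it; emit the maximally
                # specific rule and report the profile
                profile = tuple(row[a.name] for a in dataset.schema)
                if profile not in contradictions:
                    contradictions.append(profile)
                if not config.cover_all:
                    covered |= seed_mask & y_mask
                    continue
            else:
                premise = search.grow(premise, y_mask, fp_limit)
                if config.minimize_conditions:
                    premise = search.minimise(premise, y_mask, fp_limit)
            counter += 1
            rule = Rule(f"r{counter}", search.to_conditions(premise), cls)
            rules.append(rule)
            covered |= rule.covers(dataset)

    clf = Classifier(rules, list(dataset.schema), contradictions=contradictions)
    return clf.fit_stats(dataset)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class RuleInductionClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator for the bottom-up rule inducer.

    Parameters
    ----------
    schema:
        Attribute declarations.  When ``None`` the schema is inferred from
        the training frame: numeric columns become ordered attributes
        bounded by their observed range, everything else nominal over the
        observed values.
    max_training_error:
        Largest admissible per-rule training error E(r); 0 forces every
        rule to be exact on the training set, which in turn makes the
        learner cover every training instance.
    min_class_distance:
        Minimum between-class proportion gap a retained discretization
        cutpoint must separate.

    Attributes
    ----------
    classifier_ : Classifier
        Induced rule set with per-rule training statistics.
    rules_ : list[Rule]
    contradictions_ : list[tuple]
        Attribute profiles carrying more than one outcome label.
    classes_ : ndarray
    """

    def __init__(
        self,
        schema: Sequence[AttributeSchema] | None = None,
        max_training_error: float = 0.0,
        minimize_conditions: bool = True,
        cover_all: bool = True,
        min_class_distance: float = 0.20,
    ):
        self.schema = schema
        self.max_training_error = max_training_error
        self.minimize_conditions = minimize_conditions
        self.cover_all = cover_all
        self.min_class_distance = min_class_distance

    def _config(self) -> InductionConfig:
        return InductionConfig(
            max_training_error=self.max_training_error,
            minimize_conditions=self.minimize_conditions,
            cover_all=self.cover_all,
            min_class_distance=self.min_class_distance,
        )

    def _as_dataset(self, X, y) -> CohortDataset:
        if isinstance(X, CohortDataset):
            return X
        frame = pd.DataFrame(X)
        schema = list(self.schema) if self.schema is not None \
            else infer_schema(frame)
        outcome = pd.Series(np.asarray(y, dtype=object), index=frame.index)
        return CohortDataset(schema, frame, outcome)

    def fit(self, X, y=None):
        dataset = self._as_dataset(X, y if y is not None else X.outcome)
        self.classifier_ = _induce(dataset, self._config())
        self.rules_ = self.classifier_.rules
        self.contradictions_ = self.classifier_.contradictions
        self.schema_ = self.classifier_.schema
        self.classes_ = np.asarray(dataset.classes, dtype=object)
        self.n_features_in_ = len(self.schema_)
        return self

    def predict(self, X):
        check_is_fitted(self, "classifier_")
        frame = X.frame if isinstance(X, CohortDataset) else pd.DataFrame(X)
        return self.classifier_.predict_frame(frame).to_numpy(dtype=object)


def infer_schema(frame: pd.DataFrame) -> list[AttributeSchema]:
    schema = []
    for name in frame.columns:
        col = frame[name]
        if pd.api.types.is_numeric_dtype(col):
            lo, hi = float(col.min()), float(col.max())
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
            schema.append(ordered(name, lo, hi))
        else:
            schema.append(nominal(name, sorted(col.astype(str).unique())))
    return schema


def induce_classifier(
    train: CohortDataset, config: InductionConfig | None = None
) -> Classifier:
    """Induce a rule classifier on a cohort (functional facade)."""
    config = config or InductionConfig()
    est = RuleInductionClassifier(
        schema=train.schema,
        max_training_error=config.max_training_error,
        minimize_conditions=config.minimize_conditions,
        cover_all=config.cover_all,
        min_class_distance=config.min_class_distance,
    )
    est.fit(train)
    return est.classifier_
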