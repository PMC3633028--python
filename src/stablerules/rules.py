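"""Rule data model: conditions, if-then rules, classifiers, conflicts.

A rule has the form ``if <premise> then <class>`` where the premise is a
conjunction of at most one condition per attribute.  Conditions on ordered
attributes are half-open intervals ``lambda < x <= mu`` (one side may be
unbounded, written ``x > lambda`` or ``x <= mu``); conditions on nominal
attributes are membership tests ``x in {a, b, ...}``.

Relative to a labelled dataset a rule with consequence class *l* has the
confusion counts TP/FP/FN/TN (satisfiers vs non-satisfiers of the premise,
split by whether the instance belongs to class *l*), from which the three
per-rule statistics are derived::

    covering  C(r) = TP / (TP + FN)
    error     E(r) = FP / (TN + FP)
    precision P(r) = TP / (TP + FP)

A classifier is an ordered rule list; a pattern satisfied by several rules
receives the consequence of the satisfied rule with the highest covering
(ties broken by higher precision, then rule order), and patterns satisfied
by no rule receive the reserved label ``NC``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import NC, AttributeSchema, CohortDataset, SchemaError


class RuleParseError(ValueError):
    """Malformed rule text; carries the offending fragment."""


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """One premise condition on a single attribute.

    For nominal attributes ``values`` is the admitted member set; for
    ordered attributes the admitted interval is ``lo < x <= hi`` with
    ``lo = -inf`` / ``hi = +inf`` encoding unbounded sides.
    """

    attribute: str
    kind: str  # "nominal" | "ordered"
    values: frozenset = frozenset()
    lo: float = -math.inf
    hi: float = math.inf

    def satisfied(self, column: pd.Series) -> np.ndarray:
        if self.kind == "nominal":
            return column.isin(self.values).to_numpy()
        x = column.to_numpy(dtype=float)
        return (x > self.lo) & (x <= self.hi)

    def satisfied_value(self, value) -> bool:
        if self.kind == "nominal":
            return value in self.values
        return self.lo < float(value) <= self.hi

    def intersect(self, other: "Condition") -> "Condition":
        if self.attribute != other.attribute or self.kind != other.kind:
            raise ValueError("can only intersect conditions on the same attribute")
        if self.kind == "nominal":
            return replace(self, values=self.values & other.values)
        return replace(self, lo=max(self.lo, other.lo), hi=min(self.hi, other.hi))

    def satisfiable(self, attr: AttributeSchema) -> bool:
        """Whether any value of the attribute's domain meets the condition."""
        if self.kind == "nominal":
            return bool(self.values & set(attr.values))
        # points of [low, high] with lo < x <= hi
        return self.hi >= attr.low and self.lo < attr.high and self.lo < self.hi

    def text(self) -> str:
        if self.kind == "nominal":
            inner = ", ".join(sorted(self.values))
            return f"{self.attribute} in {{{inner}}}"
        if self.lo == -math.inf:
            return f"{self.attribute} <= {_fmt(self.hi)}"
        if self.hi == math.inf:
            return f"{self.attribute} > {_fmt(self.lo)}"
        return f"{_fmt(self.lo)} < {self.attribute} <= {_fmt(self.hi)}"


def _fmt(v: float) -> str:
    return f"{int(v)}" if float(v).is_integer() else repr(float(v))


def member(attribute: str, values: Iterable) -> Condition:
    return Condition(attribute, "nominal", values=frozenset(map(str, values)))


def greater(attribute: str, lam: float) -> Condition:
    return Condition(attribute, "ordered", lo=float(lam))


def at_most(attribute: str, mu: float) -> Condition:
    return Condition(attribute, "ordered", hi=float(mu))


def interval(attribute: str, lam: float, mu: float) -> Condition:
    if not lam < mu:
        raise ValueError(f"interval requires lambda < mu, got ({lam}, {mu}]")
    return Condition(attribute, "ordered", lo=float(lam), hi=float(mu))


# ---------------------------------------------------------------------------
# Rule statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleStats:
    """Covering / error / precision with undefined-denominator flags.

    A zero denominator yields the value 0 with the corresponding
    ``*_defined`` flag cleared, so downstream products stay total.
    """

    covering: float
    error: float
    precision: float
    covering_defined: bool = True
    error_defined: bool = True
    precision_defined: bool = True


def rule_stats(counts: dict) -> RuleStats:
    tp, fp, fn, tn = counts["TP"], counts["FP"], counts["FN"], counts["TN"]
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")

    def ratio(num, den):
        return (num / den, True) if den > 0 else (0.0, False)

    c, cd = ratio(tp, tp + fn)
    e, ed = ratio(fp, tn + fp)
    p, pd_ = ratio(tp, tp + fp)
    return RuleStats(c, e, p, cd, ed, pd_)


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """Conjunctive rule ``if <conditions> then <consequence>``."""

    id: str
    conditions: tuple[Condition, ...]
    consequence: str
    stats: RuleStats | None = field(default=None, compare=False)

    def __post_init__(self):
        attrs = [c.attribute for c in self.conditions]
        if len(set(attrs)) != len(attrs):
            raise ValueError("premise must hold at most one condition per attribute")

    def condition_on(self, attribute: str) -> Condition | None:
        for c in self.conditions:
            if c.attribute == attribute:
                return c
        return None

    def covers(self, dataset: CohortDataset) -> np.ndarray:
        """Boolean mask of instances satisfying every premise condition."""
        mask = np.ones(dataset.n, dtype=bool)
        for cond in self.conditions:
            mask &= cond.satisfied(dataset.frame[cond.attribute])
        return mask

    def covers_pattern(self, pattern: dict) -> bool:
        return all(c.satisfied_value(pattern[c.attribute]) for c in self.conditions)

    def without(self, condition: Condition) -> "Rule":
        rest = tuple(c for c in self.conditions if c != condition)
        if len(rest) == len(self.conditions):
            raise ValueError("condition is not part of the premise")
        return replace(self, conditions=rest, stats=None)

    def with_stats(self, dataset: CohortDataset) -> "Rule":
        return replace(self, stats=rule_stats(confusion_counts(self, dataset)))

    def text(self) -> str:
        return format_rule(self)


def confusion_counts(rule: Rule, dataset: CohortDataset) -> dict:
    """TP/FP/FN/TN of ``rule`` against a labelled dataset."""
    mask = rule.covers(dataset)
    is_target = (dataset.outcome.astype(str) == rule.consequence).to_numpy()
    tp = int(np.sum(mask & is_target))
    fp = int(np.sum(mask & ~is_target))
    fn = int(np.sum(~mask & is_target))
    tn = int(np.sum(~mask & ~is_target))
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def normalize_conditions(
    conditions: Iterable[Condition],
) -> tuple[Condition, ...]:
    """Merge duplicate-attribute conditions by intersection; sort by name."""
    merged: dict[str, Condition] = {}
    for cond in conditions:
        if cond.attribute in merged:
            merged[cond.attribute] = merged[cond.attribute].intersect(cond)
        else:
            merged[cond.attribute] = cond
    return tuple(merged[a] for a in sorted(merged))


# ---------------------------------------------------------------------------
# Rule grammar
# ---------------------------------------------------------------------------

_NAME = r"[A-Za-z_][\w.\-]*"
_NUM = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"
_RULE_RE = re.compile(r"^\s*if\b(?P<premise>.*)\bthen\b(?P<consequence>.+)$", re.S)
_INTERVAL_RE = re.compile(rf"^({_NUM})\s*<\s*({_NAME})\s*<=\s*({_NUM})$")
_GREATER_RE = re.compile(rf"^({_NAME})\s*>\s*({_NUM})$")
_ATMOST_RE = re.compile(rf"^({_NAME})\s*<=\s*({_NUM})$")
_MEMBER_RE = re.compile(rf"^({_NAME})\s+in\s+\{{([^}}]*)\}}$")
_THEN_RE = re.compile(rf"^\s*({_NAME})\s*=\s*(\S+)\s*$")


def parse_rule(
    text: str,
    schema: Sequence[AttributeSchema],
    rule_id: str = "r",
) -> Rule:
    """Parse one rule in the grammar ``if <cond> [and <cond>]* then <attr> = <label>``.

    The returned rule is normalized: conditions sorted by attribute name,
    duplicate conditions on one attribute intersected.  Raises
    :class:`RuleParseError` for malformed syntax and :class:`SchemaError`
    for unknown attributes or out-of-domain values.
    """
    by_name = {a.name: a for a in schema}
    m = _RULE_RE.match(text)
    if m is None:
        raise RuleParseError(f"rule must have the form 'if ... then ...': {text!r}")
    premise_text = m.group("premise").strip()
    cons = _THEN_RE.match(m.group("consequence"))
    if cons is None:
        raise RuleParseError(
            f"consequence must have the form '<attr> = <label>': "
            f"{m.group('consequence').strip()!r}"
        )
    consequence = cons.group(2)

    conditions: list[Condition] = []
    if premise_text:
        for pos, chunk in enumerate(re.split(r"\s+and\s+", premise_text)):
            conditions.append(_parse_condition(chunk.strip(), by_name, pos))
    return Rule(rule_id, normalize_conditions(conditions), consequence)


def _parse_condition(chunk: str, by_name: dict, pos: int) -> Condition:
    def attr_of(name: str, want_kind: str) -> AttributeSchema:
        if name not in by_name:
            raise SchemaError(f"unknown attribute {name!r} in condition {pos + 1}")
        attr = by_name[name]
        if attr.kind != want_kind:
            raise SchemaError(
                f"condition {pos + 1} ({chunk!r}) does not match the "
                f"{attr.kind} kind of attribute {name!r}"
            )
        return attr

    if (m := _INTERVAL_RE.match(chunk)) is not None:
        lam, name, mu = float(m.group(1)), m.group(2), float(m.group(3))
        attr_of(name, "ordered")
        if not lam < mu:
            raise RuleParseError(f"empty interval in condition {pos + 1}: {chunk!r}")
        return interval(name, lam, mu)
    if (m := _GREATER_RE.match(chunk)) is not None:
        attr_of(m.group(1), "ordered")
        return greater(m.group(1), float(m.group(2)))
    if (m := _ATMOST_RE.match(chunk)) is not None:
        attr_of(m.group(1), "ordered")
        return at_most(m.group(1), float(m.group(2)))
    if (m := _MEMBER_RE.match(chunk)) is not None:
        name = m.group(1)
        attr = attr_of(name, "nominal")
        values = [v.strip() for v in m.group(2).split(",") if v.strip()]
        if not values:
            raise RuleParseError(f"empty member set in condition {pos + 1}: {chunk!r}")
        unknown = [v for v in values if v not in attr.values]
        if unknown:
            raise SchemaError(
                f"value(s) {unknown} outside domain of {name!r} in condition {pos + 1}"
            )
        return member(name, values)
    raise RuleParseError(f"cannot parse condition {pos + 1}: {chunk!r}")


def format_rule(rule: Rule) -> str:
    premise = " and ".join(c.text() for c in rule.conditions)
    return f"if {premise} then outcome = {rule.consequence}" if premise \
        else f"if then outcome = {rule.consequence}"


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class Classifier:
    """Ordered rule set with the highest-covering prediction policy."""

    rules: list[Rule]
    schema: list[AttributeSchema]
    source: str = ""
    #: attribute profiles that held more than one outcome label at training
    #: time (zero training error unreachable on them)
    contradictions: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("rule ids must be unique")

    @property
    def consequences(self) -> list[str]:
        return sorted({r.consequence for r in self.rules})

    def fit_stats(self, dataset: CohortDataset) -> "Classifier":
        """Return a copy whose rules carry stats computed on ``dataset``."""
        return Classifier([r.with_stats(dataset) for r in self.rules],
                          self.schema, self.source, list(self.contradictions))

    def _priority(self) -> list[int]:
        # rank rules: higher covering first, then higher precision, then order
        def key(i):
            r = self.rules[i]
            s = r.stats
            if s is None:
                raise ValueError(
                    "rules carry no stats; call fit_stats(dataset) before predicting"
                )
            return (-s.covering, -s.precision, i)

        order = sorted(range(len(self.rules)), key=key)
        rank = [0] * len(self.rules)
        for pos, i in enumerate(order):
            rank[i] = pos
        return rank

    def predict_frame(self, frame: pd.DataFrame) -> pd.Series:
        """Predict a label (or ``NC``) for every row of an attribute table."""
        if not self.rules:
            return pd.Series([NC] * len(frame), index=frame.index, dtype=object)
        rank = self._priority()
        n = len(frame)
        best_rank = np.full(n, len(self.rules) + 1)
        out = np.array([NC] * n, dtype=object)
        for i, rule in enumerate(self.rules):
            mask = np.ones(n, dtype=bool)
            for cond in rule.conditions:
                mask &= cond.satisfied(frame[cond.attribute])
            better = mask & (rank[i] < best_rank)
            out[better] = rule.consequence
            best_rank[better] = rank[i]
        return pd.Series(out, index=frame.index, dtype=object)

    def predict(self, dataset: CohortDataset) -> pd.Series:
        return self.predict_frame(dataset.frame)


def classify(classifier: Classifier, pattern: dict) -> str:
    """Label a single pattern; ``NC`` when no rule premise is satisfied."""
    frame = pd.DataFrame([pattern])
    return classifier.predict_frame(frame).iloc[0]


# ---------------------------------------------------------------------------
# Conflict analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConflictPair:
    rule_a: Rule
    rule_b: Rule
    witness: tuple[Condition, ...]
    nc_rule: Rule


def intersect_premises(
    a: Sequence[Condition], b: Sequence[Condition]
) -> tuple[Condition, ...]:
    """Attribute-wise intersection of two premise regions.

    An attribute unconstrained in one premise keeps the other premise's
    condition; attributes constrained in both get the condition
    intersection (which may be empty, i.e. unsatisfiable).
    """
    return normalize_conditions(list(a) + list(b))


def premise_satisfiable(
    conditions: Sequence[Condition], schema: Sequence[AttributeSchema]
) -> bool:
    by_name = {s.name: s for s in schema}
    return all(c.satisfiable(by_name[c.attribute]) for c in conditions)


def conflict_pairs(classifier: Classifier) -> list[ConflictPair]:
    """All pairs of rules with different consequences whose premises are
    jointly satisfiable over the full attribute domain, each with the
    witness premise and the derived ``NC`` rule covering the overlap."""
    pairs: list[ConflictPair] = []
    rules = classifier.rules
    seq = 0
    for i in range(len(rules)):
        for j in range(i + 1, len(rules)):
            ra, rb = rules[i], rules[j]
            if ra.consequence == rb.consequence:
                continue
            witness = intersect_premises(ra.conditions, rb.conditions)
            if premise_satisfiable(witness, classifier.schema):
                seq += 1
                nc = Rule(f"nc-{seq}", witness, NC)
                pairs.append(ConflictPair(ra, rb, witness, nc))
    return pairs
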