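"""Condition and variable relevance.

Removing a condition ``c`` from a rule ``r`` gives a weaker rule ``r'``
whose error can only grow, so the error increase ``R(c) = E(r') - E(r)``
is a non-negative measure of how much the condition contributes.  The
per-variable relevance aggregates, over the rules ``r_k`` carrying a
condition ``c_kl`` on attribute ``x_j``::

    R_j = 1 - prod_k (1 - P(r_k) * R(c_kl))

which stays in [0, 1] because precision and error increments both do.
The per-class scope restricts the product to rules predicting that class.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rules import Classifier, Condition, Rule, confusion_counts, rule_stats
from .schema import CohortDataset


@dataclass(frozen=True)
class RelevanceTable:
    """Per-condition and per-variable relevance in one scope."""

    per_condition: dict  # (rule id, condition text) -> R(c)
    per_variable: dict   # attribute name -> R_j
    scope: str           # "all" or a class label


def condition_relevance(rule: Rule, condition: Condition,
                        dataset: CohortDataset) -> float:
    """Error increase from removing ``condition`` (the weaker rule ``r'``
    may be the always-true rule)."""
    stats = rule_stats(confusion_counts(rule, dataset))
    weaker = rule.without(condition)
    weaker_stats = rule_stats(confusion_counts(weaker, dataset))
    return weaker_stats.error - stats.error


def variable_relevance(
    classifier: Classifier,
    dataset: CohortDataset,
    target_class: str | None = None,
) -> dict[str, float]:
    """Per-attribute relevance ``R_j`` over all rules (or over the rules
    predicting ``target_class``).  Attributes appearing in no rule score 0;
    a rule with undefined precision contributes a neutral factor."""
    table = relevance_table(classifier, dataset, target_class)
    return table.per_variable


def relevance_table(
    classifier: Classifier,
    dataset: CohortDataset,
    target_class: str | None = None,
) -> RelevanceTable:
    rules = [r for r in classifier.rules
             if target_class is None or r.consequence == target_class]
    per_condition: dict = {}
    factors: dict[str, list[float]] = {a.name: [] for a in classifier.schema}
    for rule in rules:
        stats = rule_stats(confusion_counts(rule, dataset))
        precision = stats.precision if stats.precision_defined else None
        for cond in rule.conditions:
            r_c = condition_relevance(rule, cond, dataset)
            per_condition[(rule.id, cond.text())] = r_c
            if precision is not None:
                factors[cond.attribute].append(precision * r_c)
    per_variable = {}
    for name, fs in factors.items():
        prod = 1.0
        for f in fs:
            prod *= 1.0 - f
        per_variable[name] = 1.0 - prod
    scope = target_class if target_class is not None else "all"
    return RelevanceTable(per_condition, per_variable, scope)
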