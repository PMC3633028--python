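"""Shared fixtures: small schemas, the published-rule fixture set, random
rule/dataset generators used by the brute-force oracle tests."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stablerules as sr

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def risk_schema():
    """The four categorical risk factors of the neuroblastoma setting."""
    return [
        sr.nominal("NB-hypo", ["Low", "High"]),
        sr.nominal("INSS", ["1", "2", "3", "4", "4s"]),
        sr.nominal("MYCN", ["normal", "amplified"]),
        sr.nominal("Age", ["<1y", ">=1y"]),
    ]


@pytest.fixture(scope="session")
def final_rules(risk_schema):
    """The published four-rule final classifier (two poor-outcome, two good-outcome)."""
    texts = {
        "4.1": "if INSS in {4} and Age in {>=1y} then outcome = Poor",
        "4.2": "if NB-hypo in {High} and INSS in {2, 3, 4} and Age in {>=1y} "
               "then outcome = Poor",
        "4.3": "if NB-hypo in {Low} and MYCN in {normal} then outcome = Good",
        "4.4": "if INSS in {1, 2, 3, 4s} and MYCN in {normal} "
               "then outcome = Good",
    }
    rules = [sr.parse_rule(t, risk_schema, rid) for rid, t in texts.items()]
    return sr.Classifier(rules, risk_schema)


@pytest.fixture(scope="session")
def mixed_schema():
    return [
        sr.nominal("color", ["red", "green", "blue"]),
        sr.ordered("x1", 0.0, 100.0),
    ]


def random_nominal_schema(rng: np.random.Generator, n_attrs=3, max_vals=3):
    return [
        sr.nominal(f"a{i}", [f"v{j}" for j in range(rng.integers(2, max_vals + 1))])
        for i in range(n_attrs)
    ]


def random_dataset(rng: np.random.Generator, schema, n=50, classes=("G", "P")):
    rows = {
        a.name: rng.choice(a.values, size=n)
        if a.kind == "nominal"
        else rng.uniform(a.low, a.high, size=n)
        for a in schema
    }
    frame = pd.DataFrame(rows, index=[f"i{k}" for k in range(n)])
    outcome = pd.Series(rng.choice(classes, size=n), index=frame.index)
    return sr.CohortDataset(list(schema), frame, outcome)


def random_rule(rng: np.random.Generator, schema, consequence, rule_id="r"):
    conds = []
    for attr in schema:
        if rng.random() < 0.4:
            continue
        if attr.kind == "nominal":
            k = int(rng.integers(1, len(attr.values) + 1))
            conds.append(sr.Condition(
                attr.name, "nominal",
                values=frozenset(rng.choice(attr.values, size=k, replace=False))))
        else:
            lo, hi = sorted(rng.uniform(attr.low, attr.high, size=2))
            if lo == hi:
                continue
            conds.append(sr.Condition(attr.name, "ordered", lo=lo, hi=hi))
    from stablerules.rules import normalize_conditions
    return sr.Rule(rule_id, normalize_conditions(conds), consequence)


def brute_force_counts(rule: sr.Rule, dataset: sr.CohortDataset) -> dict:
    """Independent per-instance, per-condition confusion-count oracle."""
    tp = fp = fn = tn = 0
    for iid in dataset.ids:
        row = dataset.frame.loc[iid]
        sat = all(c.satisfied_value(row[c.attribute]) for c in rule.conditions)
        target = str(dataset.outcome.loc[iid]) == rule.consequence
        if sat and target:
            tp += 1
        elif sat:
            fp += 1
        elif target:
            fn += 1
        else:
            tn += 1
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def full_grid(schema):
    """Every pattern of a finite (nominal-only) attribute grid."""
    domains = [attr.values for attr in schema]
    names = [attr.name for attr in schema]
    for combo in itertools.product(*domains):
        yield dict(zip(names, combo))


@pytest.fixture(scope="session")
def recovery_cohort():
    return sr.generate_cohort(sr.recovery_cohort_spec(), seed=11)


@pytest.fixture(scope="session")
def clean_cohort():
    """Recovery-style cohort without any injected noise."""
    spec = sr.recovery_cohort_spec(ambiguous_size=0, with_singleton=False)
    return sr.generate_cohort(spec, seed=5)
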