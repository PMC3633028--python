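"""Rule model: grammar, confusion counts, statistics, prediction, conflicts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stablerules as sr
from stablerules.rules import normalize_conditions
from stablerules.schema import make_dataset

from conftest import (
    brute_force_counts,
    full_grid,
    random_dataset,
    random_nominal_schema,
    random_rule,
)


# ---------------------------------------------------------------------------
# parsing and formatting
# ---------------------------------------------------------------------------

class TestGrammar:
    def test_ordered_and_member_conditions(self, mixed_schema):
        rule = sr.parse_rule(
            "if x1 > 40 and color in {red, blue} then outcome = 0",
            mixed_schema)
        assert rule.consequence == "0"
        x1 = rule.condition_on("x1")
        assert (x1.lo, x1.hi) == (40.0, np.inf)
        assert rule.condition_on("color").values == {"red", "blue"}

    def test_empty_premise_covers_everything(self, mixed_schema):
        rule = sr.parse_rule("if then outcome = Good", mixed_schema)
        ds = make_dataset(mixed_schema, [
            {"color": "red", "x1": 1.0, "outcome": "Good"},
            {"color": "blue", "x1": 99.0, "outcome": "Poor"},
        ])
        assert rule.conditions == ()
        assert rule.covers(ds).all()

    def test_published_style_rule(self, risk_schema):
        rule = sr.parse_rule(
            "if NB-hypo in {High} and INSS in {2, 3, 4} and Age in {>=1y} "
            "then outcome = Poor", risk_schema)
        assert [c.attribute for c in rule.conditions] == \
            ["Age", "INSS", "NB-hypo"]
        assert rule.consequence == "Poor"

    def test_interval_condition(self, mixed_schema):
        rule = sr.parse_rule("if 10 < x1 <= 20 then outcome = 1", mixed_schema)
        cond = rule.condition_on("x1")
        assert (cond.lo, cond.hi) == (10.0, 20.0)
        assert cond.satisfied_value(20.0) and not cond.satisfied_value(10.0)

    def test_duplicate_attribute_conditions_intersected(self, mixed_schema):
        rule = sr.parse_rule(
            "if x1 > 10 and x1 <= 50 then outcome = 1", mixed_schema)
        cond = rule.condition_on("x1")
        assert (cond.lo, cond.hi) == (10.0, 50.0)
        assert len(rule.conditions) == 1

    @pytest.mark.parametrize("text, error", [
        ("if x9 > 1 then outcome = 0", sr.SchemaError),
        ("if color in {purple} then outcome = 0", sr.SchemaError),
        ("if color > 4 then outcome = 0", sr.SchemaError),
        ("if x1 >> 4 then outcome = 0", Exception),
        ("x1 > 4 then outcome = 0", Exception),
        ("if x1 > 4 then outcome", Exception),
        ("if color in {} then outcome = 0", Exception),
    ])
    def test_errors(self, mixed_schema, text, error):
        with pytest.raises(error):
            sr.parse_rule(text, mixed_schema)

    def test_roundtrip_preserves_semantics(self, mixed_schema):
        rng = np.random.default_rng(42)
        ds = random_dataset(rng, mixed_schema, n=60)
        for k in range(25):
            rule = random_rule(rng, mixed_schema, "G", f"r{k}")
            back = sr.parse_rule(sr.format_rule(rule), mixed_schema, rule.id)
            assert np.array_equal(rule.covers(ds), back.covers(ds))


# ---------------------------------------------------------------------------
# confusion counts and C/E/P
# ---------------------------------------------------------------------------

class TestCounts:
    def test_unsatisfiable_premise(self, mixed_schema):
        ds = make_dataset(mixed_schema, [
            {"color": "red", "x1": 5.0, "outcome": "G"},
            {"color": "red", "x1": 6.0, "outcome": "G"},
            {"color": "blue", "x1": 7.0, "outcome": "P"},
        ])
        rule = sr.Rule("r", (sr.Condition("color", "nominal",
                                          values=frozenset()),), "G")
        assert sr.confusion_counts(rule, ds) == \
            {"TP": 0, "FP": 0, "FN": 2, "TN": 1}

    def test_always_true_rule(self, mixed_schema):
        rows = [{"color": "red", "x1": 1.0, "outcome": "G"}] * 3 \
            + [{"color": "blue", "x1": 2.0, "outcome": "P"}] * 2
        ds = make_dataset(mixed_schema, rows)
        rule = sr.Rule("r", (), "G")
        assert sr.confusion_counts(rule, ds) == \
            {"TP": 3, "FP": 2, "FN": 0, "TN": 0}

    def test_matches_per_instance_oracle(self, mixed_schema):
        rng = np.random.default_rng(7)
        for k in range(10):
            ds = random_dataset(rng, mixed_schema, n=50)
            rule = random_rule(rng, mixed_schema, "P", f"r{k}")
            counts = sr.confusion_counts(rule, ds)
            assert counts == brute_force_counts(rule, ds)
            assert sum(counts.values()) == ds.n

    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_stats_match_formula_oracle(self, counts):
        tp, fp, fn, tn = counts
        stats = sr.rule_stats({"TP": tp, "FP": fp, "FN": fn, "TN": tn})
        assert stats.covering == (tp / (tp + fn) if tp + fn else 0.0)
        assert stats.error == (fp / (tn + fp) if tn + fp else 0.0)
        assert stats.precision == (tp / (tp + fp) if tp + fp else 0.0)
        for value in (stats.covering, stats.error, stats.precision):
            assert 0.0 <= value <= 1.0
        # perfect precision iff no false positive with some coverage
        if stats.precision_defined:
            assert (stats.precision == 1.0) == (fp == 0 and tp > 0)

    def test_zero_denominators_flagged(self):
        stats = sr.rule_stats({"TP": 0, "FP": 0, "FN": 0, "TN": 5})
        assert (stats.covering, stats.precision) == (0.0, 0.0)
        assert not stats.covering_defined and not stats.precision_defined
        assert stats.error == 0.0 and stats.error_defined


# ---------------------------------------------------------------------------
# prediction policy
# ---------------------------------------------------------------------------

class TestClassify:
    def _clf(self, schema, spec):
        """spec: list of (id, text, covering, precision)."""
        rules = []
        for rid, text, cov, prec in spec:
            rule = sr.parse_rule(text, schema, rid)
            rules.append(sr.Rule(rid, rule.conditions, rule.consequence,
                                 sr.RuleStats(cov, 0.0, prec)))
        return sr.Classifier(rules, schema)

    def test_single_match(self, mixed_schema):
        clf = self._clf(mixed_schema, [
            ("a", "if color in {red} then outcome = Good", 0.5, 1.0),
            ("b", "if color in {blue} then outcome = Poor", 0.5, 1.0),
        ])
        assert sr.classify(clf, {"color": "red", "x1": 1.0}) == "Good"

    def test_highest_covering_wins(self, mixed_schema):
        clf = self._clf(mixed_schema, [
            ("a", "if x1 > 10 then outcome = Poor", 0.9, 1.0),
            ("b", "if color in {red} then outcome = Good", 0.5, 1.0),
        ])
        assert sr.classify(clf, {"color": "red", "x1": 50.0}) == "Poor"

    def test_covering_tie_broken_by_precision_then_order(self, mixed_schema):
        clf = self._clf(mixed_schema, [
            ("a", "if x1 > 10 then outcome = Poor", 0.5, 0.7),
            ("b", "if color in {red} then outcome = Good", 0.5, 0.9),
        ])
        assert sr.classify(clf, {"color": "red", "x1": 50.0}) == "Good"
        clf = self._clf(mixed_schema, [
            ("a", "if x1 > 10 then outcome = Poor", 0.5, 0.9),
            ("b", "if color in {red} then outcome = Good", 0.5, 0.9),
        ])
        assert sr.classify(clf, {"color": "red", "x1": 50.0}) == "Poor"

    def test_no_match_gives_nc(self, mixed_schema):
        clf = self._clf(mixed_schema, [
            ("a", "if color in {green} then outcome = Good", 0.5, 1.0),
        ])
        assert sr.classify(clf, {"color": "red", "x1": 1.0}) == sr.NC

    def test_empty_classifier_gives_nc(self, mixed_schema):
        clf = sr.Classifier([], mixed_schema)
        assert sr.classify(clf, {"color": "red", "x1": 1.0}) == sr.NC

    def test_never_invents_labels(self, mixed_schema):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, mixed_schema, n=40)
        clf = sr.Classifier(
            [random_rule(rng, mixed_schema, c, f"r{i}")
             for i, c in enumerate("GGPP")],
            mixed_schema).fit_stats(ds)
        predictions = set(clf.predict(ds))
        assert predictions <= {"G", "P", sr.NC}


# ---------------------------------------------------------------------------
# conflicts
# ---------------------------------------------------------------------------

class TestConflicts:
    def test_published_final_rules(self, final_rules):
        pairs = sr.conflict_pairs(final_rules)
        ids = {(p.rule_a.id, p.rule_b.id) for p in pairs}
        assert ids == {("4.1", "4.3"), ("4.2", "4.4")}
        texts = {sr.format_rule(p.nc_rule) for p in pairs}
        assert texts == {
            "if Age in {>=1y} and INSS in {4} and MYCN in {normal} "
            "and NB-hypo in {Low} then outcome = NC",
            "if Age in {>=1y} and INSS in {2, 3} and MYCN in {normal} "
            "and NB-hypo in {High} then outcome = NC",
        }

    def test_disjoint_member_sets_no_conflict(self, risk_schema):
        rules = [
            sr.parse_rule("if INSS in {1, 2} then outcome = Good",
                          risk_schema, "a"),
            sr.parse_rule("if INSS in {3, 4} then outcome = Poor",
                          risk_schema, "b"),
        ]
        assert sr.conflict_pairs(sr.Classifier(rules, risk_schema)) == []

    def test_interval_overlap_clipped_to_bounds(self, mixed_schema):
        # (90, inf] and (-inf, 95] overlap inside the domain [0, 100];
        # (120, inf] is unsatisfiable within the bounds
        mk = lambda t, rid: sr.parse_rule(t, mixed_schema, rid)
        clf = sr.Classifier([
            mk("if x1 > 90 then outcome = Poor", "a"),
            mk("if x1 <= 95 then outcome = Good", "b"),
        ], mixed_schema)
        assert len(sr.conflict_pairs(clf)) == 1
        clf = sr.Classifier([
            mk("if x1 > 120 then outcome = Poor", "a"),
            mk("if x1 <= 95 then outcome = Good", "b"),
        ], mixed_schema)
        assert sr.conflict_pairs(clf) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        schema = random_nominal_schema(rng)
        rules = [random_rule(rng, schema, c, f"r{i}")
                 for i, c in enumerate(rng.choice(["G", "P"], size=4))]
        clf = sr.Classifier(rules, schema)
        reported = {frozenset((p.rule_a.id, p.rule_b.id))
                    for p in sr.conflict_pairs(clf)}
        expected = set()
        for pattern in full_grid(schema):
            hit = [r for r in rules if r.covers_pattern(pattern)]
            for i in range(len(hit)):
                for j in range(i + 1, len(hit)):
                    if hit[i].consequence != hit[j].consequence:
                        expected.add(frozenset((hit[i].id, hit[j].id)))
        assert reported == expected

    def test_nc_rule_covers_exactly_the_overlap(self, final_rules, risk_schema):
        for pair in sr.conflict_pairs(final_rules):
            for pattern in full_grid(risk_schema):
                both = pair.rule_a.covers_pattern(pattern) \
                    and pair.rule_b.covers_pattern(pattern)
                assert pair.nc_rule.covers_pattern(pattern) == both


def test_normalize_merges_and_sorts():
    conds = [sr.member("b", ["x", "y"]), sr.member("a", ["1"]),
             sr.member("b", ["y", "z"])]
    merged = normalize_conditions(conds)
    assert [c.attribute for c in merged] == ["a", "b"]
    assert merged[1].values == {"y"}
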