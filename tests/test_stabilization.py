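"""Instability diagnosis, the stabilization loop, matched test purging."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stablerules as sr
from stablerules.schema import make_dataset
from stablerules.stability import CoreRule, CoreRuleSet, FoldClassifier
from stablerules.stabilization import (
    CAUSE_AMBIGUOUS,
    CAUSE_LOW_COVERING,
    CAUSE_NEAR_DUPLICATE,
)


def core_set(dataset, entries, eps=0.05):
    """Build a CoreRuleSet from (rule text, consequence stability) pairs."""
    rules = []
    for i, (text, stab) in enumerate(entries):
        rule = sr.parse_rule(text, dataset.schema, f"core-{i + 1}")
        rules.append(CoreRule(rule.with_stats(dataset), stab, ()))
    return CoreRuleSet(rules, 50, eps)


class TestDiagnosis:
    def test_ambiguous_profile_group_flagged(self):
        # one profile duplicated with an even class split: every copy is
        # flagged, regardless of any rule
        ds = sr.generate_cohort(sr.nb_cohort_spec(), seed=8)
        core = core_set(ds, [("if then outcome = Good", 1.0)])
        diag = sr.diagnose_instability(ds, core, None,
                                       sr.StabilizationConfig())
        ambiguous = {f.instance_id for f in diag.flagged
                     if f.cause == CAUSE_AMBIGUOUS}
        planted = set(ds.ids[(ds.provenance == "ambiguous").to_numpy()])
        assert ambiguous == planted
        assert len(ambiguous) == 24

    def test_clean_stable_cohort_yields_empty_diagnosis(self, clean_cohort):
        core = core_set(clean_cohort, [
            ("if A in {a1} then outcome = case", 1.0),
            ("if A in {a2} then outcome = control", 1.0),
        ])
        diag = sr.diagnose_instability(clean_cohort, core, None,
                                       sr.StabilizationConfig())
        assert diag.flagged == []

    def test_near_duplicate_rules_flag_the_difference(self):
        # two same-consequence rules differing by exactly one covered
        # instance: that instance is the second instability cause
        schema = [sr.nominal("g", ["u", "v", "w"])]
        rows = [{"g": "u", "outcome": "P"}] * 6 \
            + [{"g": "v", "outcome": "P"}] + [{"g": "w", "outcome": "G"}] * 6
        ds = make_dataset(schema, rows, ids=[f"i{k}" for k in range(13)])
        core = core_set(ds, [
            ("if g in {u, v} then outcome = P", 0.5),
            ("if g in {u} then outcome = P", 1.0),
            ("if g in {w} then outcome = G", 1.0),
        ])
        diag = sr.diagnose_instability(ds, core, None,
                                       sr.StabilizationConfig())
        flagged = {f.instance_id: f.cause for f in diag.flagged}
        assert flagged == {"i6": CAUSE_NEAR_DUPLICATE}

    def test_low_covering_unstable_rule_flags_exclusive_instances(self):
        # the unstable two-instance rule covers i20/i21 exclusively and has
        # covering 2/22 <= 0.1; the difference of two instances stays above
        # the near-duplicate threshold, so only the first cause fires
        schema = [sr.nominal("g", ["u", "v", "w"])]
        rows = [{"g": "u", "outcome": "P"}] * 20 \
            + [{"g": "v", "outcome": "P"}] * 2 \
            + [{"g": "w", "outcome": "G"}] * 10
        ds = make_dataset(schema, rows, ids=[f"i{k}" for k in range(32)])
        core = core_set(ds, [
            ("if g in {u} then outcome = P", 1.0),
            ("if g in {v} then outcome = P", 0.9),
            ("if g in {w} then outcome = G", 1.0),
        ])
        diag = sr.diagnose_instability(ds, core, None,
                                       sr.StabilizationConfig())
        flagged = {f.instance_id: f.cause for f in diag.flagged}
        assert flagged == {"i20": CAUSE_LOW_COVERING,
                          "i21": CAUSE_LOW_COVERING}

    def test_instances_under_a_stable_rule_never_flagged_as_low_covering(self):
        schema = [sr.nominal("g", ["u", "v", "w"])]
        rows = [{"g": "u", "outcome": "P"}] * 10 \
            + [{"g": "v", "outcome": "P"}] + [{"g": "w", "outcome": "G"}] * 10
        ds = make_dataset(schema, rows, ids=[f"i{k}" for k in range(21)])
        core = core_set(ds, [
            # the stable broad rule also covers i10
            ("if g in {u, v} then outcome = P", 1.0),
            ("if g in {v} then outcome = P", 0.9),
            ("if g in {w} then outcome = G", 1.0),
        ])
        diag = sr.diagnose_instability(ds, core, None,
                                       sr.StabilizationConfig())
        assert all(f.instance_id != "i10" or f.cause != CAUSE_LOW_COVERING
                   for f in diag.flagged)


class TestStabilize:
    def test_converges_and_removes_exactly_the_planted_noise(
            self, recovery_cohort):
        result = sr.stabilize(recovery_cohort,
                              sr.StabilizationConfig(cv=sr.CVConfig(seed=11)))
        removed = set(result.removed_ids)
        planted = set(recovery_cohort.ids[
            (recovery_cohort.provenance != "clean").to_numpy()])
        assert removed == planted
        assert min(result.log[-1].stabilities.values()) == 1.0
        assert result.dataset.n == recovery_cohort.n - len(planted)

    def test_already_stable_dataset_short_circuits(self, clean_cohort):
        result = sr.stabilize(clean_cohort,
                              sr.StabilizationConfig(cv=sr.CVConfig(seed=5)))
        assert len(result.log) == 1
        assert result.removed_ids == []
        assert min(result.log[0].stabilities.values()) == 1.0

    def test_removed_sets_disjoint_across_iterations(self, recovery_cohort):
        result = sr.stabilize(recovery_cohort,
                              sr.StabilizationConfig(cv=sr.CVConfig(seed=11)))
        seen = set()
        for entry in result.log:
            assert not (seen & set(entry.removed))
            seen |= set(entry.removed)
        assert seen == set(result.removed_ids)

    def test_final_classifier_reproduces_stability_on_purged_cohort(
            self, recovery_cohort):
        cfg = sr.StabilizationConfig(cv=sr.CVConfig(seed=11))
        result = sr.stabilize(recovery_cohort, cfg)
        folds = sr.run_cv(result.dataset, cfg.cv, cfg.induction)
        from stablerules.stability import stability_report
        report = stability_report(result.classifier, folds, result.dataset,
                                  cfg.epsilon)
        assert report.min_stability >= 1.0 - cfg.nu

    def test_no_conflict_overlap_remains_after_stabilization(
            self, recovery_cohort):
        result = sr.stabilize(recovery_cohort,
                              sr.StabilizationConfig(cv=sr.CVConfig(seed=11)))
        for pair in sr.conflict_pairs(result.classifier):
            nc_mask = pair.nc_rule.covers(result.dataset)
            assert not nc_mask.any()

    def test_estimator_facade(self, recovery_cohort):
        est = sr.StabilizedRuleClassifier(schema=recovery_cohort.schema,
                                          random_state=11)
        est.fit(recovery_cohort.frame, recovery_cohort.outcome)
        assert est.iterations_ >= 1
        assert min(est.stability_.values()) == 1.0
        planted = set(recovery_cohort.ids[
            (recovery_cohort.provenance != "clean").to_numpy()])
        assert set(est.removed_ids_) == planted
        pred = est.predict(recovery_cohort.frame)
        kept = ~recovery_cohort.ids.isin(est.removed_ids_)
        assert (pred[kept] ==
                recovery_cohort.outcome.to_numpy()[kept]).all()

    def test_non_convergence_raises_with_log(self):
        # contradictions cannot stabilize when the ambiguous cause is
        # switched off by construction: force failure via max_iterations=1
        # on a cohort that needs two purges
        spec = sr.recovery_cohort_spec()
        ds = sr.generate_cohort(spec, seed=23)
        cfg = sr.StabilizationConfig(max_iterations=1,
                                     cv=sr.CVConfig(seed=23))
        with pytest.raises(sr.StabilizationError) as exc:
            sr.stabilize(ds, cfg)
        assert exc.value.log


class TestPurgeMatched:
    def test_no_shared_profile_leaves_test_untouched(self, clean_cohort):
        purged, dropped = sr.purge_matched(
            clean_cohort, [("a1", "b9", "c9")])
        assert dropped == []
        assert purged.n == clean_cohort.n

    def test_full_profile_match_empties_test_set(self, risk_schema):
        rows = [{"NB-hypo": "Low", "INSS": "4", "MYCN": "normal",
                 "Age": ">=1y", "outcome": "Good"}] * 4
        ds = make_dataset(risk_schema, rows, ids=list("abcd"))
        purged, dropped = sr.purge_matched(
            ds, [("Low", "4", "normal", ">=1y")])
        assert set(dropped) == set("abcd")
        assert purged.n == 0

    def test_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(9)
        spec = sr.recovery_cohort_spec()
        train = sr.generate_cohort(spec, seed=31)
        test = sr.generate_cohort(sr.recovery_cohort_spec(n=80), seed=32)
        removed_ids = list(rng.choice(train.ids, size=15, replace=False))
        purged, dropped = sr.purge_matched(
            test, [], train=train, removed_ids=removed_ids)
        removed_profiles = set(train.profiles().loc[removed_ids])
        expected = [iid for iid, p in test.profiles().items()
                    if p in removed_profiles]
        assert sorted(dropped) == sorted(expected)
        assert purged.n == test.n - len(expected)
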