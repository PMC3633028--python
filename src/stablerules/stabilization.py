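"""Iterative rule stabilization.

The stabilization loop couples induction with repeated cross-validation:
induce on the full current cohort, measure every rule's stability across
the N CV classifiers, and stop as soon as each rule is stable (stability
at least 1 - nu; nu = 0 demands exactly 1).  Otherwise Core rules are
built from the CV classifiers and used to diagnose which instances cause
the instability:

1. *low-covering unstable rule* — instances covered by an unstable Core
   rule of low covering and by no other stable rule; such a rule only
   arises when all of its few supporting instances land in the training
   split;
2. *near-duplicate rule* — two same-consequence rules whose covered sets
   differ by at most a handful of instances; those difference instances
   force the redundant rule into existence;
3. *ambiguous profile* — a group of instances sharing one full attribute
   profile but holding more than one outcome label, whose predicted class
   can only reflect the chance split between training and test sets.

Flagged instances are removed from the cohort and the cycle repeats.  On
success every rule of the returned classifier has stability >= 1 - nu.
A matched purge (:func:`purge_matched`) removes, from an independent test
cohort, every instance whose full profile equals a removed one, so that
held-out evaluation sees the same exclusions as training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .induction import InductionConfig, RuleInductionClassifier, induce_classifier
from .rules import Classifier
from .schema import AttributeSchema, CohortDataset
from .stability import (
    CoreRuleSet,
    CVConfig,
    StabilityReport,
    build_core_rules,
    run_cv,
    stability_report,
)

CAUSE_LOW_COVERING = "low_covering_unstable"
CAUSE_NEAR_DUPLICATE = "near_duplicate_rule"
CAUSE_AMBIGUOUS = "ambiguous_profile"


class StabilizationError(RuntimeError):
    """Stabilization could not converge; carries the iteration log."""

    def __init__(self, message: str, log: list):
        super().__init__(message)
        self.log = log


@dataclass(frozen=True)
class StabilizationConfig:
    """Thresholds of the stabilization loop.

    ``nu`` is the stability slack (0 demands stability exactly 1);
    ``s_cov`` the covering below which an unstable rule counts as
    low-covering; ``s_diff`` the largest covered-set difference that marks
    a rule pair as near-duplicates; ``epsilon`` the occurrence-matching
    tolerance.
    """

    nu: float = 0.0
    s_cov: float = 0.1
    s_diff: int = 1
    epsilon: float = 0.05
    max_iterations: int = 10
    cv: CVConfig = field(default_factory=CVConfig)
    induction: InductionConfig = field(default_factory=InductionConfig)

    def __post_init__(self):
        if not 0.0 <= self.nu < 1.0:
            raise ValueError("nu must lie in [0, 1)")
        if not 0.0 < self.s_cov <= 1.0:
            raise ValueError("s_cov must lie in (0, 1]")
        if self.s_diff < 1:
            raise ValueError("s_diff must be >= 1")


@dataclass(frozen=True)
class FlaggedInstance:
    instance_id: object
    cause: str
    evidence: tuple


@dataclass
class InstabilityDiagnosis:
    flagged: list[FlaggedInstance]

    @property
    def instance_ids(self) -> list:
        seen, out = set(), []
        for f in self.flagged:
            if f.instance_id not in seen:
                seen.add(f.instance_id)
                out.append(f.instance_id)
        return out

    def causes_of(self, instance_id) -> set[str]:
        return {f.cause for f in self.flagged if f.instance_id == instance_id}


@dataclass
class IterationLog:
    iteration: int
    n_instances: int
    rules: list
    stabilities: dict
    removed: list
    causes: dict


@dataclass
class StabilizationResult:
    classifier: Classifier
    removed: list[FlaggedInstance]
    log: list[IterationLog]
    dataset: CohortDataset  # purged cohort the final classifier was fit on

    @property
    def removed_ids(self) -> list:
        seen, out = set(), []
        for f in self.removed:
            if f.instance_id not in seen:
                seen.add(f.instance_id)
                out.append(f.instance_id)
        return out


# ---------------------------------------------------------------------------
# Diagnosis
# ---------------------------------------------------------------------------

def diagnose_instability(
    dataset: CohortDataset,
    core_rules: CoreRuleSet,
    stability: StabilityReport | None,
    config: StabilizationConfig,
) -> InstabilityDiagnosis:
    """Flag the instances behind the three instability causes.

    Causes 1 and 2 are read off the Core rules (whose aggregated
    stabilities summarise the CV classifiers); cause 3 is read off the
    cohort profiles directly.  Flags are deduplicated per (instance,
    cause); one instance may carry several causes.
    """
    flagged: list[FlaggedInstance] = []
    ids = dataset.ids
    stable_mask = np.zeros(dataset.n, dtype=bool)
    for core in core_rules.rules:
        if core.stability >= 1.0 - config.nu:
            stable_mask |= core.rule.covers(dataset)

    # cause 1: unstable, low-covering rules
    for core in core_rules.rules:
        if core.stability >= 1.0 - config.nu:
            continue
        stats = core.rule.stats
        covering = stats.covering if stats is not None else 0.0
        if covering > config.s_cov:
            continue
        mask = core.rule.covers(dataset) & ~stable_mask
        for iid in ids[mask]:
            flagged.append(FlaggedInstance(iid, CAUSE_LOW_COVERING,
                                           (core.rule.id,)))

    # cause 2: near-duplicate same-consequence rule pairs
    covers = {c.rule.id: c.rule.covers(dataset) for c in core_rules.rules}
    for a in core_rules.rules:
        for b in core_rules.rules:
            if a.rule.id == b.rule.id or \
                    a.rule.consequence != b.rule.consequence:
                continue
            diff = covers[a.rule.id] & ~covers[b.rule.id]
            size = int(np.sum(diff))
            if 1 <= size <= config.s_diff:
                for iid in ids[diff]:
                    flagged.append(FlaggedInstance(
                        iid, CAUSE_NEAR_DUPLICATE, (a.rule.id, b.rule.id)))

    # cause 3: one profile, several outcome labels
    profiles = dataset.profiles()
    labels = dataset.outcome.astype(str)
    for profile, group in labels.groupby(profiles.to_numpy()):
        if group.nunique() > 1:
            for iid in group.index:
                flagged.append(FlaggedInstance(iid, CAUSE_AMBIGUOUS,
                                               (profile,)))

    seen = set()
    unique = []
    for f in flagged:
        key = (f.instance_id, f.cause)
        if key not in seen:
            seen.add(key)
            unique.append(f)
    return InstabilityDiagnosis(unique)


# ---------------------------------------------------------------------------
# The stabilization loop
# ---------------------------------------------------------------------------

def stabilize(
    dataset: CohortDataset,
    config: StabilizationConfig | None = None,
) -> StabilizationResult:
    """Run the iterative stabilization loop to a fully stable classifier.

    Each iteration induces on the full current cohort, assesses per-rule
    stability in repeated CV, and either returns (all rules stable) or
    removes the diagnosed instances and recurses.  Raises
    :class:`StabilizationError` when the loop exceeds ``max_iterations``
    or a diagnosis flags nothing while instability persists.
    """
    config = config or StabilizationConfig()
    current = dataset
    removed: list[FlaggedInstance] = []
    log: list[IterationLog] = []

    for iteration in range(1, config.max_iterations + 1):
        clf = induce_classifier(current, config.induction)
        folds = run_cv(current, config.cv, config.induction)
        report = stability_report(clf, folds, current, config.epsilon)
        stabilities = {rule.id: s for rule, _, s in report.entries}
        entry = IterationLog(iteration, current.n,
                             [r.text() for r in clf.rules],
                             stabilities, [], {})
        log.append(entry)

        # a contradictory profile yields maximally specific rules that are
        # trivially stable in CV yet conflict on the very same pattern, so
        # convergence additionally requires a contradiction-free classifier
        if report.min_stability >= 1.0 - config.nu and not clf.contradictions:
            return StabilizationResult(clf, removed, log, current)

        core = build_core_rules(folds, config.epsilon, current)
        diagnosis = diagnose_instability(current, core, report, config)
        ids = diagnosis.instance_ids
        if not ids:
            raise StabilizationError(
                f"iteration {iteration}: instability persists "
                f"(min stability {report.min_stability:.2f}) but the "
                f"diagnosis flags no instance", log)
        entry.removed = list(ids)
        entry.causes = {iid: sorted(diagnosis.causes_of(iid)) for iid in ids}
        removed.extend(f for f in diagnosis.flagged)
        current = current.drop(ids)

    raise StabilizationError(
        f"no fully stable classifier within {config.max_iterations} "
        f"iterations", log)


def purge_matched(
    test: CohortDataset,
    removed_profiles: list[tuple] | CohortDataset,
    train: CohortDataset | None = None,
    removed_ids: list | None = None,
) -> tuple[CohortDataset, list]:
    """Remove from ``test`` every instance whose full attribute profile
    equals the profile of a removed training instance; returns the purged
    copy and the removed test ids."""
    if isinstance(removed_profiles, CohortDataset):
        profiles = set(removed_profiles.profiles())
    elif train is not None and removed_ids is not None:
        profiles = set(train.profiles().loc[removed_ids])
    else:
        profiles = set(map(tuple, removed_profiles))
    test_profiles = test.profiles()
    drop = [iid for iid, p in test_profiles.items() if p in profiles]
    return test.drop(drop), drop


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class StabilizedRuleClassifier(ClassifierMixin, BaseEstimator):
    """Rule classifier fitted through the iterative stabilization loop.

    Fitting runs bottom-up rule induction inside repeated stratified
    cross-validation, removes the instances diagnosed as instability
    sources, and stops when every rule's stability reaches ``1 - nu``.

    Parameters mirror :class:`StabilizationConfig` plus the induction and
    CV settings; ``random_state`` seeds the CV fold assignment.

    Attributes
    ----------
    classifier_ : Classifier
        The final, fully stable rule set.
    rules_ : list[Rule]
    stability_ : dict
        Per-rule stability of the final classifier.
    removed_ids_ : list
        Training instances removed as instability sources.
    removed_profiles_ : list[tuple]
        Their full attribute profiles (inputs to a matched test purge).
    iterations_ : int
    log_ : list[IterationLog]
    """

    def __init__(
        self,
        schema: list[AttributeSchema] | None = None,
        nu: float = 0.0,
        s_cov: float = 0.1,
        s_diff: int = 1,
        epsilon: float = 0.05,
        max_iterations: int = 10,
        cv_repetitions: int = 5,
        cv_folds: int = 10,
        stratified: bool = True,
        max_training_error: float = 0.0,
        min_class_distance: float = 0.20,
        random_state: int = 0,
    ):
        self.schema = schema
        self.nu = nu
        self.s_cov = s_cov
        self.s_diff = s_diff
        self.epsilon = epsilon
        self.max_iterations = max_iterations
        self.cv_repetitions = cv_repetitions
        self.cv_folds = cv_folds
        self.stratified = stratified
        self.max_training_error = max_training_error
        self.min_class_distance = min_class_distance
        self.random_state = random_state

    def _config(self) -> StabilizationConfig:
        return StabilizationConfig(
            nu=self.nu, s_cov=self.s_cov, s_diff=self.s_diff,
            epsilon=self.epsilon, max_iterations=self.max_iterations,
            cv=CVConfig(repetitions=self.cv_repetitions, folds=self.cv_folds,
                        stratified=self.stratified,
                        seed=int(self.random_state or 0)),
            induction=InductionConfig(
                max_training_error=self.max_training_error,
                min_class_distance=self.min_class_distance),
        )

    def fit(self, X, y=None):
        helper = RuleInductionClassifier(schema=self.schema)
        dataset = helper._as_dataset(X, y if y is not None else X.outcome)
        result = stabilize(dataset, self._config())
        self.result_ = result
        self.classifier_ = result.classifier
        self.rules_ = result.classifier.rules
        self.stability_ = result.log[-1].stabilities
        self.removed_ids_ = result.removed_ids
        self.removed_profiles_ = [
            tuple(p) for p in dataset.profiles().loc[self.removed_ids_]
        ]
        self.iterations_ = len(result.log)
        self.log_ = result.log
        self.schema_ = result.classifier.schema
        self.classes_ = np.asarray(result.dataset.classes, dtype=object)
        self.n_features_in_ = len(self.schema_)
        return self

    def predict(self, X):
        check_is_fitted(self, "classifier_")
        frame = X.frame if isinstance(X, CohortDataset) else pd.DataFrame(X)
        return self.classifier_.predict_frame(frame).to_numpy(dtype=object)
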