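"""Cross-validation rule stability and Core rules.

Repeated stratified k-fold cross-validation yields N = repetitions x folds
classifiers, each induced on a different training subset.  Two rules with
the same consequence count as occurrences of the same rule when their
covered sets on the full reference cohort are close (coverage Jaccard
distance below a tolerance epsilon).  The *stability* of a reference rule
is b / N, where b is the number of CV classifiers containing at least one
occurrence of it; a rule at stability 1 is recovered from every training
subset.

*Core rules* condense the N classifiers: same-consequence rules are
clustered (single linkage at distance epsilon) and each cluster is
replaced by the attribute-wise intersection of its component premises,
whose covered set is therefore contained in every component's covered
set.  The aggregated stability of a Core rule is the fraction of CV
classifiers contributing at least one component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold

from .induction import InductionConfig, induce_classifier
from .rules import Classifier, Rule, normalize_conditions, premise_satisfiable
from .schema import CohortDataset


@dataclass(frozen=True)
class CVConfig:
    """Repeated cross-validation settings (5 x 10-fold by default)."""

    repetitions: int = 5
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def n_classifiers(self) -> int:
        return self.repetitions * self.folds


@dataclass(frozen=True)
class FoldClassifier:
    classifier: Classifier
    repetition: int
    fold: int
    test_ids: tuple


@dataclass
class StabilityReport:
    """Per-rule occurrence counts across the CV classifiers."""

    entries: list = field(default_factory=list)  # (rule, b, stability)
    n_classifiers: int = 0
    epsilon: float = 0.05

    @property
    def min_stability(self) -> float:
        return min((s for _, _, s in self.entries), default=1.0)

    def stability_of(self, rule_id: str) -> float:
        for rule, _, s in self.entries:
            if rule.id == rule_id:
                return s
        raise KeyError(rule_id)


@dataclass(frozen=True)
class CoreRule:
    rule: Rule
    stability: float
    components: tuple  # (classifier index, rule id)


@dataclass
class CoreRuleSet:
    rules: list[CoreRule]
    n_classifiers: int
    epsilon: float


def run_cv(
    dataset: CohortDataset,
    cv_config: CVConfig | None = None,
    induction_config: InductionConfig | None = None,
) -> list[FoldClassifier]:
    """Induce one classifier per held-out fold per repetition.

    Fold assignment is stratified (unless disabled) and fully determined
    by the seed; with stratification every class must hold at least
    ``folds`` instances.
    """
    cv = cv_config or CVConfig()
    ind = induction_config or InductionConfig()
    y = dataset.outcome.astype(str).to_numpy()
    if cv.stratified:
        smallest = min(np.unique(y, return_counts=True)[1])
        if smallest < cv.folds:
            raise ValueError(
                f"smallest class has {smallest} instances; stratified "
                f"{cv.folds}-fold CV needs at least {cv.folds} per class "
                f"(use fewer folds)"
            )
    out: list[FoldClassifier] = []
    rng = np.random.SeedSequence(cv.seed)
    rep_seeds = [int(s) for s in rng.generate_state(cv.repetitions) % (2**31 - 1)]
    for rep in range(cv.repetitions):
        splitter_cls = StratifiedKFold if cv.stratified else KFold
        splitter = splitter_cls(n_splits=cv.folds, shuffle=True,
                                random_state=rep_seeds[rep])
        for fold, (train_idx, test_idx) in enumerate(
            splitter.split(np.zeros(dataset.n), y)
        ):
            train = dataset.subset(dataset.ids[train_idx])
            clf = induce_classifier(train, ind)
            clf.source = f"rep{rep}-fold{fold}"
            out.append(FoldClassifier(clf, rep, fold,
                                      tuple(dataset.ids[test_idx])))
    return out


def rule_distance(r1: Rule, r2: Rule, dataset: CohortDataset) -> float | None:
    """Coverage Jaccard distance on the reference cohort.

    ``None`` (incomparable) when the consequences differ, or when both
    covered sets are empty and the premises are not symbolically equal.
    """
    if r1.consequence != r2.consequence:
        return None
    m1, m2 = r1.covers(dataset), r2.covers(dataset)
    union = int(np.sum(m1 | m2))
    if union == 0:
        same = normalize_conditions(r1.conditions) == \
            normalize_conditions(r2.conditions)
        return 0.0 if same else None
    inter = int(np.sum(m1 & m2))
    return 1.0 - inter / union


def rule_stability(
    reference: Rule,
    classifiers: list[FoldClassifier],
    epsilon: float,
    dataset: CohortDataset,
) -> float:
    """Fraction of CV classifiers containing an occurrence of ``reference``."""
    b = 0
    for fc in classifiers:
        for rule in fc.classifier.rules:
            d = rule_distance(reference, rule, dataset)
            if d is not None and d < epsilon:
                b += 1
                break
    return b / len(classifiers)


def stability_report(
    classifier: Classifier,
    classifiers: list[FoldClassifier],
    dataset: CohortDataset,
    epsilon: float = 0.05,
) -> StabilityReport:
    report = StabilityReport(n_classifiers=len(classifiers), epsilon=epsilon)
    for rule in classifier.rules:
        s = rule_stability(rule, classifiers, epsilon, dataset)
        report.entries.append((rule, round(s * len(classifiers)), s))
    return report


def build_core_rules(
    classifiers: list[FoldClassifier],
    epsilon: float,
    dataset: CohortDataset,
) -> CoreRuleSet:
    """Cluster same-consequence rules across the CV classifiers (single
    linkage under the coverage distance) and intersect each cluster's
    premises into a Core rule; clusters whose intersection is unsatisfiable
    are dropped."""
    pool = [(ci, rule) for ci, fc in enumerate(classifiers)
            for rule in fc.classifier.rules]
    n = len(pool)
    masks = [rule.covers(dataset) for _, rule in pool]

    # union-find over occurrence pool
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = pool[i][1], pool[j][1]
            if ri.consequence != rj.consequence:
                continue
            union = int(np.sum(masks[i] | masks[j]))
            if union == 0:
                d = rule_distance(ri, rj, dataset)
                if d is None or d >= epsilon:
                    continue
            else:
                inter = int(np.sum(masks[i] & masks[j]))
                if 1.0 - inter / union >= epsilon:
                    continue
            parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    core: list[CoreRule] = []
    seq = 0
    for members in clusters.values():
        conds = []
        for i in members:
            conds.extend(pool[i][1].conditions)
        premise = normalize_conditions(conds)
        if not premise_satisfiable(premise, dataset.schema):
            continue
        seq += 1
        stability = len({pool[i][0] for i in members}) / len(classifiers)
        rule = Rule(f"core-{seq}", premise, pool[members[0]][1].consequence)
        core.append(CoreRule(rule.with_stats(dataset), stability,
                             tuple((pool[i][0], pool[i][1].id)
                                   for i in members)))
    return CoreRuleSet(core, len(classifiers), epsilon)
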