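"""Synthetic cohorts with planted structure, and the k-means dichotomizer.

The cohort generator emulates the statistical shape the stabilization
method assumes: categorical risk factors drawn from declared marginal
frequencies, outcomes produced by planted first-match rules over those
attributes, plus the two kinds of deliberately injected noise the
diagnosis is meant to find — *ambiguous groups* (many copies of one full
profile with an exact split of outcome labels) and *singletons* (a lone
instance whose label contradicts its planted neighbourhood, forcing a
private rule).  Background sampling avoids the injected profiles so the
ground-truth provenance (clean / ambiguous / singleton) partitions the
cohort exactly.

The expression generator produces a samples x probe-sets matrix as a
two-group Gaussian mixture, and :func:`kmeans_dichotomize` reduces such a
matrix to a binary attribute with Manhattan-distance k-means
(order-preserving deterministic initialisation) together with the
sum-of-within-cluster-distance curve used to pick the cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rules import Rule, member, parse_rule
from .schema import AttributeSchema, CohortDataset, SchemaError, nominal


@dataclass(frozen=True)
class AmbiguousGroup:
    """``size`` copies of one full profile, labels fixed by ``split``."""

    profile: dict
    size: int
    split: dict  # class label -> count; counts sum to size


@dataclass(frozen=True)
class SingletonInjection:
    profile: dict
    label: str


@dataclass
class CohortSpec:
    n: int
    schema: list[AttributeSchema]
    marginals: dict  # attribute -> {value: probability}
    planted_rules: list[Rule]
    background_class: str
    label_noise: float = 0.0
    ambiguous_groups: list[AmbiguousGroup] = field(default_factory=list)
    singletons: list[SingletonInjection] = field(default_factory=list)

    def __post_init__(self):
        for attr in self.schema:
            if attr.kind != "nominal":
                raise SchemaError(
                    "the cohort generator draws nominal attributes; "
                    f"{attr.name!r} is ordered"
                )
            probs = self.marginals.get(attr.name)
            if probs is None:
                raise SchemaError(f"no marginals for attribute {attr.name!r}")
            if set(probs) != set(attr.values):
                raise SchemaError(
                    f"marginals of {attr.name!r} must cover its domain"
                )
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise SchemaError(f"marginals of {attr.name!r} must sum to 1")
        injected = sum(g.size for g in self.ambiguous_groups) \
            + len(self.singletons)
        if injected > self.n:
            raise SchemaError("injected instances exceed the cohort size")
        for group in self.ambiguous_groups:
            if sum(group.split.values()) != group.size:
                raise SchemaError("ambiguous split counts must sum to size")
        for profile in [g.profile for g in self.ambiguous_groups] \
                + [s.profile for s in self.singletons]:
            for attr in self.schema:
                if attr.name not in profile:
                    raise SchemaError(
                        f"injected profile lacks attribute {attr.name!r}")
                if not attr.contains(profile[attr.name]):
                    raise SchemaError(
                        f"injected value {profile[attr.name]!r} outside the "
                        f"domain of {attr.name!r}")


def planted_label(spec: CohortSpec, row: dict) -> str:
    """Outcome the planted first-match rules assign to a profile."""
    for rule in spec.planted_rules:
        if rule.covers_pattern(row):
            return rule.consequence
    return spec.background_class


def generate_cohort(spec: CohortSpec, seed: int) -> CohortDataset:
    """Draw a cohort; same (spec, seed) gives the identical cohort.

    The returned dataset carries a ``provenance`` series with values
    ``clean`` / ``ambiguous`` / ``singleton``.
    """
    rng = np.random.default_rng(seed)
    forbidden = {
        tuple(str(p[a.name]) for a in spec.schema)
        for p in ([g.profile for g in spec.ambiguous_groups]
                  + [s.profile for s in spec.singletons])
    }
    n_background = spec.n - sum(g.size for g in spec.ambiguous_groups) \
        - len(spec.singletons)

    names = [a.name for a in spec.schema]
    rows, labels, provenance = [], [], []
    classes = sorted({spec.background_class}
                     | {r.consequence for r in spec.planted_rules})
    while len(rows) < n_background:
        row = {
            a.name: str(rng.choice(list(spec.marginals[a.name]),
                                   p=list(spec.marginals[a.name].values())))
            for a in spec.schema
        }
        if tuple(row[n] for n in names) in forbidden:
            continue
        label = planted_label(spec, row)
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            others = [c for c in classes if c != label]
            if others:
                label = str(rng.choice(others))
        rows.append(row)
        labels.append(label)
        provenance.append("clean")

    for group in spec.ambiguous_groups:
        for cls, count in sorted(group.split.items()):
            for _ in range(count):
                rows.append({n: str(group.profile[n]) for n in names})
                labels.append(cls)
                provenance.append("ambiguous")
    for single in spec.singletons:
        rows.append({n: str(single.profile[n]) for n in names})
        labels.append(single.label)
        provenance.append("singleton")

    order = rng.permutation(len(rows))
    ids = [f"p{i + 1:04d}" for i in range(len(rows))]
    frame = pd.DataFrame([rows[i] for i in order], index=ids)
    outcome = pd.Series([labels[i] for i in order], index=ids)
    prov = pd.Series([provenance[i] for i in order], index=ids)
    return CohortDataset(list(spec.schema), frame, outcome, prov)


# ---------------------------------------------------------------------------
# Ready-made cohort specifications
# ---------------------------------------------------------------------------

def nb_cohort_spec(n: int = 182, ambiguous_size: int = 24) -> CohortSpec:
    """A neuroblastoma-like cohort: four categorical risk factors with
    study-like marginal frequencies (47% of patients younger than one
    year, 38% stage 4, 16% MYCN-amplified, about a quarter with high
    hypoxia signature), outcomes planted by the two poor-outcome rules
    "stage 4 and age >= 1" and "high hypoxia and stage 2-4 and age >= 1",
    and a 24-patient ambiguous group (low hypoxia, stage 4, normal MYCN,
    age >= 1) split 12/12 between the outcome classes."""
    schema = [
        nominal("NB-hypo", ["Low", "High"]),
        nominal("INSS", ["1", "2", "3", "4", "4s"]),
        nominal("MYCN", ["normal", "amplified"]),
        nominal("Age", ["<1y", ">=1y"]),
    ]
    marginals = {
        "NB-hypo": {"Low": 0.747, "High": 0.253},
        "INSS": {"1": 0.23, "2": 0.13, "3": 0.13, "4": 0.38, "4s": 0.13},
        "MYCN": {"normal": 0.84, "amplified": 0.16},
        "Age": {"<1y": 0.47, ">=1y": 0.53},
    }
    rules = [
        parse_rule("if INSS in {4} and Age in {>=1y} then outcome = Poor",
                   schema, "g1"),
        parse_rule("if NB-hypo in {High} and INSS in {2, 3, 4} "
                   "and Age in {>=1y} then outcome = Poor", schema, "g2"),
    ]
    half = ambiguous_size // 2
    groups = [AmbiguousGroup(
        profile={"NB-hypo": "Low", "INSS": "4", "MYCN": "normal",
                 "Age": ">=1y"},
        size=ambiguous_size,
        split={"Good": ambiguous_size - half, "Poor": half},
    )] if ambiguous_size > 0 else []
    return CohortSpec(n=n, schema=schema, marginals=marginals,
                      planted_rules=rules, background_class="Good",
                      ambiguous_groups=groups)


def recovery_cohort_spec(
    n: int = 200,
    ambiguous_size: int = 12,
    with_singleton: bool = True,
) -> CohortSpec:
    """A cohort whose two outcome classes are separated by one attribute
    (case <=> A = a1), with an ambiguous profile group in the case region
    and one label-contradicting singleton in the control region.  Both
    clean classes have a unique greedy rule, so after removal of the
    injected noise every induced rule is recovered from any training
    subset."""
    schema = [
        nominal("A", ["a1", "a2"]),
        nominal("B", ["b1", "b2", "b3", "b4"]),
        nominal("C", ["c1", "c2"]),
    ]
    marginals = {
        "A": {"a1": 0.5, "a2": 0.5},
        "B": {"b1": 0.25, "b2": 0.25, "b3": 0.25, "b4": 0.25},
        "C": {"c1": 0.5, "c2": 0.5},
    }
    rules = [Rule("g1", (member("A", ["a1"]),), "case")]
    half = ambiguous_size // 2
    groups = [AmbiguousGroup(
        profile={"A": "a1", "B": "b4", "C": "c1"},
        size=ambiguous_size,
        split={"case": ambiguous_size - half, "control": half},
    )] if ambiguous_size > 0 else []
    singles = [SingletonInjection({"A": "a2", "B": "b1", "C": "c2"}, "case")] \
        if with_singleton else []
    return CohortSpec(n=n, schema=schema, marginals=marginals,
                      planted_rules=rules, background_class="control",
                      ambiguous_groups=groups, singletons=singles)


# ---------------------------------------------------------------------------
# Expression matrices and dichotomization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSpec:
    """Two-group Gaussian mixture over a probe-set signature."""

    samples: int = 182
    probes: int = 62
    group_fraction: float = 0.25
    shift: float = 2.0
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.probes < 2:
            raise ValueError("need at least two probe sets")
        if not 0.0 < self.group_fraction < 1.0:
            raise ValueError("group_fraction must lie in (0, 1)")


def generate_expression(
    spec: ExpressionSpec, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Samples x probes matrix plus the true group label per sample."""
    rng = np.random.default_rng(seed)
    n_high = max(1, int(round(spec.samples * spec.group_fraction)))
    labels = np.zeros(spec.samples, dtype=int)
    labels[rng.choice(spec.samples, size=n_high, replace=False)] = 1
    matrix = rng.normal(0.0, spec.noise_scale, (spec.samples, spec.probes))
    matrix[labels == 1] += spec.shift
    frame = pd.DataFrame(
        matrix,
        index=[f"s{i + 1:04d}" for i in range(spec.samples)],
        columns=[f"probe{j + 1:03d}" for j in range(spec.probes)],
    )
    return frame, labels


def manhattan_kmeans(
    X: np.ndarray, k: int, iterations: int = 500
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd-style k-means under the Manhattan (L1) metric.

    Initial centroids are the first ``k`` rows in input order (the
    order-preserving deterministic initialisation); centroid updates use
    the component-wise median, the L1 minimiser.  Returns labels,
    centroids and the sum of within-cluster distances.
    """
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} samples")
    centroids = X[:k].copy()
    labels = np.zeros(len(X), dtype=int)
    for _ in range(iterations):
        dist = np.abs(X[:, None, :] - centroids[None, :, :]).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        for c in range(k):
            members = X[new_labels == c]
            if len(members):
                centroids[c] = np.median(members, axis=0)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
    dist = np.abs(X[:, None, :] - centroids[None, :, :]).sum(axis=2)
    labels = dist.argmin(axis=1)
    wcd = float(dist[np.arange(len(X)), labels].sum())
    return labels, centroids, wcd


def kmeans_dichotomize(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 2,
    iterations: int = 500,
    max_k: int = 6,
) -> tuple[np.ndarray, dict[int, float]]:
    """Cluster samples by their signature and report the within-cluster
    distance curve for every candidate cluster count 1..max_k (the elbow
    of the curve indicates the preferable partition; with a bimodal
    signature the curve flattens after k = 2)."""
    X = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix
    labels, _, _ = manhattan_kmeans(X, k, iterations)
    curve = {
        kk: manhattan_kmeans(X, kk, iterations)[2]
        for kk in range(1, min(max_k, len(X)) + 1)
    }
    return labels, curve
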