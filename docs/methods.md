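# Methods

## Setting and data model

A cohort is a table of n instances (patients) over d declared attributes
and a categorical outcome with q classes. Ordered attributes live in a
finite interval [a, b]; nominal attributes in a finite unordered value
set. Rules are conjunctions of at most one condition per attribute:
half-open intervals `λ < x ≤ μ` (one side may be unbounded, printed as
`x > λ` or `x ≤ μ`) and member sets `x ∈ {…}`. Intervals are half-open
on the left by convention, which makes symbolic intersection of premises
closed under the grammar. The label `NC` is reserved for "not
classified" and can never be an outcome class.

Per-rule statistics are covering C = TP/(TP+FN), error E = FP/(TN+FP)
and precision P = TP/(TP+FP). A zero denominator returns the value 0
together with a cleared `*_defined` flag rather than raising: downstream
products (relevance) stay total while degeneracy remains diagnosable.

Prediction follows the highest-covering policy. Exact covering ties are
broken by higher precision and then by rule order; the policy itself
fixes only "highest covering", so the tie-break is our choice, made for
determinism and documented here.

## Rule induction

The inducer reconstructs an aggregative bottom-up learner in the family
of Boolean-function-synthesis methods (the original implementation is
proprietary; its published configuration — bottom-up aggregation,
condition minimisation, 0% maximum training error, full covering — is
honoured, its internals are not claimed). For each class, in sorted
label order:

1. seed: the first uncovered class instance in dataset order (a
   determinism choice);
2. initialise the maximally specific premise — every nominal attribute
   pinned to the seed's value, every ordered attribute to the seed's
   discretization bin;
3. greedily apply the single generalization step (drop one condition,
   add one nominal value, extend one interval end to the adjacent
   cutpoint) with the largest TP gain among steps keeping E(r) within
   the error budget; ties prefer dropping a whole condition, then follow
   schema attribute order and domain value order;
4. when no admissible step gains TP, drop every condition whose removal
   is free at the error budget (condition minimisation), emit the rule,
   and repeat until the class is covered.

Each step only weakens the premise, so TP is non-decreasing and, at a 0%
budget, no false positive is ever admitted. A profile carried by
instances of both classes makes 0% error unreachable; the inducer then
emits the maximally specific rule anyway (so covering stays total),
records the profile in `Classifier.contradictions`, and leaves the
resolution to the stabilization loop's third cause.

Ordered attributes are discretized first (class-driven): candidate
cutpoints sit at midpoints between consecutive distinct values with
different class composition; adjacent intervals are merged, weakest
boundary first, until every retained boundary separates intervals whose
class-proportion gap is at least `min_class_distance` (default 0.20).
The method name this emulates is published without internals; reading
the "minimum distance between classes" as a class-proportion gap across
the boundary is our interpretation, and the per-boundary gap is
re-checkable from the returned cutpoints. Induced interval endpoints are
restricted to these cutpoints.

## Stability

`run_cv` performs n independent stratified m-fold cross-validations
(defaults 5 × 10), inducing one classifier per training fold; all fold
assignments derive from a single seed. The notation for the number of
classifiers is normalised to N = n·m = 50, matching the count of
classifiers actually produced.

Rule occurrence matching uses a *semantic* distance: for two rules with
the same consequence, d = 1 − Jaccard(covered sets on the full reference
cohort); rules with different consequences are incomparable, and two
rules with empty coverage are at distance 0 only when symbolically
identical. The distance metric and tolerance are deliberately
configurable because neither is canonical; the default ε = 0.05 treats
rules as the same occurrence when their covered sets differ by less than
5% of their union, and the coverage formulation is scale-free and
agnostic to syntactic variation. Stability(r) = b/N with b the number of
CV classifiers containing at least one occurrence of r.

Core rules condense the N classifiers: same-consequence occurrences are
clustered by single linkage at threshold ε (the cheapest reading of
"identify similar rules"), each cluster's premises are intersected
attribute-wise (member-set intersection, interval intersection; an
attribute unconstrained in a component imposes nothing), unsatisfiable
intersections are dropped, and the aggregated stability is the fraction
of classifiers contributing at least one component. By construction a
Core rule's covered set is contained in every component's covered set.

## Stabilization loop

Each iteration: induce on the full current cohort → run repeated CV →
compute each reference rule's stability → stop when min stability
≥ 1 − ν *and* the inducer reports no contradictory profile → otherwise
build Core rules, diagnose, remove the flagged instances, iterate.
ν defaults to 0 (the loop runs until every rule is at stability one).
The extra contradiction-free requirement in the exit test is needed
because a duplicated both-label profile yields maximally specific rules
that are themselves perfectly stable across folds while conflicting on
the very pattern they cover; without the extra test the loop could
return a "stable" classifier whose conflict overlap still contains
instances.

The three diagnosed causes (evaluated on the Core rules, whose
aggregated stabilities summarise the CV ensemble, except cause 3 which
reads the cohort directly):

1. **low-covering unstable rule** — an unstable Core rule with covering
   ≤ s_cov (default 0.1) flags the instances it covers that no stable
   rule covers; restricting to exclusively covered instances keeps
   stable rules from losing support.
2. **near-duplicate rules** — same-consequence rules r_k, r_h with
   1 ≤ |H(r_k) \ H(r_h)| ≤ s_diff (default 1, inclusive — a strict
   reading of "< s with s = 1" would make the set empty) flag the
   difference instances.
3. **ambiguous profile** — every group of instances sharing one full
   attribute profile but holding more than one outcome label is flagged
   whole.

Flags are deduplicated with all causes retained. Removal always happens
between iterations on the full cohort, never inside CV folds. The loop
raises (carrying the full per-iteration log) after `max_iterations`
(default 10; a safety cap, the reference analysis converged in three) or
when instability persists while the diagnosis flags nothing — the three
causes are explicitly not claimed to be exhaustive, and on cohorts whose
minority-class complement admits several equally valid rule covers the
residual instability is genuine rule multiplicity, not an instance
problem (see Limitations).

`purge_matched` removes from an independent test cohort every instance
whose full profile equals a removed training instance's profile, so that
held-out evaluation sees the same exclusions as training.

## Significance and performance

Each rule is scored by Fisher's exact test on the 2×2 table (premise
satisfied × outcome class), oriented with the rule's own consequence as
the target class and one-sided toward enrichment by default (matching
the per-class switching of the target; a two-sided variant is a flag).
Degenerate margins give p = 1. Performance metrics take one class as
positive: accuracy, recall, precision, specificity, NPV. NC predictions
are counted separately and scored as misclassifications by default
(conservative headline numbers); they never enter predicted-positive or
predicted-negative denominators, and can be excluded entirely.

## Synthetic cohorts

The generator draws attribute vectors i.i.d. from declared nominal
marginals, labels them by the first matching planted rule (else the
background class), optionally flips labels at a noise rate, and then
injects (a) ambiguous groups — exact copies of one profile with an exact
outcome split — and (b) singletons — lone instances whose label
contradicts their planted neighbourhood. Background sampling rejects the
injected profiles, so the provenance annotation (clean / ambiguous /
singleton) partitions the cohort exactly and recovery tests can compare
flagged sets against ground truth. Everything is a pure function of
(spec, seed).

Two ready-made specifications:

* `nb_cohort_spec` mirrors the neuroblastoma setting: four categorical
  risk factors with study-like marginals (47% of patients younger than
  one year, 38% stage 4, 16% amplified, 25% high-hypoxia), outcomes
  planted by the two published poor-outcome rules, and a 24-patient
  ambiguous group on the profile (low hypoxia, stage 4, normal MYCN,
  age ≥ 1). The induced poor-outcome fraction (~20%) is a consequence of
  the planted rules and marginals, not an independent dial.
* `recovery_cohort_spec` is the calibration scenario used by the
  acceptance checks: 200 instances over three attributes, one class
  defined by a single attribute value, a 12-instance ambiguous group and
  one singleton. Because both clean classes have a unique greedy rule,
  post-purge stability is exactly 1 for every rule under any fold
  assignment, which makes the expected behaviour of the full loop known
  in advance.

What the generator does **not** emulate: correlated risk factors,
missing values, cohort-specific batch structure, survival times, and
raw microarray processing. Passing tests therefore demonstrate the
mechanics of induction, stability measurement and instance diagnosis
under the stated assumptions — not clinical performance on real
patients.

The expression generator produces a samples × probes two-group Gaussian
mixture (default 62 probes, matching the signature length of the
motivating study). `kmeans_dichotomize` reduces it to a binary attribute
with Manhattan-distance k-means: initial centroids are the first k rows
in input order (the deterministic, order-preserving initialisation),
centroid updates use the component-wise median (the L1 minimiser), and
the sum-of-within-cluster-distance curve over k = 1..K is reported for
elbow inspection — the elbow is reported, not automatically selected.

## Numerical and degenerate-input choices

* Premise normalization merges duplicate-attribute conditions by
  intersection and sorts conditions by attribute name; an empty member
  set or empty interval is representable (an unsatisfiable premise
  covers nothing).
* Interval satisfiability during conflict analysis is decided against
  the schema bounds, so `x > 120` on a domain ending at 100 conflicts
  with nothing.
* The error budget comparison uses FP ≤ budget · (class complement
  size) + 1e-9 to avoid float-equality artefacts at 0%.
* Empty cohorts are valid containers (a matched purge may empty a test
  set) but cannot be induced on.
* Fisher tests delegate to `scipy.stats.fisher_exact`; the test suite
  cross-checks against exhaustive enumeration of all tables with the
  observed margins.
* Cross-validation folds come from scikit-learn's stratified splitter;
  repetition seeds are spawned from the user seed via
  `numpy.random.SeedSequence`.

## Problem sizes

Default analyses run on cohorts of ~200 instances and a handful of
attributes: one stabilization iteration then induces 51 classifiers
(full cohort + 50 folds) and completes in about a second; the 20-seed
recovery study takes under half a minute. These sizes are the package's
reference configuration; nothing prevents larger cohorts, with cost
roughly linear in n per candidate step and quadratic in the rule pool
for Core-rule clustering.

## Known limitations

* The inducer is a faithful reconstruction of the published *behaviour*
  of the original learner, not of its proprietary internals; induced
  rule sets can differ from the original tool's on the same data.
* When a class region is not uniquely coverable by conjunctions (e.g.
  the complement of a union of boxes), different training folds can
  legitimately prefer different exact covers. The resulting instability
  is not caused by any instance, the diagnosis correctly flags nothing,
  and the loop raises rather than purging arbitrarily — on such cohorts
  full stability may be unattainable at ε = 0.05. The study-shaped
  cohort exhibits this for some seeds.
* The occurrence distance is semantic (coverage-based); a syntactic
  edit-distance alternative is an extension point, not shipped.
* Per-class relevance values depend on the cohort the statistics are
  computed on; published per-attribute relevances from the original
  patient data are not reproducible without that data and are not
  targeted.
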