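# stablerules

Explicit-rule stratification of patients from categorical risk factors,
with a measure of how *stable* each rule is under repeated
cross-validation and an iterative procedure that removes the patients
responsible for instability until every rule is recovered from every
training subset.

The package is aimed at biostatisticians building interpretable
prognostic classifiers — the motivating setting is neuroblastoma outcome
prediction from age at diagnosis, INSS tumour stage, MYCN amplification
and a dichotomized hypoxia gene-expression signature — but nothing in it
is specific to that disease: any cohort of nominal/ordered attributes
with a categorical outcome works.

## The model

A classifier g(**x**) is an ordered set of conjunctive rules
`if <premise> then <class>`, where each premise holds at most one
condition per attribute: interval conditions `λ < x_j ≤ μ` on ordered
attributes, membership conditions `x_j ∈ {α, δ, …}` on nominal ones.
Against a labelled training set, a rule r for class *l* has confusion
counts TP/FP/FN/TN and the three statistics

    C(r) = TP / (TP + FN)        covering
    E(r) = FP / (TN + FP)        error
    P(r) = TP / (TP + FP)        precision

A pattern satisfied by several rules receives the consequence of the
satisfied rule with the highest covering; patterns satisfied by no rule
are *NC* (not classified). Rules are induced bottom-up: a maximally
specific premise seeded on an uncovered instance is weakened one step at
a time (drop a condition, admit a nominal value, extend an interval to
the adjacent discretization cutpoint), taking the step with the largest
TP gain that keeps E(r) within the error budget (0% by default, which
also forces every training instance into at least one rule).

The relevance of a condition c in r is the error increase
R(c) = E(r′) − E(r) of the weakened rule r′ without it, and the relevance
of attribute x_j aggregates over the rules r_k carrying a condition c_kl
on it:

    R_j = 1 − Π_k (1 − P(r_k) · R(c_kl))      ∈ [0, 1]

**Stability.** n independent m-fold cross-validations give N = n·m
classifiers (5 × 10 = 50 by default). Two same-consequence rules are
occurrences of the same rule when their covered sets on the full cohort
are close (coverage Jaccard distance < ε, default 0.05). The stability
of a rule is b/N, the fraction of CV classifiers containing an
occurrence. *Core rules* intersect, attribute by attribute, the premises
of each cluster of similar rules across the N classifiers.

**Stabilization.** While any rule has stability < 1 − ν (ν = 0 by
default) — or the inducer reports a contradictory profile — the loop
diagnoses three causes of instability and removes the flagged patients:
(1) instances exclusively covered by an unstable rule of covering
≤ s_cov; (2) the instances by which one rule's covered set exceeds a
near-duplicate rule's; (3) groups of instances sharing one full profile
but holding both outcome labels. Each rule's Fisher exact test and the
usual accuracy / recall / precision / specificity / NPV metrics assess
the result; a matched purge applies the removed profiles to an
independent test cohort before evaluation.

## Worked example

Cohorts with the study-like structure are generated by the package
itself (the real patient tables are not public); the generator plants
the outcome rules, a 24-patient ambiguous profile group, and study-like
marginal frequencies:

```python
import stablerules as sr

cohort = sr.generate_cohort(sr.nb_cohort_spec(n=182), seed=0)
result = sr.stabilize(cohort, sr.StabilizationConfig(cv=sr.CVConfig(seed=0)))
print("iterations:", len(result.log), " removed:", len(result.removed_ids))
for rule in result.classifier.rules:
    s = result.log[-1].stabilities[rule.id]
    print(f"  stability {s:.2f}  covering {rule.stats.covering:.2f}  "
          f"error {rule.stats.error:.2f}  {sr.format_rule(rule)}")
```

prints

```
iterations: 2  removed: 24
  stability 1.00  covering 0.58  error 0.00  if MYCN in {normal} and NB-hypo in {Low} then outcome = Good
  stability 1.00  covering 0.63  error 0.00  if Age in {<1y} then outcome = Good
  stability 1.00  covering 0.47  error 0.00  if INSS in {1, 4s} then outcome = Good
  stability 1.00  covering 0.58  error 0.00  if INSS in {1, 2, 3, 4s} and NB-hypo in {Low} then outcome = Good
  stability 1.00  covering 0.79  error 0.00  if Age in {>=1y} and INSS in {2, 3, 4} and NB-hypo in {High} then outcome = Poor
  stability 1.00  covering 0.62  error 0.00  if Age in {>=1y} and INSS in {4} then outcome = Poor
```

The loop removed the 24 ambiguous patients (low hypoxia, stage 4, normal
MYCN, age ≥ 1 year — a profile split evenly between good and poor
outcome, on which no algorithm can make a meaningful prediction) and
every remaining rule is recovered in all 50 CV classifiers. The two
poor-outcome rules are the planted ground truth; the good-outcome class,
being the complement region, is covered by several overlapping exact
rules. A matched purge then prepares an independent test cohort:

```python
test = sr.generate_cohort(sr.nb_cohort_spec(n=51, ambiguous_size=8), seed=99)
purged, dropped = sr.purge_matched(test, [], train=cohort,
                                   removed_ids=result.removed_ids)
report = sr.performance_metrics(result.classifier, purged, positive_class="Good")
```

which drops the 8 test patients (15%) matching a removed profile and
scores the classifier on the remaining 43 — all five metrics are 1.0
here because the synthetic labels are a noise-free function of the
attributes once the ambiguous profiles are gone.

The same machinery is available as scikit-learn estimators
(`RuleInductionClassifier`, `StabilizedRuleClassifier` with
`fit`/`predict`/`get_params`) and from the shell:

```
stablerules simulate cohort --kind nb --n 182 --seed 0 --out cohort.csv --schema-out schema.yaml
stablerules stabilize --data cohort.csv --schema schema.yaml --seed 0 --out final_rules.json
stablerules evaluate --rules final_rules.json --data cohort.csv --schema schema.yaml --positive Good
```

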