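"""Per-rule significance and classifier performance metrics.

Each rule's association between premise satisfaction and its consequence
class is scored with Fisher's exact test on the 2x2 table

=============== ============== ==================
 .               target class   other class
=============== ============== ==================
satisfies        TP             FP
does not         FN             TN
=============== ============== ==================

oriented so the rule's own consequence plays the target role (the test
asks for enrichment of that class among premise satisfiers; one-sided by
default, a two-sided variant is available).

Classifier performance treats one class (typically the good-outcome one)
as positive.  Patterns predicted ``NC`` are counted separately and, by
default, scored as misclassifications; they can instead be excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .rules import Classifier, Rule, confusion_counts
from .schema import NC, CohortDataset


def fisher_rule_test(
    rule: Rule, dataset: CohortDataset, alternative: str = "greater"
) -> float:
    """Exact hypergeometric p-value of the rule's 2x2 premise-by-outcome
    table (enrichment of the consequence class among satisfiers).

    Degenerate margins (empty coverage, single-class cohort) give p = 1.
    """
    counts = confusion_counts(rule, dataset)
    table = [[counts["TP"], counts["FP"]], [counts["FN"], counts["TN"]]]
    return float(sps.fisher_exact(table, alternative=alternative)[1])


@dataclass(frozen=True)
class PerformanceReport:
    """Headline metrics with the confusion matrix they derive from."""

    accuracy: float
    recall: float
    precision: float
    specificity: float
    npv: float
    positive_class: str
    tp: int
    fp: int
    tn: int
    fn: int
    n_not_classified: int
    n: int
    exclude_nc: bool = False

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "recall": self.recall,
            "precision": self.precision, "specificity": self.specificity,
            "npv": self.npv, "not_classified": self.n_not_classified,
            "n": self.n,
        }


def performance_metrics(
    classifier: Classifier,
    dataset: CohortDataset,
    positive_class: str,
    exclude_nc: bool = False,
) -> PerformanceReport:
    """Accuracy, recall, precision, specificity and NPV of the classifier's
    predictions on a labelled cohort.

    ``NC`` predictions never enter the predicted-positive or
    predicted-negative denominators; with ``exclude_nc`` the affected
    instances are removed from every denominator, otherwise they count as
    misclassified.
    """
    pred = classifier.predict(dataset).to_numpy(dtype=object)
    truth = dataset.outcome.astype(str).to_numpy()
    nc_mask = pred == NC
    n_nc = int(np.sum(nc_mask))
    if exclude_nc:
        pred, truth = pred[~nc_mask], truth[~nc_mask]
        nc_mask = np.zeros(len(pred), dtype=bool)

    pos_true = truth == positive_class
    pos_pred = pred == positive_class
    neg_pred = (~pos_pred) & (pred != NC)
    tp = int(np.sum(pos_true & pos_pred))
    fp = int(np.sum(~pos_true & pos_pred))
    tn = int(np.sum(~pos_true & neg_pred))
    fn = int(np.sum(pos_true & neg_pred))
    n = len(truth)

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    correct = int(np.sum((pred == truth) & ~nc_mask))
    return PerformanceReport(
        accuracy=ratio(correct, n),
        recall=ratio(tp, int(np.sum(pos_true))),
        precision=ratio(tp, tp + fp),
        specificity=ratio(tn, int(np.sum(~pos_true))),
        npv=ratio(tn, tn + fn),
        positive_class=positive_class,
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_not_classified=n_nc, n=n, exclude_nc=exclude_nc,
    )
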