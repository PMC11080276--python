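"""Hold-out validation: confusion matrix, classification metrics, ROC/AUC.

Metrics follow the standard case-positive conventions: accuracy
(TP+TN)/total, precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity
TN/(TN+FP); a zero denominator yields ``None`` (not 0).  The AUC confidence
interval uses the Hanley-McNeil standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .bayesnet import BayesNet
from .inference import ImpossibleEvidenceError, predictive_probability


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float


def confusion(predicted, truth, *, positive=1) -> ConfusionMatrix:
    """Tally a confusion matrix; the case group is the positive class."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    p = predicted == positive
    t = truth == positive
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricSet:
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
    )


def hanley_mcneil_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil standard-error confidence interval for an AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_auc(
    scores,
    truth,
    *,
    positive=1,
    ci: str = "hanley-mcneil",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC curve and AUC with a 95% CI.

    The AUC uses the rank (Mann-Whitney) formulation, which equals the
    trapezoid area under the threshold-swept curve and handles ties.
    ``ci`` may be ``"hanley-mcneil"`` (default) or ``"bootstrap"``.
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(truth) == positive).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    if ci == "hanley-mcneil":
        lo, hi = hanley_mcneil_ci(auc, n_pos, n_neg)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(y)
        reps = []
        while len(reps) < n_boot:
            idx = rng.integers(0, n, size=n)
            if y[idx].min() == y[idx].max():
                continue
            reps.append(roc_auc_score(y[idx], scores[idx]))
        lo, hi = np.quantile(reps, [0.025, 0.975])
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, ci_low=float(lo),
                     ci_high=float(hi))


def score_records(
    net: BayesNet,
    test: pd.DataFrame,
    disease: str,
    *,
    yes_state=1,
) -> tuple[np.ndarray, int]:
    """Disease posterior for every test record, marginalizing absent fields.

    Pure-MLE tables can assign zero mass to a record's configuration; such
    impossible-evidence records fall back to the disease prior.  Returns
    (scores, number of fallback records).
    """
    prior = None
    scores = np.empty(len(test))
    fallbacks = 0
    cols = [c for c in test.columns if c in net.dag.nodes and c != disease]
    for i, (_, row) in enumerate(test.iterrows()):
        evidence = {c: row[c] for c in cols if pd.notna(row[c])}
        try:
            scores[i] = predictive_probability(
                net, disease, evidence, yes_state=yes_state
            )
        except ImpossibleEvidenceError:
            if prior is None:
                prior = predictive_probability(net, disease, {},
                                               yes_state=yes_state)
            scores[i] = prior
            fallbacks += 1
    return scores, fallbacks


def evaluate_holdout(
    net: BayesNet,
    test: pd.DataFrame,
    disease: str,
    *,
    threshold: float = 0.5,
    yes_state=1,
) -> dict:
    """Confusion matrix, metrics and ROC of the net on a hold-out table."""
    truth = (test[disease] == yes_state).astype(int).to_numpy()
    scores, fallbacks = score_records(net, test, disease, yes_state=yes_state)
    predicted = (scores > threshold).astype(int)
    cm = confusion(predicted, truth)
    roc = roc_auc(scores, truth)
    return {
        "confusion": cm,
        "metrics": metrics(cm),
        "roc": roc,
        "scores": scores,
        "impossible_evidence_fallbacks": fallbacks,
    }
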