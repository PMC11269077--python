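"""ROC/AUC evaluation with bootstrap confidence intervals and
Youden-index operating thresholds.

AUC is the probability that a random positive case outscores a random
negative one (rank / Mann-Whitney formulation, ties counted 1/2), so it
applies unchanged to continuous model scores and to ordinal risk
categories used as scores.  The operating threshold maximises the
Youden index J = sensitivity + specificity - 1 over the distinct
observed scores (rule: score >= threshold is called positive), and 95%
confidence intervals come from percentile bootstrap over patients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["ModelEvaluation", "auc", "youden_threshold", "bootstrap_auc_ci",
           "evaluate_scores", "evaluate_ordinal_score"]


@dataclass
class ModelEvaluation:
    """AUC with bootstrap CI plus the Youden operating point."""
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    n_boot: int

    def to_dict(self):
        return {k: (float(v) if v is not None else None)
                for k, v in self.__dict__.items()} | {"n_boot": int(self.n_boot)}

    def to_json(self, path=None):
        if path is None:
            return json.dumps(self.to_dict(), indent=2)
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)


def _check_two_classes(labels):
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    return labels


def auc(scores, labels):
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_threshold(scores, labels):
    """Operating threshold maximising sensitivity + specificity - 1.

    Candidates are the distinct observed scores plus +inf; among ties the
    lowest threshold wins.  Returns ``(threshold, sensitivity,
    specificity)`` under the rule score >= threshold -> positive.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    # thresholds are decreasing; the last argmax is the lowest threshold
    best = len(j) - 1 - int(np.argmax(j[::-1]))
    return float(thresholds[best]), float(tpr[best]), float(1 - fpr[best])


def bootstrap_auc_ci(scores, labels, n_boot=1000, seed=None, stratified=False):
    """Percentile 95% bootstrap CI of the AUC, resampling patients.

    Rows (score, label pairs) are resampled jointly; resamples holding a
    single class are skipped and counted, and more than 50% skips raises.
    With ``stratified=True`` positives and negatives are resampled
    separately (no skips possible).
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(labels)
    pos = np.flatnonzero(labels == np.max(labels))
    neg = np.flatnonzero(labels != np.max(labels))
    stats_ = []
    skipped = 0
    for _ in range(n_boot):
        if stratified:
            idx = np.concatenate([rng.choice(pos, len(pos)),
                                  rng.choice(neg, len(neg))])
        else:
            idx = rng.integers(n, size=n)
        lb = labels[idx]
        if len(np.unique(lb)) < 2:
            skipped += 1
            continue
        stats_.append(roc_auc_score(lb, scores[idx]))
    if skipped > n_boot / 2:
        raise RuntimeError(f"{skipped}/{n_boot} bootstrap resamples were "
                           "single-class; sample too small or too imbalanced")
    if skipped:
        logger.info("skipped %d/%d single-class bootstrap resamples",
                    skipped, n_boot)
    lo, hi = np.percentile(stats_, [2.5, 97.5])
    return float(lo), float(hi)


def evaluate_scores(scores, labels, n_boot=1000, seed=None,
                    stratified=False) -> ModelEvaluation:
    """Full evaluation of a scorer: AUC, bootstrap CI, Youden operating point."""
    a = auc(scores, labels)
    lo, hi = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed,
                              stratified=stratified)
    thr, sens, spec = youden_threshold(scores, labels)
    return ModelEvaluation(auc=a, ci_low=lo, ci_high=hi, threshold=thr,
                           sensitivity=sens, specificity=spec, n_boot=n_boot)


def evaluate_ordinal_score(categories, labels, n_boot=1000,
                           seed=None) -> ModelEvaluation:
    """Evaluate an ordinal risk category (e.g. RACHS-1, STS-EACTS, or the
    fitted stratification) used directly as a score; within-category ties
    count 1/2 in the AUC."""
    return evaluate_scores(np.asarray(categories, dtype=float), labels,
                           n_boot=n_boot, seed=seed)
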