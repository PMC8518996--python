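"""Diagnostic-test evaluation of a scalar wheeze index.

Evaluates any per-subject score (primarily the band count per 30 s) as a
predictor of bronchodilator non-response: 2x2 confusion metrics with
likelihood ratios, the full ROC curve, trapezoidal AUC (identical to the
tie-corrected Mann-Whitney probability), the Hanley-McNeil standard
error of the AUC, cutoff selection, and an ROC-based sample-size solve.

Orientation: the *positive class* is the condition the test should flag
(by default "non-disappear": wheezing persisting after beta2-agonist
inhalation) and, by default, higher scores predict it; subjects at or
above the cutoff are called positive. Both choices are explicit fields
of :class:`LabeledScores` because published 2x2 figures do not always
pin them down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm


@dataclass
class LabeledScores:
    """Per-subject scores with binary group labels."""

    scores: np.ndarray
    labels: np.ndarray
    positive_class: str = "non-disappear"
    higher_is_positive: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if self.scores.size == 0:
            raise ValueError("empty data")

    @property
    def y(self) -> np.ndarray:
        """Boolean positive-class indicator."""
        return self.labels == self.positive_class

    @property
    def oriented_scores(self) -> np.ndarray:
        """Scores transformed so that larger always means more positive."""
        return self.scores if self.higher_is_positive else -self.scores

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.y).sum())


@dataclass
class DiagnosticSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    cutoff: float | None = None
    auc: float | None = None
    auc_se: float | None = None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "lr_pos": self.lr_pos, "lr_neg": self.lr_neg,
            "cutoff": self.cutoff, "auc": self.auc, "auc_se": self.auc_se,
        }


@dataclass
class RocCurve:
    """Operating points of the threshold sweep, anchored at (0,0) and
    (1,1). ``thresholds`` are on the original score scale (midpoints
    between consecutive distinct scores, plus +/-inf anchors)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    data: LabeledScores


def confusion_at(data: LabeledScores, cutoff: float) -> tuple[int, int, int, int]:
    """2x2 counts (tp, fp, tn, fn) calling positive at score >= cutoff
    (direction-adjusted)."""
    if not math.isfinite(cutoff) and not math.isinf(cutoff):
        raise ValueError("cutoff must not be NaN")
    s = data.oriented_scores
    c = cutoff if data.higher_is_positive else -cutoff
    pred = s >= c
    y = data.y
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    return tp, fp, tn, fn


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> DiagnosticSummary:
    """Standard 2x2 metrics. Likelihood ratios are NaN at their
    division-by-zero boundaries (LR+ undefined at specificity 1, LR-
    undefined at specificity 0); predictive values use the table's own
    prevalence."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be represented")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp > 0 else math.nan
    npv = tn / (tn + fn) if tn + fn > 0 else math.nan
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else math.nan
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else math.nan
    return DiagnosticSummary(tp, fp, tn, fn, sens, spec, ppv, npv, lr_pos, lr_neg)


def roc_curve(data: LabeledScores) -> RocCurve:
    """ROC curve over all distinct cutoffs.

    Thresholds descend from +inf through the midpoints between
    consecutive distinct sorted scores down to -inf, so every achievable
    confusion table appears exactly once and the curve runs from (0,0)
    to (1,1)."""
    if data.n_pos == 0 or data.n_neg == 0:
        raise ValueError("ROC requires both classes present")
    s = data.oriented_scores
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    oriented_thr = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    fpr = np.empty(oriented_thr.size)
    tpr = np.empty(oriented_thr.size)
    y = data.y
    for i, c in enumerate(oriented_thr):
        pred = s >= c
        tpr[i] = np.sum(pred & y) / data.n_pos
        fpr[i] = np.sum(pred & ~y) / data.n_neg
    thresholds = oriented_thr if data.higher_is_positive else -oriented_thr
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, data=data)


def auc(data: LabeledScores) -> float:
    """Trapezoidal area under the ROC curve; equals the tie-corrected
    probability that a random positive outscores a random negative."""
    roc = roc_curve(data)
    return float(np.trapezoid(roc.tpr, roc.fpr))


def auc_se(auc_value: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate, using the
    exponential approximations Q1 = A/(2-A), Q2 = 2A^2/(1+A)."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one subject per class")
    if not 0.0 < auc_value < 1.0:
        raise ValueError("auc must lie strictly in (0, 1)")
    a = auc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(var)


def choose_cutoff(
    roc: RocCurve,
    criterion: str = "youden",
    min_sensitivity: float | None = None,
) -> tuple[float, DiagnosticSummary]:
    """Select an operating point on the ROC curve.

    criterion:
      * ``youden`` — maximize sensitivity + specificity - 1 (ties go to
        the lower cutoff, i.e. the more sensitive operating point);
      * ``min_sensitivity`` — the largest cutoff whose sensitivity is at
        least ``min_sensitivity`` (a sensitivity-weighted rule for a
        rule-out test);
      * ``closest_topleft`` — minimize distance to the ideal (fpr 0,
        tpr 1) corner.
    """
    thr, fpr, tpr = roc.thresholds, roc.fpr, roc.tpr
    finite = np.isfinite(thr)
    if criterion == "youden":
        j = tpr - fpr
        # thresholds descend, so the last tied maximum is the lower cutoff
        best = np.flatnonzero(j >= j.max() - 1e-12)
        idx = int(best[-1])
    elif criterion == "min_sensitivity":
        if min_sensitivity is None:
            raise ValueError("min_sensitivity target required")
        ok = np.flatnonzero(finite & (tpr >= min_sensitivity))
        if ok.size == 0:
            raise ValueError(f"sensitivity {min_sensitivity} unattainable")
        idx = ok[0]  # thresholds descend: first qualifying = largest cutoff
    elif criterion == "closest_topleft":
        d = np.hypot(fpr, 1.0 - tpr)
        idx = int(np.argmin(d))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    cutoff = float(thr[idx])
    if not np.isfinite(cutoff):
        # an anchor was selected; replace with a score-scale cutoff that
        # realizes the same confusion table
        s = roc.data.scores
        oriented_neg_inf = (thr[idx] < 0) == roc.data.higher_is_positive
        if oriented_neg_inf:  # everyone called positive
            cutoff = float(s.min() if roc.data.higher_is_positive else s.max())
        else:  # no one called positive
            cutoff = float(s.max() + 1.0 if roc.data.higher_is_positive else s.min() - 1.0)
    summary = metrics_from_counts(*confusion_at(roc.data, cutoff))
    summary = replace(
        summary,
        cutoff=cutoff,
        auc=float(np.trapezoid(roc.tpr, roc.fpr)),
    )
    summary.auc_se = (
        auc_se(summary.auc, roc.data.n_pos, roc.data.n_neg)
        if 0.0 < summary.auc < 1.0
        else math.nan
    )
    return cutoff, summary


def evaluate(data: LabeledScores, criterion: str = "youden",
             min_sensitivity: float | None = None) -> DiagnosticSummary:
    """Convenience: ROC + cutoff selection + AUC with SE in one call."""
    roc = roc_curve(data)
    _, summary = choose_cutoff(roc, criterion, min_sensitivity)
    return summary


def _hm_var(a: float, n: int) -> float:
    """Hanley-McNeil AUC variance with n subjects per group."""
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (a * (1.0 - a) + (n - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (n * n)


def roc_sample_size(
    auc_alt: float, power: float = 0.95, alpha: float = 0.05, sided: int = 1
) -> int:
    """Subjects per group needed to distinguish ``auc_alt`` from the
    null AUC 0.5 by a normal-approximation test with Hanley-McNeil
    variances under each hypothesis (equal group sizes).

    This is one of several published conventions for ROC sample-size
    planning; variance models differ between software packages, so
    results are indicative rather than canonical.
    """
    if not 0.5 < auc_alt < 1.0:
        raise ValueError("auc_alt must lie in (0.5, 1)")
    if not 0.0 < power < 1.0 or not 0.0 < alpha < 1.0:
        raise ValueError("power and alpha must lie in (0, 1)")
    if sided not in (1, 2):
        raise ValueError("sided must be 1 or 2")
    z_a = norm.ppf(1.0 - alpha / sided)
    z_b = norm.ppf(power)
    for n in range(2, 100000):
        lhs = z_a * math.sqrt(_hm_var(0.5, n)) + z_b * math.sqrt(_hm_var(auc_alt, n))
        if auc_alt - 0.5 >= lhs:
            return n
    raise RuntimeError("sample size search did not converge")
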