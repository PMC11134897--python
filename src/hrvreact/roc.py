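"""ROC analysis of reactivity deltas as cardiotoxicity predictors.

The curve is built from empirical thresholds only (equal scores grouped into
one step, giving diagonal tie segments), the orientation with AUC >= 0.5 is
retained and reported, the optimal cut-off minimises the Euclidean distance
from a curve point to the ideal corner (0, 1), and inference on AUC uses the
Hanley-McNeil standard error with a two-sided normal test of AUC = 0.5.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, UndefinedROCError

POSITIVE_IF_GE = "positive_if_ge"
POSITIVE_IF_LE = "positive_if_le"


@dataclass
class ROCResult:
    name: str
    maneuver: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    direction: str
    auc_positive_if_ge: float
    n_case: int
    n_control: int
    auc_ci95: Optional[Tuple[float, float]] = None
    p_value_vs_half: Optional[float] = None
    best_cutoff: Optional[float] = None
    sensitivity_pct: Optional[float] = None
    specificity_pct: Optional[float] = None

    @property
    def cutoff_label(self) -> Optional[str]:
        if self.best_cutoff is None:
            return None
        symbol = "≤" if self.direction == POSITIVE_IF_LE else "≥"
        return f"{symbol} {self.best_cutoff:g}"


def _sweep_ge(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Curve for the rule 'score >= threshold predicts case', ties grouped."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    # last position of each tie group of equal scores
    last = np.flatnonzero(np.r_[np.diff(s) != 0, True])
    tps = np.cumsum(y)[last]
    fps = np.cumsum(1.0 - y)[last]
    n1 = tps[-1]
    n0 = fps[-1]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s[last]]
    return fpr, tpr, thresholds


def roc_curve(scores, labels, name: str = "", maneuver: str = "") -> ROCResult:
    """Empirical ROC curve with trapezoidal AUC and automatic orientation.

    ``labels`` are truthy for cases (cardiotoxicity).  Both classes must be
    present and all scores finite (drop missing values before calling).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite; filter flagged-missing values first")
    n_case = int(labels.sum())
    n_control = int((~labels).sum())
    if n_case == 0 or n_control == 0:
        raise UndefinedROCError("ROC undefined: both classes must be present")
    fpr, tpr, thr = _sweep_ge(scores, labels)
    auc_ge = float(np.trapezoid(tpr, fpr))
    if auc_ge >= 0.5:
        direction, auc = POSITIVE_IF_GE, auc_ge
    else:
        direction = POSITIVE_IF_LE
        fpr, tpr, thr = _sweep_ge(-scores, labels)
        thr = -thr  # rule becomes 'score <= threshold predicts case'
        auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(name=name, maneuver=maneuver, fpr=fpr, tpr=tpr,
                     thresholds=thr, auc=auc, direction=direction,
                     auc_positive_if_ge=auc_ge, n_case=n_case, n_control=n_control)


def best_cutoff(result: ROCResult) -> Tuple[float, float, float]:
    """Threshold minimising the distance sqrt((1-tpr)^2 + fpr^2) to (0, 1).

    Earliest (most extreme) threshold wins ties.  Returns (cutoff,
    sensitivity %, specificity %) and records them on the result.
    """
    finite = np.isfinite(result.thresholds)
    if not np.any(finite):
        raise DegenerateInputError("empty ROC curve")
    fpr = result.fpr[finite]
    tpr = result.tpr[finite]
    thr = result.thresholds[finite]
    dist = np.hypot(fpr, 1.0 - tpr)
    j = int(np.argmin(dist))  # first minimum == most extreme threshold
    result.best_cutoff = float(thr[j])
    result.sensitivity_pct = float(100.0 * tpr[j])
    result.specificity_pct = float(100.0 * (1.0 - fpr[j]))
    return result.best_cutoff, result.sensitivity_pct, result.specificity_pct


def hanley_mcneil_se(auc: float, n_case: int, n_control: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1.0 - auc)
           + (n_case - 1) * (q1 - auc * auc)
           + (n_control - 1) * (q2 - auc * auc)) / (n_case * n_control)
    return math.sqrt(max(var, 0.0))


def auc_inference(result: ROCResult,
                  n_case: Optional[int] = None,
                  n_control: Optional[int] = None) -> Tuple[Tuple[float, float], float]:
    """95% CI (Hanley-McNeil) and two-sided normal p-value for AUC = 0.5."""
    n1 = result.n_case if n_case is None else n_case
    n0 = result.n_control if n_control is None else n_control
    if n1 < 2 or n0 < 2:
        raise DegenerateInputError("auc_inference requires n_case, n_control >= 2")
    auc = result.auc
    se = hanley_mcneil_se(auc, n1, n0)
    if se == 0.0:
        ci = (auc, auc)
        p = 1.0 if auc == 0.5 else 0.0  # boundary case (perfect separation)
    else:
        half = 1.959963984540054 * se
        ci = (max(auc - half, 0.0), min(auc + half, 1.0))
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    result.auc_ci95 = ci
    result.p_value_vs_half = p
    return ci, p


def analyze(scores, labels, name: str = "", maneuver: str = "") -> ROCResult:
    """Full ROC analysis: curve, cut-off and AUC inference in one call."""
    result = roc_curve(scores, labels, name=name, maneuver=maneuver)
    best_cutoff(result)
    auc_inference(result)
    return result
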