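"""Empirical ROC machinery: curves, Mann-Whitney AUC, DeLong variance,
Youden-index cutoffs, fixed-threshold metrics, and paired comparison of
correlated AUCs.

Conventions: a subject is called positive when its score is **at or
above** the threshold (score >= t).  Candidate thresholds are the unique
observed scores plus a sentinel above the maximum (sensitivity 0,
specificity 1).  Ties in the Youden index are broken toward the larger
sensitivity, i.e. the lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CutoffResult",
    "ROCResult",
    "auc_mann_whitney",
    "delong_components",
    "metrics_at_threshold",
    "paired_auc_test",
    "roc_points",
    "youden_cutoff",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    ci_low: float
    ci_high: float
    p_value: float          # vs AUC = 0.5, normal approximation
    n_pos: int
    n_neg: int


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components and the Mann-Whitney AUC.

    Returns (auc, v10, v01): v10[i] is the mean over negatives of the
    kernel psi(pos_i, neg_j) = 1 if pos>neg, 1/2 if equal, 0 otherwise;
    v01[j] symmetrically averages over positives.
    """
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def auc_mann_whitney(scores, labels) -> tuple[float, float]:
    """AUC = P(pos > neg) + 0.5 P(pos = neg), with its DeLong SE."""
    pos, neg = _split(scores, labels)
    auc, v10, v01 = delong_components(pos, neg)
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    return auc, se


def roc_points(scores, labels) -> ROCResult:
    """Empirical ROC over all observed thresholds (positive <=> score >= t)."""
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)
    sentinel = thresholds[-1] + 1.0 if np.isfinite(thresholds[-1]) else np.inf
    thresholds = np.append(thresholds, sentinel)
    se_curve = np.array([(pos >= t).mean() for t in thresholds])
    sp_curve = np.array([(neg < t).mean() for t in thresholds])
    auc, auc_se = auc_mann_whitney(scores, labels)
    if auc_se > 0:
        z = (auc - 0.5) / auc_se
        p = 2 * stats.norm.sf(abs(z))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    half = 1.959963984540054 * auc_se
    return ROCResult(
        thresholds=thresholds,
        sensitivity=se_curve,
        specificity=sp_curve,
        auc=auc,
        auc_se=auc_se,
        ci_low=auc - half,
        ci_high=auc + half,
        p_value=float(p),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def youden_cutoff(roc: ROCResult) -> CutoffResult:
    """Threshold maximizing J = Se + Sp - 1; ties go to the larger Se.

    With the score >= threshold convention, the larger-sensitivity
    tie-break is the lower threshold.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(np.isclose(j, j.max(), rtol=0, atol=1e-12))
    idx = best[np.argmin(roc.thresholds[best])]
    return CutoffResult(
        cutoff=float(roc.thresholds[idx]),
        sensitivity=float(roc.sensitivity[idx]),
        specificity=float(roc.specificity[idx]),
    )


def metrics_at_threshold(scores, labels, t: float) -> CutoffResult:
    """Sensitivity/specificity (positive <=> score >= t) at a fixed cutoff."""
    pos, neg = _split(scores, labels)
    return CutoffResult(
        cutoff=float(t),
        sensitivity=float((pos >= t).mean()),
        specificity=float((neg < t).mean()),
    )


def paired_auc_test(scores_a, scores_b, labels):
    """DeLong test for two correlated AUCs measured on the same subjects.

    Returns (delta_auc, se, z, p) with delta = AUC(a) - AUC(b) and a
    two-sided normal p value.  Degenerate variance (e.g. identical score
    vectors) yields z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have the same length")
    labels = np.asarray(labels).astype(bool)
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    auc_a, v10_a, v01_a = delong_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = delong_components(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        s10[0, 0] / m + s01[0, 0] / n
        + s10[1, 1] / m + s01[1, 1] / n
        - 2 * (s10[0, 1] / m + s01[0, 1] / n)
    )
    delta = auc_a - auc_b
    if var <= 0:
        return delta, 0.0, 0.0, 1.0
    se = float(np.sqrt(var))
    z = delta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return delta, se, float(z), p
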