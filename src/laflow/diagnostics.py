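"""Diagnostic evaluation: Bland-Altman agreement and ROC analysis.

ROC analysis evaluates the acceleration factor as a classifier for
elevated PAWP (> 15 mmHg by default).  The empirical AUC is the
midrank (tie-corrected) Mann-Whitney statistic with a DeLong 95%
confidence interval; operating points are reported at the
regression-derived cut-off (the fitted calibration line evaluated at
the PAWP threshold) and at the Youden cut-off (maximal sensitivity +
specificity, lowest threshold on ties), each with exact
Clopper-Pearson binomial confidence intervals.  Positivity is strict:
a patient is predicted positive when alpha > cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import CalibrationModel

__all__ = [
    "BlandAltman",
    "CutoffPerformance",
    "RocResult",
    "DiagnosticsError",
    "bland_altman",
    "empirical_auc",
    "delong_ci",
    "clopper_pearson",
    "roc_analysis",
]


class DiagnosticsError(ValueError):
    """Raised for invalid diagnostic inputs."""


@dataclass(frozen=True)
class BlandAltman:
    """Agreement between measured and back-calculated PAWP (mmHg)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(pawp_true, pawp_calc) -> BlandAltman:
    """bias = mean(true - calc); limits of agreement = bias +/- 1.96 SD
    of the paired differences (sample SD, n - 1)."""
    t = np.asarray(pawp_true, dtype=float)
    c = np.asarray(pawp_calc, dtype=float)
    if t.size != c.size:
        raise DiagnosticsError("paired vectors must have equal length")
    keep = np.isfinite(t) & np.isfinite(c)
    t, c = t[keep], c[keep]
    if t.size < 3:
        raise DiagnosticsError("need at least 3 pairs")
    d = t - c
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, int(t.size))


@dataclass(frozen=True)
class CutoffPerformance:
    """Sensitivity/specificity of the rule score > threshold."""

    threshold: float
    sensitivity: float
    specificity: float
    sens_ci95: tuple[float, float]
    spec_ci95: tuple[float, float]
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci95_auc: tuple[float, float]
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    cutoff_regression: CutoffPerformance | None
    cutoff_youden: CutoffPerformance
    n_pos: int
    n_neg: int


def empirical_auc(scores, labels) -> float:
    """Midrank AUC: (concordant pairs + half the tied pairs) divided
    by n_pos * n_neg."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DiagnosticsError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """DeLong variance estimate for the empirical AUC.

    Uses the structural components: for each positive the mean
    placement against the negatives and vice versa; the CI is normal
    on the AUC scale, clipped to [0, 1].  Degenerate (separated)
    samples give a zero-width interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise DiagnosticsError("both classes must be present")
    # placement values via midranks
    comparison = pos[:, None] - neg[None, :]
    psi = np.where(comparison > 0, 1.0, np.where(comparison == 0, 0.5, 0.0))
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if n <= 0:
        raise DiagnosticsError("empty denominator")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def _performance_at(scores, labels, threshold: float) -> CutoffPerformance:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores > threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return CutoffPerformance(
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        sens_ci95=clopper_pearson(tp, tp + fn),
        spec_ci95=clopper_pearson(tn, tn + fp),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def roc_analysis(
    scores,
    labels,
    regression_model: CalibrationModel | None = None,
    pawp_threshold: float = 15.0,
) -> RocResult:
    """ROC analysis of a score for a binary state.

    Candidate thresholds are the midpoints between consecutive sorted
    distinct scores, with -inf/+inf sentinels.  The Youden cut-off is
    the lowest threshold maximising sensitivity + specificity.  When a
    calibration model is supplied, performance is also reported at the
    regression-derived cut-off a + b * pawp_threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DiagnosticsError("both classes must be present")

    uniq = np.unique(scores)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([np.mean(scores[labels] > t) for t in thresholds])
    spec = np.array([np.mean(scores[~labels] <= t) for t in thresholds])

    auc, ci_auc = delong_ci(scores, labels)

    youden = sens + spec
    best = int(np.flatnonzero(youden == youden.max())[0])  # lowest threshold on ties
    youden_perf = _performance_at(scores, labels, thresholds[best])

    reg_perf = None
    if regression_model is not None:
        reg_perf = _performance_at(
            scores, labels, regression_model.cutoff_at(pawp_threshold)
        )

    return RocResult(
        auc=auc,
        ci95_auc=ci_auc,
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        cutoff_regression=reg_perf,
        cutoff_youden=youden_perf,
        n_pos=n_pos,
        n_neg=n_neg,
    )
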