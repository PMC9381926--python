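"""Statistical machinery for the acceleration-factor analysis.

* Non-linear least squares of PAWP on the general velocity-ratio
  family with large-sample (Wald) confidence intervals for the ratio
  constants, used to select the functional form of the acceleration
  factor.
* Ordinary least squares calibration of alpha on PAWP with PRESS
  (leave-one-out) R-squared and inversion to back-calculate PAWP.
* One-way ANOVA with Tukey-Kramer pairwise comparisons.
* Partial F-tests for added binary/continuous predictors.
* Williams-Hotelling comparison of two dependent correlations sharing
  one variable, and the one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GeneralRatioFit",
    "CalibrationModel",
    "GroupComparison",
    "CorrelationComparison",
    "FitError",
    "fit_general_ratio",
    "fit_calibration",
    "compare_groups",
    "partial_f_test",
    "compare_dependent_correlations",
    "one_sample_t",
]

#: Multi-start grid for the ratio constants, covering the plausible
#: corners of the (c_out, c_in) plane.
C_OUT_STARTS = (0.0, 0.5, 1.0)
C_IN_STARTS = (-0.5, 0.0, 0.5, 1.0)


class FitError(RuntimeError):
    """Raised when a model cannot be fitted."""


@dataclass(frozen=True)
class GeneralRatioFit:
    """Result of regressing PAWP on the general velocity ratio.

    PAWP_i = beta0 + beta1 * alpha_general(q_i; c_out, c_in) + eps_i.
    ``r_nonlinear`` is sqrt(1 - SSE/SST).  The ratio form is judged
    optimal when c_out = 1 lies in its 95% CI and c_in = 0 in its 95%
    CI (for the fixed-c_out fit only the c_in condition applies).
    """

    beta0: float
    beta1: float
    c_out: float
    c_in: float
    ci95_c_out: tuple[float, float] | None
    ci95_c_in: tuple[float, float]
    r_nonlinear: float
    n_used: int
    converged: bool
    fixed_c_out: bool
    sse: float
    sst: float

    @property
    def optimal(self) -> bool:
        ok_in = bool(self.ci95_c_in[0] <= 0.0 <= self.ci95_c_in[1])
        if self.fixed_c_out or self.ci95_c_out is None:
            return ok_in
        ok_out = bool(self.ci95_c_out[0] <= 1.0 <= self.ci95_c_out[1])
        return ok_in and ok_out


@dataclass(frozen=True)
class CalibrationModel:
    """OLS calibration alpha = a + b * PAWP and its inversion
    PAWP_calc = inverse_intercept + inverse_slope * alpha."""

    intercept_a: float
    slope_b: float
    r: float
    rmse: float
    press_r2: float
    r2: float
    n: int

    @property
    def inverse_slope(self) -> float:
        return 1.0 / self.slope_b

    @property
    def inverse_intercept(self) -> float:
        return -self.intercept_a / self.slope_b

    def predict_alpha(self, pawp) -> np.ndarray:
        return self.intercept_a + self.slope_b * np.asarray(pawp, dtype=float)

    def pawp_calc(self, alpha_values) -> np.ndarray:
        return self.inverse_intercept + self.inverse_slope * np.asarray(
            alpha_values, dtype=float
        )

    def cutoff_at(self, pawp_threshold: float) -> float:
        """The alpha value the regression maps to a PAWP threshold."""
        return self.intercept_a + self.slope_b * pawp_threshold


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA plus Tukey-Kramer pairwise adjusted p-values."""

    groups: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    anova_f: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]


@dataclass(frozen=True)
class CorrelationComparison:
    """Williams-Hotelling test of H0: rho(x, y) = rho(x, z)."""

    r_xy: float
    r_xz: float
    r_yz: float
    n: int
    t_statistic: float
    p_value: float


def _ratio_design(
    pawp, v_e, v_s, v_d, v_a
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arrays = [np.asarray(x, dtype=float) for x in (pawp, v_e, v_s, v_d)]
    va = None if v_a is None else np.asarray(v_a, dtype=float)
    n = arrays[0].size
    if any(a.size != n for a in arrays) or (va is not None and va.size != n):
        raise FitError("input vectors must have equal length")
    return (*arrays, va)


def fit_general_ratio(
    pawp,
    v_e,
    v_s,
    v_d,
    v_a=None,
    fix_c_out: float | None = None,
) -> GeneralRatioFit:
    """Least-squares fit of PAWP on the general velocity ratio.

    With ``fix_c_out=None`` both ratio constants are free and rows
    with missing v_A are dropped (biphasic patients only; at least 10
    required).  With ``fix_c_out=1`` the numerator reduces to v_E, so
    v_A-free records are admissible and all patients enter.

    The intercept/slope are profiled out (they enter linearly), the
    ratio constants are optimised by trust-region least squares from a
    small multi-start grid, and 95% confidence intervals come from the
    classical large-sample normal-theory covariance s^2 (J^T J)^{-1}
    of the full parameter vector at the optimum.
    """
    pawp, v_e, v_s, v_d, v_a = _ratio_design(pawp, v_e, v_s, v_d, v_a)

    free_c_out = fix_c_out is None
    if free_c_out:
        if v_a is None:
            raise FitError("the free fit requires v_A")
        keep = np.isfinite(v_a)
        pawp, v_e, v_s, v_d, v_a = (
            x[keep] for x in (pawp, v_e, v_s, v_d, v_a)
        )
        if pawp.size < 10:
            raise FitError("need at least 10 biphasic records for the free fit")
    else:
        if float(fix_c_out) != 1.0:
            # with c_out fixed at a value other than 1 the numerator
            # still involves v_A
            if v_a is None:
                raise FitError("fixing c_out != 1 requires v_A")
        else:
            # c_out = 1 collapses the numerator to v_E
            v_a = v_e.copy()
    if pawp.size < 4:
        raise FitError("too few records")

    v_ea_p = 0.5 * (v_e + v_a)
    v_ea_m = 0.5 * (v_e - v_a)
    v_sd_p = 0.5 * (v_s + v_d)
    v_sd_m = 0.5 * (v_s - v_d)
    n = pawp.size
    sst = float(np.sum((pawp - pawp.mean()) ** 2))
    if sst <= 0:
        raise FitError("PAWP has zero variance")

    def num_den(c_out: float, c_in: float) -> tuple[np.ndarray, np.ndarray]:
        return v_ea_p + c_out * v_ea_m, v_sd_p + c_in * v_sd_m

    big = 1e6

    def profiled_residuals(theta: np.ndarray) -> np.ndarray:
        c_out = theta[0] if free_c_out else float(fix_c_out)
        c_in = theta[-1]
        num, den = num_den(c_out, c_in)
        if np.any(den <= 0):
            return np.full(n, big)  # step into a degenerate denominator: reject
        g = num / den
        X = np.column_stack([np.ones(n), g])
        beta, *_ = np.linalg.lstsq(X, pawp, rcond=None)
        return pawp - X @ beta

    starts = (
        [np.array([co, ci]) for co in C_OUT_STARTS for ci in C_IN_STARTS]
        if free_c_out
        else [np.array([ci]) for ci in C_IN_STARTS]
    )
    best = None
    any_success = False
    for x0 in starts:
        if np.any(num_den(x0[0] if free_c_out else float(fix_c_out), x0[-1])[1] <= 0):
            continue
        try:
            res = optimize.least_squares(profiled_residuals, x0, method="trf")
        except Exception:
            continue
        any_success = any_success or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("general-ratio fit failed from every start")

    c_out_hat = float(best.x[0]) if free_c_out else float(fix_c_out)
    c_in_hat = float(best.x[-1])
    num, den = num_den(c_out_hat, c_in_hat)
    g = num / den
    X = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(X, pawp, rcond=None)
    beta0, beta1 = float(beta[0]), float(beta[1])
    resid = pawp - X @ beta
    sse = float(resid @ resid)

    # full-parameter Jacobian of the residuals at the optimum:
    # r_i = pawp_i - beta0 - beta1 * g_i(c_out, c_in)
    cols = [-np.ones(n), -g]
    if free_c_out:
        cols.append(-beta1 * v_ea_m / den)
    cols.append(beta1 * num * v_sd_m / den**2)
    J = np.column_stack(cols)
    p = J.shape[1]
    dof = n - p
    if dof <= 0:
        raise FitError("not enough records for the requested model")
    s2 = sse / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information matrix in general-ratio fit") from exc
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(cov))
    if free_c_out:
        ci_c_out = (c_out_hat - tcrit * se[2], c_out_hat + tcrit * se[2])
        ci_c_in = (c_in_hat - tcrit * se[3], c_in_hat + tcrit * se[3])
    else:
        ci_c_out = None
        ci_c_in = (c_in_hat - tcrit * se[2], c_in_hat + tcrit * se[2])

    return GeneralRatioFit(
        beta0=beta0,
        beta1=beta1,
        c_out=c_out_hat,
        c_in=c_in_hat,
        ci95_c_out=ci_c_out,
        ci95_c_in=ci_c_in,
        r_nonlinear=float(np.sqrt(max(0.0, 1.0 - sse / sst))),
        n_used=n,
        converged=bool(any_success),
        fixed_c_out=not free_c_out,
        sse=sse,
        sst=sst,
    )


def fit_calibration(pawp, alpha_values) -> CalibrationModel:
    """OLS of alpha on PAWP with PRESS R-squared.

    PRESS residuals use the hat-matrix shortcut e_i / (1 - h_ii),
    which equals the prediction error of the model refitted without
    observation i.
    """
    pawp = np.asarray(pawp, dtype=float)
    a = np.asarray(alpha_values, dtype=float)
    keep = np.isfinite(pawp) & np.isfinite(a)
    pawp, a = pawp[keep], a[keep]
    n = pawp.size
    if n < 3:
        raise FitError("need at least 3 records to calibrate")
    if np.ptp(pawp) == 0:
        raise FitError("PAWP has zero variance")

    X = np.column_stack([np.ones(n), pawp])
    beta, *_ = np.linalg.lstsq(X, a, rcond=None)
    fitted = X @ beta
    resid = a - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    r = float(np.corrcoef(pawp, a)[0, 1])

    h = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    press_r2 = 1.0 - press / sst if sst > 0 else np.nan

    if beta[1] == 0:
        raise FitError("zero calibration slope cannot be inverted")
    return CalibrationModel(
        intercept_a=float(beta[0]),
        slope_b=float(beta[1]),
        r=r,
        rmse=float(np.sqrt(sse / (n - 2))),
        press_r2=float(press_r2),
        r2=float(r2),
        n=n,
    )


def compare_groups(values, labels) -> GroupComparison:
    """One-way ANOVA plus Tukey-Kramer pairwise comparisons (exact for
    unequal group sizes via the studentized-range distribution)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    names = tuple(pd.unique(labels))
    if len(names) < 2:
        raise FitError("need at least two groups")
    samples = [values[labels == g] for g in names]
    if any(s.size < 2 for s in samples):
        raise FitError("every group needs at least two observations")

    f_stat, p = stats.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, labels)
    pairwise: dict[tuple[str, str], float] = {}
    for (g1, g2), padj in zip(combinations(tukey.groupsunique, 2), tukey.pvalues):
        pairwise[(str(g1), str(g2))] = float(padj)

    return GroupComparison(
        groups=tuple(str(g) for g in names),
        means={str(g): float(s.mean()) for g, s in zip(names, samples)},
        sds={str(g): float(s.std(ddof=1)) for g, s in zip(names, samples)},
        ns={str(g): int(s.size) for g, s in zip(names, samples)},
        anova_f=float(f_stat),
        anova_p=float(p),
        pairwise_p=pairwise,
    )


def partial_f_test(y, x_base, x_added) -> tuple[float, float]:
    """Extra-sum-of-squares F-test of nested OLS models.

    The reduced model regresses ``y`` on an intercept plus the columns
    of ``x_base``; the full model adds the columns of ``x_added``
    (binary indicators, interactions, or continuous covariates).  The
    stacked full design must have full column rank.
    """
    y = np.asarray(y, dtype=float)
    xb = np.atleast_2d(np.asarray(x_base, dtype=float))
    xa = np.atleast_2d(np.asarray(x_added, dtype=float))
    if xb.shape[0] != y.size:
        xb = xb.T
    if xa.shape[0] != y.size:
        xa = xa.T
    n = y.size
    Xr = np.column_stack([np.ones(n), xb])
    Xf = np.column_stack([Xr, xa])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise FitError("full design matrix is rank deficient (non-nested or duplicated terms)")

    def sse(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    sse_r, sse_f = sse(Xr), sse(Xf)
    q = Xf.shape[1] - Xr.shape[1]
    dof = n - Xf.shape[1]
    if dof <= 0:
        raise FitError("not enough records for the full model")
    f_stat = max(0.0, (sse_r - sse_f) / q) / (sse_f / dof)
    p = float(stats.f.sf(f_stat, q, dof))
    return float(f_stat), p


def compare_dependent_correlations(x, y, z) -> CorrelationComparison:
    """Williams' t-test for two dependent correlations r(x, y) and
    r(x, z) sharing the variable x.

    t = (r_xy - r_xz) * sqrt((n - 1)(1 + r_yz) /
        (2 ((n-1)/(n-3)) |R| + rbar^2 (1 - r_yz)^3)),

    with |R| the determinant of the 3x3 correlation matrix and rbar
    the mean of the two compared correlations; two-sided p on n - 3
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    n = x.size
    if n < 4:
        raise FitError("need at least 4 complete triples")

    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])

    if np.isclose(r_yz, 1.0) and np.isclose(r_xy, r_xz):
        # identical (up to affinity) comparison variables: no difference
        return CorrelationComparison(r_xy, r_xz, r_yz, n, 0.0, 1.0)
    if np.isclose(abs(r_yz), 1.0):
        raise FitError("|r_yz| = 1: the compared variables are collinear")

    det_r = 1.0 - r_xy**2 - r_xz**2 - r_yz**2 + 2.0 * r_xy * r_xz * r_yz
    rbar = 0.5 * (r_xy + r_xz)
    denom = 2.0 * ((n - 1.0) / (n - 3.0)) * det_r + rbar**2 * (1.0 - r_yz) ** 3
    if denom <= 0:
        raise FitError("degenerate correlation structure")
    t = (r_xy - r_xz) * np.sqrt((n - 1.0) * (1.0 + r_yz) / denom)
    p = float(2.0 * stats.t.sf(abs(t), n - 3))
    return CorrelationComparison(r_xy, r_xz, r_yz, n, float(t), p)


def one_sample_t(differences) -> tuple[float, float]:
    """Two-sided one-sample t-test of mean zero.

    Zero-variance input: all-zero differences give (0, 1); a constant
    non-zero difference gives (+/-inf, 0) by sign convention.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise FitError("need at least 2 differences")
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return (np.inf if d[0] > 0 else -np.inf), 0.0
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p)
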