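"""Statistical machinery against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from laflow.acceleration import alpha_general_from_arrays
from laflow.inference import (
    FitError,
    compare_dependent_correlations,
    compare_groups,
    fit_calibration,
    fit_general_ratio,
    one_sample_t,
    partial_f_test,
)


# --- general-ratio fit -------------------------------------------------------


def test_noise_free_cohort_recovers_generative_constants(noise_free_cohort_df):
    """Data generated with alpha exactly linear in PAWP identify
    c_out = 1, c_in = 0 to solver tolerance, with r = 1."""
    df = noise_free_cohort_df
    fit = fit_general_ratio(
        df["pawp_mmHg"], df["vE"], df["vS"], df["vD"], df["vA"]
    )
    assert fit.c_out == pytest.approx(1.0, abs=1e-5)
    assert fit.c_in == pytest.approx(0.0, abs=1e-5)
    assert fit.r_nonlinear == pytest.approx(1.0, abs=1e-8)
    assert fit.converged and fit.optimal


def test_fit_reduces_to_ols_at_fitted_constants(default_cohort_df):
    """With the ratio constants held at their estimates, the remaining
    model is plain OLS of PAWP on the computed ratio values."""
    df = default_cohort_df
    keep = df["vA"].notna()
    fit = fit_general_ratio(
        df["pawp_mmHg"], df["vE"], df["vS"], df["vD"], df["vA"]
    )
    g = alpha_general_from_arrays(
        df.loc[keep, "vE"], df.loc[keep, "vA"], df.loc[keep, "vS"],
        df.loc[keep, "vD"], fit.c_out, fit.c_in,
    )
    X = np.column_stack([np.ones(g.size), g])
    beta, *_ = np.linalg.lstsq(X, df.loc[keep, "pawp_mmHg"].to_numpy(), rcond=None)
    assert fit.beta0 == pytest.approx(beta[0], rel=1e-8)
    assert fit.beta1 == pytest.approx(beta[1], rel=1e-8)
    # nesting consistency: r_nonlinear equals |Pearson r| of PAWP vs the ratio
    r = np.corrcoef(df.loc[keep, "pawp_mmHg"], g)[0, 1]
    assert fit.r_nonlinear == pytest.approx(abs(r), rel=1e-8)


def test_fixed_c_out_admits_monophasic_records(default_cohort_df):
    df = default_cohort_df
    fit = fit_general_ratio(
        df["pawp_mmHg"], df["vE"], df["vS"], df["vD"], df["vA"], fix_c_out=1.0
    )
    assert fit.n_used == len(df)  # v_A-free records enter
    assert fit.ci95_c_out is None and fit.fixed_c_out


def test_free_fit_requires_biphasic_records():
    rng = np.random.default_rng(0)
    with pytest.raises(FitError):
        fit_general_ratio(
            rng.normal(10, 4, 8), rng.uniform(30, 60, 8),
            rng.uniform(20, 40, 8), rng.uniform(20, 40, 8),
            rng.uniform(20, 50, 8),
        )


# --- calibration -------------------------------------------------------------


def test_calibration_exact_interpolation():
    pawp = [0.0, 10.0, 20.0]
    a = [0.5, 1.5, 2.5]  # exactly on a line with slope 0.10
    m = fit_calibration(pawp, a)
    assert m.intercept_a == pytest.approx(0.5, abs=1e-12)
    assert m.slope_b == pytest.approx(0.10, abs=1e-12)
    assert m.inverse_intercept == pytest.approx(-5.0, abs=1e-9)
    assert m.inverse_slope == pytest.approx(10.0, abs=1e-9)
    assert m.cutoff_at(15.0) == pytest.approx(2.0, abs=1e-12)


def test_press_equals_explicit_leave_one_out_refits(default_cohort_df):
    df = default_cohort_df
    pawp = df["pawp_mmHg"].to_numpy()
    a = df["alpha"].to_numpy()
    m = fit_calibration(pawp, a)

    press = 0.0
    for i in range(len(pawp)):
        mask = np.ones(len(pawp), dtype=bool)
        mask[i] = False
        b, c = np.polyfit(pawp[mask], a[mask], 1)
        press += (a[i] - (c + b * pawp[i])) ** 2
    sst = np.sum((a - a.mean()) ** 2)
    assert m.press_r2 == pytest.approx(1.0 - press / sst, rel=1e-10)
    assert m.press_r2 <= m.r2


def test_calibration_errors():
    with pytest.raises(FitError):
        fit_calibration([1.0, 2.0], [0.5, 0.6])
    with pytest.raises(FitError):
        fit_calibration([5.0, 5.0, 5.0], [0.5, 0.6, 0.7])


# --- group comparison --------------------------------------------------------


def test_identical_groups_give_null_anova():
    vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
    labels = np.repeat(["a", "b", "c"], 4)
    gc = compare_groups(vals, labels)
    assert gc.anova_f == pytest.approx(0.0, abs=1e-12)
    assert all(p == pytest.approx(1.0, abs=1e-9) for p in gc.pairwise_p.values())


def test_two_group_tukey_equals_pooled_t_test():
    """With two groups the Tukey-Kramer adjusted p equals the pooled
    t-test p through q = t * sqrt(2)."""
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 12)
    y = rng.normal(0.8, 1, 17)
    vals = np.concatenate([x, y])
    labels = np.array(["a"] * 12 + ["b"] * 17)
    gc = compare_groups(vals, labels)
    t, p_t = stats.ttest_ind(x, y, equal_var=True)
    p_q = stats.studentized_range.sf(abs(t) * np.sqrt(2), 2, 12 + 17 - 2)
    assert p_t == pytest.approx(p_q, rel=1e-6)  # oracle identity
    assert gc.pairwise_p[("a", "b")] == pytest.approx(p_t, rel=1e-4)


def test_group_alpha_pattern_on_default_cohort(default_cohort_df):
    """Mean alpha separates the post-capillary group from both other
    groups, while non-PH and pre-capillary PH do not differ."""
    df = default_cohort_df
    gc = compare_groups(df["alpha"].to_numpy(), df["group"].to_numpy())
    p = {tuple(sorted(k)): v for k, v in gc.pairwise_p.items()}
    assert p[("non_PH", "pre_capillary_PH")] > 0.05
    assert p[("non_PH", "post_capillary_PH")] < 0.001
    assert p[("post_capillary_PH", "pre_capillary_PH")] < 0.001


def test_zero_variance_group_handled():
    vals = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
    labels = np.array(["a"] * 3 + ["b"] * 3)
    gc = compare_groups(vals, labels)
    assert np.isfinite(gc.anova_f)
    assert 0.0 <= gc.pairwise_p[("a", "b")] <= 1.0


# --- partial F-test ----------------------------------------------------------


def test_partial_f_matches_manual_sse_algebra():
    rng = np.random.default_rng(12)
    n = 10
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = 1.0 + 2.0 * x + 0.5 * z + rng.normal(0, 0.3, n)
    f, p = partial_f_test(y, x, z)

    Xr = np.column_stack([np.ones(n), x])
    Xf = np.column_stack([np.ones(n), x, z])
    sse_r = np.sum((y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]) ** 2)
    sse_f = np.sum((y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]) ** 2)
    f_manual = ((sse_r - sse_f) / 1) / (sse_f / (n - 3))
    assert f == pytest.approx(f_manual, abs=1e-10)
    assert p == pytest.approx(stats.f.sf(f_manual, 1, n - 3), abs=1e-12)


def test_orthogonal_added_term_gives_zero_f():
    rng = np.random.default_rng(3)
    n = 40
    x = rng.normal(size=n)
    y = 2.0 + x + rng.normal(size=n)
    v = rng.normal(size=n)
    # orthogonalise v against intercept, x and y: its OLS coefficient is 0
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), x, y]))
    v = v - Q @ (Q.T @ v)
    f, p = partial_f_test(y, x, v)
    assert f == pytest.approx(0.0, abs=1e-18)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_duplicated_predictor_rejected():
    rng = np.random.default_rng(4)
    x = rng.normal(size=15)
    y = x + rng.normal(size=15)
    with pytest.raises(FitError, match="rank"):
        partial_f_test(y, x, 2.0 * x)


def test_binary_with_interaction_addition(default_cohort_df):
    """Slope/intercept shifts by a binary covariate enter as indicator
    plus indicator-by-PAWP interaction columns."""
    df = default_cohort_df
    pawp = df["pawp_mmHg"].to_numpy()
    a = df["alpha"].to_numpy()
    left = (df["vein_used"] == "left_inferior").to_numpy().astype(float)
    f, p = partial_f_test(a, pawp, np.column_stack([left, left * pawp]))
    assert f >= 0.0 and 0.0 <= p <= 1.0
    # the generator makes the vein label carry no information about alpha
    assert p > 0.01


# --- dependent correlations --------------------------------------------------


def test_identical_comparison_variables_give_null_result():
    rng = np.random.default_rng(8)
    x = rng.normal(size=25)
    y = x + rng.normal(size=25)
    cc = compare_dependent_correlations(x, y, y)
    assert cc.t_statistic == 0.0
    assert cc.p_value == 1.0


def test_collinear_comparison_variables_rejected():
    rng = np.random.default_rng(9)
    x = rng.normal(size=25)
    y = x + rng.normal(size=25)
    # a positive affine image of y carries identical correlations: null result
    cc = compare_dependent_correlations(x, y, 2.0 * y + 1.0)
    assert (cc.t_statistic, cc.p_value) == (0.0, 1.0)
    # sign-flipped y is collinear but changes the correlation: undefined
    with pytest.raises(FitError, match="collinear"):
        compare_dependent_correlations(x, y, -y)


def test_williams_p_agrees_with_permutation_oracle():
    """Under exchangeable y/z the Williams p-value matches a sign-flip
    permutation distribution of r_xy - r_xz within Monte-Carlo error."""
    rng = np.random.default_rng(77)
    n = 20
    x = rng.normal(size=n)
    common = 0.7 * x
    y = common + rng.normal(0, 0.8, n)
    z = common + rng.normal(0, 0.8, n)
    cc = compare_dependent_correlations(x, y, z)

    def stat(yy, zz):
        return np.corrcoef(x, yy)[0, 1] - np.corrcoef(x, zz)[0, 1]

    obs = abs(stat(y, z))
    n_perm = 4000
    count = 0
    for _ in range(n_perm):
        flip = rng.random(n) < 0.5
        y2 = np.where(flip, z, y)
        z2 = np.where(flip, y, z)
        if abs(stat(y2, z2)) >= obs - 1e-15:
            count += 1
    p_perm = count / n_perm
    assert abs(cc.p_value - p_perm) < 0.08


def test_stronger_junction_correlation_detected(default_cohort_df):
    """alpha correlates with PAWP more strongly than alpha from vein
    velocities; the dependent-correlation test flags the difference."""
    from laflow.acceleration import alpha_variants

    df = default_cohort_df
    var = alpha_variants(df)
    cc = compare_dependent_correlations(
        df["pawp_mmHg"].to_numpy(), var["alpha"].to_numpy(), var["alpha_vein"].to_numpy()
    )
    assert cc.r_xy > cc.r_xz
    assert cc.p_value < 0.01


# --- one-sample t ------------------------------------------------------------


def test_one_sample_t_matches_arithmetic_for_tip_bias():
    """A sample with mean 6 and SD 9 over 56 patients gives
    t = 6 / (9 / sqrt(56)) and p < 1e-4."""
    rng = np.random.default_rng(21)
    z = rng.normal(size=56)
    d = 6.0 + 9.0 * (z - z.mean()) / z.std(ddof=1)
    t, p = one_sample_t(d)
    assert t == pytest.approx(6.0 / (9.0 / np.sqrt(56)), rel=1e-12)
    assert p < 1e-4


def test_one_sample_t_edge_cases():
    assert one_sample_t(np.zeros(5)) == (0.0, 1.0)
    t, p = one_sample_t(np.full(5, 2.0))
    assert t == np.inf and p == 0.0
    d = np.random.default_rng(2).normal(1, 2, 30)
    t1, _ = one_sample_t(d)
    t2, _ = one_sample_t(-d)
    assert t1 == pytest.approx(-t2, rel=1e-12)
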