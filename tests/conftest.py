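import numpy as np
import pytest

from laflow import CohortConfig, cohort_to_dataframe, generate_cohort
from laflow.acceleration import alpha_from_arrays


@pytest.fixture(scope="session")
def default_cohort():
    """One default 62-patient cohort under a fixed seed."""
    return generate_cohort(CohortConfig(seed=20240917))


@pytest.fixture(scope="session")
def default_cohort_df(default_cohort):
    df = cohort_to_dataframe(default_cohort)
    df["alpha"] = alpha_from_arrays(df["vE"], df["vS"], df["vD"])
    return df


@pytest.fixture(scope="session")
def noise_free_cohort_df():
    """A cohort generated with zero residual scatter on the alpha law."""
    cfg = CohortConfig(seed=7, alpha_noise_sd=0.0, monophasic_fraction=0.0)
    df = cohort_to_dataframe(generate_cohort(cfg))
    df["alpha"] = alpha_from_arrays(df["vE"], df["vS"], df["vD"])
    return df


def per_cohort_stats(df, pawp_threshold=15.0, fixed_cutoff=2.10):
    """Headline statistics of one cohort, shared by acceptance checks."""
    from laflow.diagnostics import empirical_auc
    from laflow.inference import fit_calibration

    a = df["alpha"].to_numpy()
    pawp = df["pawp_mmHg"].to_numpy()
    calib = fit_calibration(pawp, a)
    pawp_calc = calib.pawp_calc(a)
    pos = pawp > pawp_threshold
    ph = df["group"].isin(["pre_capillary_PH", "post_capillary_PH"]).to_numpy()
    return {
        "r": calib.r,
        "slope": calib.slope_b,
        "intercept": calib.intercept_a,
        "sd_diff": float(np.std(pawp - pawp_calc, ddof=1)),
        "cutoff": calib.cutoff_at(pawp_threshold),
        "auc": empirical_auc(a, pos),
        "spec": float(np.mean(a[~pos] <= fixed_cutoff)) * 100.0,
        "sens": float(np.mean(a[pos] > fixed_cutoff)) * 100.0,
        "mean_alpha": float(a.mean()),
        "post_mean_alpha": float(a[(df["group"] == "post_capillary_PH").to_numpy()].mean()),
        "auc_ph": empirical_auc(a[ph], (df["group"] == "post_capillary_PH").to_numpy()[ph]),
        "press_r2": calib.press_r2,
        "r2": calib.r2,
    }
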