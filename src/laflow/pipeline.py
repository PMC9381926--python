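"""End-to-end seeded analysis pipeline.

Orchestrates: cohort generation -> (optional) waveform round-trip
through peak extraction -> acceleration-factor table -> group
comparison -> general-ratio model selection -> linear calibration ->
Bland-Altman agreement -> ROC analyses (elevated PAWP in all
patients; post-capillary PH among PH patients) -> measurement-location
comparison (one-sample t-tests on velocity differences and
Williams-Hotelling tests on dependent correlations).  All outputs are
reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acceleration, diagnostics, inference
from .cohort import CohortConfig, cohort_to_dataframe, generate_cohort, write_cohort_csv
from .extraction import detect_inflow_peaks, detect_outflow_peaks
from .waveforms import WaveformConfig, generate_waveforms

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_replicates"]

logger = logging.getLogger(__name__)


def _json_default(obj):
    """Coerce numpy scalars for JSON serialisation."""
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    The seed is mandatory and drives every source of randomness.
    ``pawp_threshold`` (mmHg) defines the elevated-PAWP state used for
    the regression-derived cut-off and ROC analyses.
    """

    seed: int
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pawp_threshold: float = 15.0
    waveform_roundtrip: bool = True
    outdir: str | None = None
    replicates: int = 1
    save_plots: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        """Load a flat key-value YAML config.

        Recognised keys: seed, pawp_threshold, waveform_roundtrip,
        outdir, replicates, save_plots, plus any CohortConfig scalar
        field (alpha_intercept, alpha_slope, alpha_noise_sd,
        monophasic_fraction, rho_vs_vd, rho_vs_va, p_left_vein).
        """
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        cohort_keys = {
            "alpha_intercept",
            "alpha_slope",
            "alpha_noise_sd",
            "monophasic_fraction",
            "rho_vs_vd",
            "rho_vs_va",
            "p_left_vein",
            "max_retries",
        }
        run_keys = {
            "seed",
            "pawp_threshold",
            "waveform_roundtrip",
            "outdir",
            "replicates",
            "save_plots",
        }
        unknown = set(raw) - cohort_keys - run_keys
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if seed is None:
            if "seed" not in raw:
                raise ValueError("a seed is mandatory for pipeline runs")
            seed = int(raw["seed"])
        cohort = CohortConfig(
            seed=seed, **{k: raw[k] for k in cohort_keys if k in raw}
        )
        kwargs = {k: raw[k] for k in run_keys if k in raw and k != "seed"}
        return cls(seed=seed, cohort=cohort, **kwargs)


def _roundtrip_extraction(df: pd.DataFrame, records, wconfig: WaveformConfig) -> dict:
    """Generate noise-free waveforms per patient, re-extract the peaks
    and report the maximal absolute discrepancy (cm/s)."""
    max_err = 0.0
    n_mono = 0
    n_va_below_prominence = 0
    for rec in records:
        tm, ven = generate_waveforms(rec, wconfig)
        out = detect_outflow_peaks(tm)
        inn = detect_inflow_peaks(ven)
        max_err = max(
            max_err,
            abs(out.v_e - rec.v_e),
            abs(inn.v_s - rec.v_s),
            abs(inn.v_d - rec.v_d),
        )
        if rec.v_a is None:
            n_mono += 1
            if out.v_a is not None:
                raise PipelineError(
                    "extraction: late diastolic peak detected on a monophasic record"
                )
        elif out.v_a is None:
            # a planted late peak below the prominence rule is read as
            # monophasic; counted, not an error
            n_va_below_prominence += 1
        else:
            max_err = max(max_err, abs(out.v_a - rec.v_a))
    return {
        "max_abs_error_cm_s": max_err,
        "n_monophasic": n_mono,
        "n_va_below_prominence": n_va_below_prominence,
    }


def _cutoff_dict(perf: diagnostics.CutoffPerformance | None) -> dict | None:
    if perf is None:
        return None
    return {
        "threshold": perf.threshold,
        "sensitivity": perf.sensitivity,
        "specificity": perf.specificity,
        "sens_ci95": list(perf.sens_ci95),
        "spec_ci95": list(perf.spec_ci95),
        "tp": perf.tp,
        "fp": perf.fp,
        "tn": perf.tn,
        "fn": perf.fn,
    }


def _roc_dict(roc: diagnostics.RocResult) -> dict:
    return {
        "auc": roc.auc,
        "ci95_auc": list(roc.ci95_auc),
        "n_pos": roc.n_pos,
        "n_neg": roc.n_neg,
        "cutoff_regression": _cutoff_dict(roc.cutoff_regression),
        "cutoff_youden": _cutoff_dict(roc.cutoff_youden),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis once; returns the report dict and, if
    ``config.outdir`` is set, writes report.json, cohort.csv,
    roc_points.csv, run.log and optional figures."""
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    def stage(name: str):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged per stage
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrap

    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    records = stage("generate")(generate_cohort, cohort_cfg)
    df = cohort_to_dataframe(records)
    log("generate", f"{len(records)} patients, seed {config.seed}")

    roundtrip = None
    if config.waveform_roundtrip:
        roundtrip = stage("extract")(_roundtrip_extraction, df, records, WaveformConfig())
        log("extract", f"waveform round-trip max error {roundtrip['max_abs_error_cm_s']:.3g} cm/s")

    variants = stage("alpha")(acceleration.alpha_variants, df)
    df = df.merge(variants, on="patient_id")
    alpha_vals = df["alpha"].to_numpy()
    pawp = df["pawp_mmHg"].to_numpy()
    log("alpha", f"mean alpha {alpha_vals.mean():.3f}")

    groups = stage("groups")(inference.compare_groups, alpha_vals, df["group"].to_numpy())

    free_fit = stage("ratio_fit")(
        inference.fit_general_ratio,
        pawp, df["vE"].to_numpy(), df["vS"].to_numpy(), df["vD"].to_numpy(),
        df["vA"].to_numpy(),
    )
    fixed_fit = stage("ratio_fit")(
        inference.fit_general_ratio,
        pawp, df["vE"].to_numpy(), df["vS"].to_numpy(), df["vD"].to_numpy(),
        df["vA"].to_numpy(), fix_c_out=1.0,
    )
    log(
        "ratio_fit",
        f"free fit: c_out {free_fit.c_out:.3f} {free_fit.ci95_c_out}, "
        f"c_in {free_fit.c_in:.3f} {free_fit.ci95_c_in}, r {free_fit.r_nonlinear:.3f}",
    )

    calib = stage("calibration")(inference.fit_calibration, pawp, alpha_vals)
    log(
        "calibration",
        f"alpha = {calib.intercept_a:.3f} + {calib.slope_b:.4f} PAWP, "
        f"r {calib.r:.3f}, PRESS R2 {calib.press_r2:.3f}",
    )

    pawp_calc = calib.pawp_calc(alpha_vals)
    ba = stage("bland_altman")(diagnostics.bland_altman, pawp, pawp_calc)

    positive = pawp > config.pawp_threshold
    roc_all = stage("roc")(
        diagnostics.roc_analysis, alpha_vals, positive, calib, config.pawp_threshold
    )
    ph_mask = df["group"].isin(["pre_capillary_PH", "post_capillary_PH"]).to_numpy()
    roc_ph = stage("roc")(
        diagnostics.roc_analysis,
        alpha_vals[ph_mask],
        (df["group"] == "post_capillary_PH").to_numpy()[ph_mask],
        calib,
        config.pawp_threshold,
    )
    log("roc", f"AUC (elevated PAWP) {roc_all.auc:.3f}; AUC (post-capillary among PH) {roc_ph.auc:.3f}")

    # measurement-location comparison
    location_bias = {}
    for alt_col, base_col in (
        ("vS_vein", "vS"), ("vD_vein", "vD"), ("vE_tip", "vE"), ("vA_tip", "vA"),
    ):
        d = (df[alt_col] - df[base_col]).to_numpy()
        t, p = stage("locations")(inference.one_sample_t, d)
        d = d[np.isfinite(d)]
        location_bias[alt_col] = {
            "mean_bias_cm_s": float(d.mean()),
            "sd_bias_cm_s": float(d.std(ddof=1)),
            "t": t,
            "p": p,
        }
    location_corr = {}
    for variant in ("alpha_tip", "alpha_vein", "alpha_tip_vein"):
        cc = stage("locations")(
            inference.compare_dependent_correlations,
            pawp, alpha_vals, df[variant].to_numpy(),
        )
        location_corr[variant] = {
            "r_alpha": cc.r_xy,
            "r_variant": cc.r_xz,
            "t": cc.t_statistic,
            "p": cc.p_value,
            "n": cc.n,
        }

    report = {
        "seed": config.seed,
        "n_patients": int(len(records)),
        "pawp_threshold_mmHg": config.pawp_threshold,
        "waveform_roundtrip": roundtrip,
        "alpha_summary": {
            "mean": float(alpha_vals.mean()),
            "sd": float(alpha_vals.std(ddof=1)),
            "group_means": groups.means,
            "group_sds": groups.sds,
        },
        "group_comparison": {
            "anova_f": groups.anova_f,
            "anova_p": groups.anova_p,
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in groups.pairwise_p.items()},
        },
        "general_ratio_fit": {
            "free": {
                "c_out": free_fit.c_out,
                "c_in": free_fit.c_in,
                "ci95_c_out": list(free_fit.ci95_c_out),
                "ci95_c_in": list(free_fit.ci95_c_in),
                "r_nonlinear": free_fit.r_nonlinear,
                "n_used": free_fit.n_used,
                "optimal": free_fit.optimal,
            },
            "fixed_c_out_1": {
                "c_in": fixed_fit.c_in,
                "ci95_c_in": list(fixed_fit.ci95_c_in),
                "r_nonlinear": fixed_fit.r_nonlinear,
                "n_used": fixed_fit.n_used,
            },
        },
        "calibration": {
            "intercept_a": calib.intercept_a,
            "slope_b": calib.slope_b,
            "r": calib.r,
            "r2": calib.r2,
            "press_r2": calib.press_r2,
            "rmse_alpha": calib.rmse,
            "inverse_intercept": calib.inverse_intercept,
            "inverse_slope": calib.inverse_slope,
            "cutoff_regression": calib.cutoff_at(config.pawp_threshold),
        },
        "bland_altman": {
            "bias_mmHg": ba.bias,
            "sd_diff_mmHg": ba.sd_diff,
            "loa_low_mmHg": ba.loa_low,
            "loa_high_mmHg": ba.loa_high,
        },
        "roc_elevated_pawp": _roc_dict(roc_all),
        "roc_postcapillary_in_ph": _roc_dict(roc_ph),
        "location_bias": location_bias,
        "location_correlations": location_corr,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(records, outdir / "cohort.csv")
        df.to_csv(outdir / "cohort_with_alpha.csv", index=False,
                  float_format="%.10g", lineterminator="\n")
        roc_points = pd.DataFrame(
            {
                "threshold": roc_all.thresholds,
                "sensitivity": roc_all.sensitivities,
                "specificity": roc_all.specificities,
            }
        )
        roc_points.to_csv(outdir / "roc_points.csv", index=False,
                          float_format="%.10g", lineterminator="\n")
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        with open(outdir / "run.log", "w", encoding="utf-8") as fh:
            fh.write("\n".join(log_lines) + "\n")
        if config.save_plots:
            from . import plots

            plots.save_all(outdir, df, calib, ba, roc_all)

    return report


def run_replicates(config: RunConfig) -> pd.DataFrame:
    """Repeat the core analysis over ``config.replicates`` derived
    seeds and tabulate the headline statistics per replicate."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.replicates):
        seed_i = int(rng.integers(0, 2**31 - 1))
        rep = run_pipeline(
            dataclasses.replace(
                config, seed=seed_i, outdir=None, replicates=1,
                waveform_roundtrip=False, save_plots=False,
            )
        )
        rows.append(
            {
                "replicate": i,
                "seed": seed_i,
                "r": rep["calibration"]["r"],
                "slope_b": rep["calibration"]["slope_b"],
                "intercept_a": rep["calibration"]["intercept_a"],
                "press_r2": rep["calibration"]["press_r2"],
                "cutoff_regression": rep["calibration"]["cutoff_regression"],
                "sd_diff_mmHg": rep["bland_altman"]["sd_diff_mmHg"],
                "auc": rep["roc_elevated_pawp"]["auc"],
                "sens_reg": rep["roc_elevated_pawp"]["cutoff_regression"]["sensitivity"],
                "spec_reg": rep["roc_elevated_pawp"]["cutoff_regression"]["specificity"],
                "auc_ph": rep["roc_postcapillary_in_ph"]["auc"],
                "mean_alpha": rep["alpha_summary"]["mean"],
                "c_out": rep["general_ratio_fit"]["free"]["c_out"],
                "c_in": rep["general_ratio_fit"]["free"]["c_in"],
            }
        )
    return pd.DataFrame(rows)
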