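"""Optional figures: calibration scatter, Bland-Altman and ROC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diagnostics import BlandAltman, RocResult
from .inference import CalibrationModel

__all__ = ["save_all"]

_GROUP_COLORS = {
    "non_PH": "tab:green",
    "pre_capillary_PH": "tab:blue",
    "post_capillary_PH": "tab:red",
}


def save_all(
    outdir,
    cohort: pd.DataFrame,
    calib: CalibrationModel,
    ba: BlandAltman,
    roc: RocResult,
) -> list[Path]:
    outdir = Path(outdir)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, color in _GROUP_COLORS.items():
        sub = cohort[cohort["group"] == g]
        ax.scatter(sub["pawp_mmHg"], sub["alpha"], s=18, color=color, label=g)
    xs = np.linspace(cohort["pawp_mmHg"].min(), cohort["pawp_mmHg"].max(), 50)
    ax.plot(xs, calib.predict_alpha(xs), "k-",
            label=f"alpha = {calib.intercept_a:.2f} + {calib.slope_b:.2f} PAWP")
    ax.set_xlabel("PAWP (mmHg)")
    ax.set_ylabel("LA acceleration factor")
    ax.legend(fontsize=7)
    p = outdir / "calibration.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    pawp = cohort["pawp_mmHg"].to_numpy()
    calc = calib.pawp_calc(cohort["alpha"].to_numpy())
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(0.5 * (pawp + calc), pawp - calc, s=18)
    for y, style in ((ba.bias, "k-"), (ba.loa_low, "k--"), (ba.loa_high, "k--")):
        ax.axhline(y, ls=style[1:], color="k")
    ax.set_xlabel("mean of PAWP and PAWP_calc (mmHg)")
    ax.set_ylabel("PAWP - PAWP_calc (mmHg)")
    p = outdir / "bland_altman.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    order = np.argsort(1 - roc.specificities)
    ax.plot((1 - roc.specificities)[order], roc.sensitivities[order], "-", drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.2f}")
    p = outdir / "roc.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
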