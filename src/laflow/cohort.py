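"""Synthetic cohort generation.

Generates patient cohorts whose statistical structure matches a
three-group study population of patients with known or suspected
pulmonary hypertension (PH): a non-PH group, a pre-capillary PH group
(mean pulmonary artery wedge pressure, PAWP, <= 15 mmHg) and a
post-capillary PH group (PAWP > 15 mmHg).  Each synthetic patient
carries a PAWP value, the four left-atrial (LA) peak velocities

* ``v_S``, ``v_D`` -- systolic / early-diastolic LA peak *inflow*
  velocities (pulmonary venous), and
* ``v_E``, ``v_A`` -- early / late-diastolic LA peak *outflow*
  velocities (transmitral),

plus alternative-location measurements (mitral-valve-tip and
intra-vein planes).  The generator plants a linear law on the LA
acceleration factor

    alpha = v_E / ((v_S + v_D)/2) = a + b * PAWP + eps,

so every downstream stage (peak extraction, ratio modelling,
calibration, diagnostics) has a known ground truth.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "GroupSpec",
    "AltLocationSpec",
    "CohortConfig",
    "CohortRecord",
    "CohortGenerationError",
    "generate_cohort",
    "cohort_to_dataframe",
    "write_cohort_csv",
    "read_cohort_csv",
]

GROUP_NAMES = ("non_PH", "pre_capillary_PH", "post_capillary_PH")

#: Pooled (all-patient) velocity means and SDs in cm/s, used to
#: standardise a junction velocity before drawing a correlated
#: alternative-location velocity.
POOLED_VELOCITY_STATS = {
    "v_s": (34.0, 13.0),
    "v_d": (33.0, 9.0),
    "v_e": (54.0, 19.0),
    "v_a": (39.0, 16.0),
}


class CohortGenerationError(RuntimeError):
    """Raised when rejection sampling cannot produce valid draws."""


@dataclass(frozen=True)
class GroupSpec:
    """Group-conditional distribution parameters.

    PAWP is drawn from a normal truncated to ``(pawp_lo, pawp_hi]``;
    velocities are group-conditional normals truncated to positive
    values.  Units: mmHg for pressures, cm/s for velocities.
    """

    name: str
    n: int
    pawp_mean: float
    pawp_sd: float
    pawp_lo: float
    pawp_hi: float
    v_s_mean: float
    v_s_sd: float
    v_d_mean: float
    v_d_sd: float
    v_a_mean: float
    v_a_sd: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for sd in (self.pawp_sd, self.v_s_sd, self.v_d_sd, self.v_a_sd):
            if sd <= 0:
                raise ValueError("standard deviations must be positive")
        if not self.pawp_lo < self.pawp_hi:
            raise ValueError("pawp_lo must be below pawp_hi")


@dataclass(frozen=True)
class AltLocationSpec:
    """Marginal mean/SD and correlation with the junction velocity for
    one alternative-location measurement (cm/s)."""

    base: str  # key into POOLED_VELOCITY_STATS
    mean: float
    sd: float
    r: float

    def __post_init__(self) -> None:
        if not -1.0 < self.r < 1.0:
            raise ValueError("|r| must be < 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def default_groups() -> tuple[GroupSpec, ...]:
    """The default three-group cohort: 28 non-PH, 21 pre-capillary PH
    and 13 post-capillary PH patients.

    PAWP: 8 +/- 4, 10 +/- 4 and 18 +/- 3 mmHg, truncated so that the
    post-capillary group (and only it) satisfies PAWP > 15 mmHg.
    Velocities use the group-conditional means/SDs of the study
    population (v_S falls with PAWP group; v_D and v_A are nearly
    flat).
    """
    return (
        GroupSpec("non_PH", 28, 8.0, 4.0, 0.0, 15.0, 39.0, 11.0, 33.0, 9.0, 38.0, 10.0),
        GroupSpec("pre_capillary_PH", 21, 10.0, 4.0, 0.0, 15.0, 32.0, 10.0, 33.0, 9.0, 39.0, 16.0),
        GroupSpec("post_capillary_PH", 13, 18.0, 3.0, 15.0, 28.0, 24.0, 14.0, 31.0, 9.0, 42.0, 27.0),
    )


def default_alt_specs() -> dict[str, AltLocationSpec]:
    """Alternative-location velocity calibration.

    Marginals and correlations with the corresponding junction
    velocity: v_S,vein 35 +/- 11 (r = 0.73), v_D,vein 34 +/- 10
    (r = 0.44), v_E,tip 60 +/- 19 (r = 0.88), v_A,tip 40 +/- 17
    (r = 0.81).  These jointly imply the observed location biases
    (e.g. v_E,tip - v_E = 6 +/- 9 cm/s).
    """
    return {
        "v_s_vein": AltLocationSpec("v_s", 35.0, 11.0, 0.73),
        "v_d_vein": AltLocationSpec("v_d", 34.0, 10.0, 0.44),
        "v_e_tip": AltLocationSpec("v_e", 60.0, 19.0, 0.88),
        "v_a_tip": AltLocationSpec("v_a", 40.0, 17.0, 0.81),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort.

    Defaults encode the study conditions: 62 patients (28/21/13), the
    linear law alpha = 0.61 + 0.10 * PAWP with residual SD 0.20 on the
    alpha scale (equivalently 2.0 mmHg on the PAWP scale), a v_S--v_D
    correlation of 0.38, a v_S--v_A correlation of 0.58, a monophasic
    transmitral-profile fraction of 6/62, and the left/right inferior
    pulmonary vein split 25:37.
    """

    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    alpha_intercept: float = 0.61
    alpha_slope: float = 0.10  # per mmHg
    alpha_noise_sd: float = 0.20
    monophasic_fraction: float = 6.0 / 62.0
    rho_vs_vd: float = 0.38
    rho_vs_va: float = 0.58
    p_left_vein: float = 25.0 / 62.0
    alt_specs: dict[str, AltLocationSpec] = field(default_factory=default_alt_specs)
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.alpha_slope <= 0:
            raise ValueError("alpha_slope must be positive")
        if self.alpha_noise_sd < 0:
            raise ValueError("alpha_noise_sd must be non-negative")
        if not 0.0 <= self.monophasic_fraction < 1.0:
            raise ValueError("monophasic_fraction must be in [0, 1)")
        for rho in (self.rho_vs_vd, self.rho_vs_va):
            if not -1.0 < rho < 1.0:
                raise ValueError("|rho| must be < 1")
        if not 0.0 <= self.p_left_vein <= 1.0:
            raise ValueError("p_left_vein must be in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CohortRecord:
    """One synthetic patient.

    ``v_a`` (and ``v_a_tip``) are ``None`` for patients with a
    monophasic transmitral outflow profile, in which case the late
    diastolic peak cannot be specified.
    """

    patient_id: str
    group: str
    pawp: float  # mmHg
    v_s: float  # cm/s
    v_d: float
    v_e: float
    v_a: float | None
    vein_used: str  # left_inferior / right_inferior
    v_s_vein: float
    v_d_vein: float
    v_e_tip: float
    v_a_tip: float | None

    @property
    def monophasic(self) -> bool:
        return self.v_a is None


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    """Exact truncated-normal draws by inverse-CDF of a uniform."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size)
    return mean + sd * ndtri(u)


def generate_cohort(config: CohortConfig) -> list[CohortRecord]:
    """Generate one cohort.  Deterministic given ``config.seed``.

    Per patient: PAWP from the group truncated normal; a latent
    alpha_true = intercept + slope * PAWP + eps with eps ~ N(0,
    alpha_noise_sd) redrawn until alpha_true > 0; (v_S, v_D) from a
    group-conditional bivariate normal with correlation ``rho_vs_vd``
    truncated to positive values; v_E = alpha_true * (v_S + v_D)/2;
    v_A sharing a latent factor with v_S (correlation ``rho_vs_va``)
    and marked missing for a Bernoulli(monophasic_fraction) subset;
    alternative-location velocities drawn conditionally on their
    junction counterparts with the configured marginals/correlations.
    """
    rng = np.random.default_rng(config.seed)
    mr = config.max_retries

    pawp_parts: list[np.ndarray] = []
    vs_parts: list[np.ndarray] = []
    vd_parts: list[np.ndarray] = []
    va_parts: list[np.ndarray] = []
    alpha_parts: list[np.ndarray] = []
    labels: list[str] = []

    for g in config.groups:
        n = g.n
        pawp = _truncated_normal(rng, g.pawp_mean, g.pawp_sd, g.pawp_lo, g.pawp_hi, n)

        alpha_mean = config.alpha_intercept + config.alpha_slope * pawp
        if config.alpha_noise_sd > 0:
            alpha_true = alpha_mean + rng.normal(0.0, config.alpha_noise_sd, n)
            # the acceleration factor is a ratio of positive velocities
            bad = alpha_true <= 0
            retries = 0
            while bad.any():
                if retries >= mr:
                    raise CohortGenerationError(
                        "could not draw a positive acceleration factor"
                    )
                alpha_true[bad] = alpha_mean[bad] + rng.normal(
                    0.0, config.alpha_noise_sd, int(bad.sum())
                )
                bad = alpha_true <= 0
                retries += 1
        else:
            alpha_true = alpha_mean.copy()
            if (alpha_true <= 0).any():
                raise CohortGenerationError("non-positive noise-free alpha")

        # correlated (v_S, v_D) pair; pairs with a non-positive member
        # are redrawn jointly
        rho = config.rho_vs_vd
        sq = np.sqrt(1.0 - rho * rho)

        def draw_pair(m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            z1 = rng.normal(size=m)
            z2 = rho * z1 + sq * rng.normal(size=m)
            return z1, g.v_s_mean + g.v_s_sd * z1, g.v_d_mean + g.v_d_sd * z2

        z_s, v_s, v_d = draw_pair(n)
        retries = 0
        while True:
            bad = (v_s <= 0) | (v_d <= 0)
            if not bad.any():
                break
            if retries >= mr:
                raise CohortGenerationError("could not draw positive (v_S, v_D)")
            zb, sb, db = draw_pair(int(bad.sum()))
            z_s[bad], v_s[bad], v_d[bad] = zb, sb, db
            retries += 1

        # v_A shares a latent factor with v_S
        rho_a = config.rho_vs_va
        sq_a = np.sqrt(1.0 - rho_a * rho_a)
        v_a = g.v_a_mean + g.v_a_sd * (rho_a * z_s + sq_a * rng.normal(size=n))
        retries = 0
        while True:
            bad = v_a <= 0
            if not bad.any():
                break
            if retries >= mr:
                raise CohortGenerationError("could not draw positive v_A")
            v_a[bad] = g.v_a_mean + g.v_a_sd * (
                rho_a * z_s[bad] + sq_a * rng.normal(size=int(bad.sum()))
            )
            retries += 1

        pawp_parts.append(pawp)
        vs_parts.append(v_s)
        vd_parts.append(v_d)
        va_parts.append(v_a)
        alpha_parts.append(alpha_true)
        labels.extend([g.name] * n)

    pawp = np.concatenate(pawp_parts)
    v_s = np.concatenate(vs_parts)
    v_d = np.concatenate(vd_parts)
    v_a = np.concatenate(va_parts)
    alpha_true = np.concatenate(alpha_parts)
    v_e = alpha_true * 0.5 * (v_s + v_d)
    n_total = pawp.size

    monophasic = rng.uniform(size=n_total) < config.monophasic_fraction
    vein_left = rng.uniform(size=n_total) < config.p_left_vein

    base_values = {"v_s": v_s, "v_d": v_d, "v_e": v_e, "v_a": v_a}
    alt_values: dict[str, np.ndarray] = {}
    for key, spec in config.alt_specs.items():
        mu_b, sd_b = POOLED_VELOCITY_STATS[spec.base]
        z = (base_values[spec.base] - mu_b) / sd_b
        sq_r = np.sqrt(1.0 - spec.r * spec.r)
        alt = spec.mean + spec.sd * (spec.r * z + sq_r * rng.normal(size=n_total))
        retries = 0
        while True:
            bad = alt <= 0
            if not bad.any():
                break
            if retries >= mr:
                raise CohortGenerationError(f"could not draw positive {key}")
            alt[bad] = spec.mean + spec.sd * (
                spec.r * z[bad] + sq_r * rng.normal(size=int(bad.sum()))
            )
            retries += 1
        alt_values[key] = alt

    records: list[CohortRecord] = []
    width = len(str(n_total))
    for i in range(n_total):
        records.append(
            CohortRecord(
                patient_id=f"P{i + 1:0{width}d}",
                group=labels[i],
                pawp=float(pawp[i]),
                v_s=float(v_s[i]),
                v_d=float(v_d[i]),
                v_e=float(v_e[i]),
                v_a=None if monophasic[i] else float(v_a[i]),
                vein_used="left_inferior" if vein_left[i] else "right_inferior",
                v_s_vein=float(alt_values["v_s_vein"][i]),
                v_d_vein=float(alt_values["v_d_vein"][i]),
                v_e_tip=float(alt_values["v_e_tip"][i]),
                v_a_tip=None if monophasic[i] else float(alt_values["v_a_tip"][i]),
            )
        )
    return records


_CSV_COLUMNS = [
    "patient_id",
    "group",
    "pawp_mmHg",
    "vS",
    "vD",
    "vE",
    "vA",
    "vein_used",
    "vS_vein",
    "vD_vein",
    "vE_tip",
    "vA_tip",
]


def cohort_to_dataframe(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """One row per patient; missing v_A / v_A,tip become NaN."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "group": r.group,
                "pawp_mmHg": r.pawp,
                "vS": r.v_s,
                "vD": r.v_d,
                "vE": r.v_e,
                "vA": np.nan if r.v_a is None else r.v_a,
                "vein_used": r.vein_used,
                "vS_vein": r.v_s_vein,
                "vD_vein": r.v_d_vein,
                "vE_tip": r.v_e_tip,
                "vA_tip": np.nan if r.v_a_tip is None else r.v_a_tip,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_cohort_csv(records: Sequence[CohortRecord], path) -> None:
    """UTF-8, '.' decimal, fixed column order, missing values empty."""
    df = cohort_to_dataframe(records)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g", lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    return df[_CSV_COLUMNS]
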