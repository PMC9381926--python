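"""The LA acceleration factor and its general-ratio family.

The LA acceleration factor is the dimensionless ratio of the early
diastolic LA peak outflow velocity to the average of the systolic and
early diastolic LA peak inflow velocities,

    alpha = v_E / ((v_S + v_D)/2).

It is a member of the general family of ratios of linear combinations
of outflow peaks to linear combinations of inflow peaks, which (up to
an overall multiplicative constant) can be written as

    alpha_general = (v_{E+A} + c_out * v_{E-A}) / (v_{S+D} + c_in * v_{S-D}),

with v_{E+A} = (v_E + v_A)/2, v_{E-A} = (v_E - v_A)/2, v_{S+D} =
(v_S + v_D)/2 and v_{S-D} = (v_S - v_D)/2.  The choices c_out = 1 and
c_in = 0 recover alpha; c_out = c_in = 1 recovers v_E / v_S.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VelocityQuad",
    "RatioConstants",
    "alpha",
    "alpha_from_arrays",
    "alpha_general",
    "alpha_general_from_arrays",
    "alpha_variants",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VelocityQuad:
    """The four LA peak velocities of one patient (cm/s).

    ``v_a`` is optional: patients with a monophasic transmitral
    profile have no late diastolic outflow peak.  The half-sum /
    half-difference combinations are derived on access and never
    stored.
    """

    v_e: float
    v_s: float
    v_d: float
    v_a: float | None = None

    def __post_init__(self) -> None:
        for name in ("v_e", "v_s", "v_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_a is not None and self.v_a <= 0:
            raise ValueError("v_a must be positive when present")

    @property
    def v_e_plus_a(self) -> float:
        self._require_va()
        return 0.5 * (self.v_e + self.v_a)

    @property
    def v_e_minus_a(self) -> float:
        self._require_va()
        return 0.5 * (self.v_e - self.v_a)

    @property
    def v_s_plus_d(self) -> float:
        return 0.5 * (self.v_s + self.v_d)

    @property
    def v_s_minus_d(self) -> float:
        return 0.5 * (self.v_s - self.v_d)

    def _require_va(self) -> None:
        if self.v_a is None:
            raise ValueError("v_a is missing (monophasic transmitral profile)")


@dataclass(frozen=True)
class RatioConstants:
    """Constants (c_out, c_in) selecting a member of the general
    ratio family."""

    c_out: float
    c_in: float


def alpha(q: VelocityQuad) -> float:
    """LA acceleration factor alpha = v_E / ((v_S + v_D)/2).

    Does not require v_A, so it is defined for monophasic patients.
    """
    denom = q.v_s_plus_d
    if denom <= 0:
        raise ValueError("mean inflow velocity must be positive")
    return q.v_e / denom


def alpha_from_arrays(v_e, v_s, v_d) -> np.ndarray:
    """Vectorised alpha; propagates NaN."""
    v_e = np.asarray(v_e, dtype=float)
    denom = 0.5 * (np.asarray(v_s, dtype=float) + np.asarray(v_d, dtype=float))
    with np.errstate(invalid="ignore"):
        if np.any(denom[np.isfinite(denom)] <= 0):
            raise ValueError("mean inflow velocity must be positive")
    return v_e / denom


def alpha_general(q: VelocityQuad, c: RatioConstants) -> float:
    """General outflow/inflow velocity ratio.

    Requires v_A.  Satisfies alpha_general(q, (1, 0)) == alpha(q) and
    alpha_general(q, (1, 1)) == v_E / v_S exactly.  The denominator
    v_{S+D} + c_in * v_{S-D} must be positive (negative v_{S-D}, i.e.
    v_D > v_S, is allowed).
    """
    num = q.v_e_plus_a + c.c_out * q.v_e_minus_a
    den = q.v_s_plus_d + c.c_in * q.v_s_minus_d
    if den <= 0:
        raise ValueError("non-positive denominator in alpha_general")
    return num / den


def alpha_general_from_arrays(v_e, v_a, v_s, v_d, c_out, c_in) -> np.ndarray:
    """Vectorised alpha_general; rows with NaN v_A yield NaN."""
    v_e = np.asarray(v_e, dtype=float)
    v_a = np.asarray(v_a, dtype=float)
    v_s = np.asarray(v_s, dtype=float)
    v_d = np.asarray(v_d, dtype=float)
    num = 0.5 * (v_e + v_a) + c_out * 0.5 * (v_e - v_a)
    den = 0.5 * (v_s + v_d) + c_in * 0.5 * (v_s - v_d)
    with np.errstate(invalid="ignore"):
        if np.any(den[np.isfinite(den)] <= 0):
            raise ValueError("non-positive denominator in alpha_general")
    return num / den


def alpha_variants(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient acceleration factors at all measurement locations.

    * ``alpha``          -- junction velocities (v_E; v_S, v_D)
    * ``alpha_tip``      -- v_E,tip with junction inflow velocities
    * ``alpha_vein``     -- v_E with intra-vein inflow velocities
    * ``alpha_tip_vein`` -- v_E,tip with intra-vein inflow velocities

    Rows lacking a required component velocity get NaN for that
    variant and are logged.
    """
    out = pd.DataFrame({"patient_id": cohort["patient_id"]})
    combos = {
        "alpha": ("vE", "vS", "vD"),
        "alpha_tip": ("vE_tip", "vS", "vD"),
        "alpha_vein": ("vE", "vS_vein", "vD_vein"),
        "alpha_tip_vein": ("vE_tip", "vS_vein", "vD_vein"),
    }
    for name, (e_col, s_col, d_col) in combos.items():
        vals = alpha_from_arrays(cohort[e_col], cohort[s_col], cohort[d_col])
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            ids = cohort.loc[np.isnan(vals), "patient_id"].tolist()
            logger.info("%s undefined for %d patients: %s", name, n_missing, ids)
        out[name] = vals
    return out
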