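"""Maximal-velocity-time waveforms over one cardiac cycle.

A patient's transmitral (LA outflow) and pulmonary-venous (LA inflow)
maximal-velocity-time curves are modelled as sums of raised-cosine
bumps on a zero baseline: the venous curve carries a systolic (S) and
an early diastolic (D) bump, the transmitral curve an early (E) and --
for biphasic profiles -- a late (A) diastolic bump.  Bump heights
equal the patient's peak velocities, so downstream peak detection has
a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRecord

__all__ = [
    "VelocityCurve",
    "WaveformConfig",
    "WaveformError",
    "generate_waveforms",
    "raised_cosine_bump",
    "waveforms_to_dataframe",
    "write_waveforms_csv",
    "read_waveforms_csv",
]

CURVE_LOCATIONS = (
    "mitral_junction",
    "mitral_tips",
    "vein_orifice_left",
    "vein_orifice_right",
    "vein_interior",
)


class WaveformError(ValueError):
    """Raised for inconsistent waveform configurations."""


@dataclass(frozen=True)
class VelocityCurve:
    """A maximal-velocity-time series at one measurement location.

    Times are milliseconds from the R-wave, strictly increasing within
    one RR interval; velocities are non-negative maximal 3D speeds in
    cm/s.
    """

    location: str
    times_ms: np.ndarray
    values: np.ndarray
    rr_interval_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size:
            raise WaveformError("times and values must have equal length")
        if t.size < 10:
            raise WaveformError("a velocity curve needs at least 10 samples")
        if np.any(np.diff(t) <= 0):
            raise WaveformError("times must be strictly increasing")
        if np.any(v < 0):
            raise WaveformError("maximal speeds cannot be negative")

    @property
    def phase_fractions(self) -> np.ndarray:
        """Sample times as fractions of the RR interval."""
        return self.times_ms / self.rr_interval_ms

    @property
    def n_samples(self) -> int:
        return int(self.times_ms.size)


@dataclass(frozen=True)
class WaveformConfig:
    """Waveform shape parameters.

    Peak times and half-widths are fractions of the RR interval; the
    defaults (S at 0.20, D and E at 0.55, A at 0.85, half-width 0.10)
    respect the physiological ordering S -> D/E -> A and fall on
    sample points of the default 20-phase grid, so that peak detection
    inverts waveform generation exactly at zero noise.
    """

    n_phases: int = 20
    rr_interval_ms: float = 800.0
    t_s: float = 0.20
    t_d: float = 0.55
    t_e: float = 0.55
    t_a: float = 0.85
    w_s: float = 0.10
    w_d: float = 0.10
    w_e: float = 0.10
    w_a: float = 0.10
    noise_sd: float = 0.0  # cm/s, additive on sampled curves
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_phases < 10:
            raise WaveformError("need at least 10 cardiac phases")
        if not (0.0 < self.t_s < self.t_d <= self.t_e < self.t_a < 1.0):
            raise WaveformError("peak times must satisfy 0 < t_S < t_D <= t_E < t_A < 1")
        for w in (self.w_s, self.w_d, self.w_e, self.w_a):
            if w <= 0:
                raise WaveformError("bump half-widths must be positive")
        if self.noise_sd < 0:
            raise WaveformError("noise_sd must be non-negative")

    @property
    def phase_times_ms(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.rr_interval_ms / self.n_phases


def raised_cosine_bump(t, t0: float, half_width: float, height: float):
    """height/2 * (1 + cos(pi (t - t0)/w)) for |t - t0| <= w, else 0.

    ``t`` in fractions of the RR interval.  The bump attains its
    maximum ``height`` exactly at ``t0``.
    """
    t = np.asarray(t, dtype=float)
    x = (t - t0) / half_width
    out = np.where(np.abs(x) <= 1.0, 0.5 * height * (1.0 + np.cos(np.pi * x)), 0.0)
    return out


def _check_bumps(bumps: Sequence[tuple[float, float, float]], what: str) -> None:
    """Bumps must stay inside (0, 1) and must not overlap, otherwise
    planted maxima would not be attained."""
    for t0, w, _h in bumps:
        if t0 - w < 0.0 or t0 + w > 1.0:
            raise WaveformError(
                f"{what}: bump at {t0} with half-width {w} leaves the RR interval"
            )
    ordered = sorted(bumps)
    for (t0a, wa, _), (t0b, wb, _) in zip(ordered, ordered[1:]):
        if t0b - t0a < wa + wb:
            raise WaveformError(
                f"{what}: bumps at {t0a} and {t0b} overlap; planted peaks "
                "would not be attained"
            )


def _sample_curve(
    bumps: Sequence[tuple[float, float, float]],
    wconfig: WaveformConfig,
    rng: np.random.Generator | None,
) -> np.ndarray:
    frac = np.arange(wconfig.n_phases) / wconfig.n_phases
    v = np.zeros(wconfig.n_phases)
    for t0, w, h in bumps:
        v += raised_cosine_bump(frac, t0, w, h)
    if wconfig.noise_sd > 0:
        if rng is None:
            raise WaveformError("noise_sd > 0 requires a seed")
        v = np.maximum(v + rng.normal(0.0, wconfig.noise_sd, v.size), 0.0)
    return v


def generate_waveforms(
    record: CohortRecord, wconfig: WaveformConfig = WaveformConfig()
) -> tuple[VelocityCurve, VelocityCurve]:
    """Build (transmitral, venous) curves for one patient.

    The transmitral curve carries an E bump of height ``v_e`` and --
    unless the record is monophasic -- an A bump of height ``v_a``;
    the venous curve carries S and D bumps of heights ``v_s`` and
    ``v_d``.
    """
    rng = None if wconfig.seed is None else np.random.default_rng(wconfig.seed)

    tm_bumps = [(wconfig.t_e, wconfig.w_e, record.v_e)]
    if record.v_a is not None:
        tm_bumps.append((wconfig.t_a, wconfig.w_a, record.v_a))
    _check_bumps(tm_bumps, "transmitral")

    ven_bumps = [
        (wconfig.t_s, wconfig.w_s, record.v_s),
        (wconfig.t_d, wconfig.w_d, record.v_d),
    ]
    _check_bumps(ven_bumps, "venous")

    times = wconfig.phase_times_ms
    transmitral = VelocityCurve(
        "mitral_junction", times, _sample_curve(tm_bumps, wconfig, rng),
        wconfig.rr_interval_ms,
    )
    vein_loc = (
        "vein_orifice_left" if record.vein_used == "left_inferior" else "vein_orifice_right"
    )
    venous = VelocityCurve(
        vein_loc, times, _sample_curve(ven_bumps, wconfig, rng),
        wconfig.rr_interval_ms,
    )
    return transmitral, venous


def waveforms_to_dataframe(
    patient_id: str, curves: Sequence[VelocityCurve]
) -> pd.DataFrame:
    rows = []
    for curve in curves:
        kind = "transmitral" if curve.location.startswith("mitral") else "venous"
        for k, (t, v) in enumerate(zip(curve.times_ms, curve.values)):
            rows.append(
                {
                    "patient_id": patient_id,
                    "location": kind,
                    "phase_index": k,
                    "time_ms": float(t),
                    "vmax_cm_s": float(v),
                }
            )
    return pd.DataFrame(rows)


def write_waveforms_csv(frames: Sequence[pd.DataFrame], path) -> None:
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n"
    )


def read_waveforms_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "location", "phase_index", "time_ms", "vmax_cm_s"}
    if not required <= set(df.columns):
        raise ValueError(f"waveform CSV lacks columns: {sorted(required - set(df.columns))}")
    return df
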