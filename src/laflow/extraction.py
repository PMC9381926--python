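"""Peak-velocity extraction from maximal-velocity-time curves.

Turns a velocity-time curve (or a toy 4D field) into the four LA peak
velocities: the systolic (v_S) and early diastolic (v_D) inflow peaks
of a pulmonary-venous curve, and the early (v_E) and late (v_A)
diastolic outflow peaks of a transmitral curve.  Peaks are assigned by
phase windows expressed as fractions of the RR interval; the late
diastolic outflow peak v_A additionally requires a distinct local
maximum (prominence rule) -- a curve without one is a monophasic
transmitral profile and v_A is reported missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .fields import Flow4DToy
from .waveforms import VelocityCurve

__all__ = [
    "PhaseWindows",
    "PeakSet",
    "ExtractionError",
    "extract_max_speed_curve",
    "detect_outflow_peaks",
    "detect_inflow_peaks",
    "select_vein",
    "peaksets_to_dataframe",
]

OUTFLOW_LOCATIONS = ("mitral_junction", "mitral_tips")
INFLOW_LOCATIONS = ("vein_orifice_left", "vein_orifice_right", "vein_interior")

#: Default prominence of a late diastolic peak relative to the curve
#: maximum below which the transmitral profile is called monophasic.
DEFAULT_PROMINENCE_FRACTION = 0.10


class ExtractionError(ValueError):
    """Raised for invalid curves, windows or planes."""


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open phase windows [lo, hi) in fractions of the RR
    interval from the R-wave.

    Systole hosts v_S, early diastole v_E and v_D, late diastole v_A;
    defaults follow the physiological ordering S -> D/E -> A.
    """

    systole: tuple[float, float] = (0.0, 0.40)
    early_diastole: tuple[float, float] = (0.40, 0.75)
    late_diastole: tuple[float, float] = (0.75, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.systole, self.early_diastole, self.late_diastole):
            if not (0.0 <= lo < hi <= 1.0):
                raise ExtractionError("phase windows must satisfy 0 <= lo < hi <= 1")


@dataclass(frozen=True)
class PeakSet:
    """Extracted peak velocities (cm/s) with their phase indices.

    Outflow curves populate ``v_e`` (and ``v_a`` when biphasic);
    inflow curves populate ``v_s`` and ``v_d``.  ``curve_max`` is the
    overall curve maximum, used for vein selection.
    """

    location: str
    curve_max: float
    v_e: float | None = None
    v_a: float | None = None
    v_s: float | None = None
    v_d: float | None = None
    phase_e: int | None = None
    phase_a: int | None = None
    phase_s: int | None = None
    phase_d: int | None = None


def _window_mask(frac: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (frac >= lo) & (frac < hi)


def _window_argmax(values: np.ndarray, mask: np.ndarray, what: str) -> int:
    """Index of the window maximum; ties broken toward the earliest
    sample (np.argmax returns the first maximal entry)."""
    if not mask.any():
        raise ExtractionError(f"empty {what} window for this curve")
    idx = np.flatnonzero(mask)
    return int(idx[np.argmax(values[idx])])


def detect_outflow_peaks(
    curve: VelocityCurve,
    windows: PhaseWindows = PhaseWindows(),
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> PeakSet:
    """Early (v_E) and, if biphasic, late (v_A) diastolic outflow peaks.

    v_E is the maximum over the early diastolic window.  v_A requires
    a local maximum inside the late diastolic window with prominence
    of at least ``prominence_fraction`` of the curve maximum;
    otherwise the profile is monophasic and v_A is None.
    """
    if curve.location not in OUTFLOW_LOCATIONS:
        raise ExtractionError(
            f"outflow peaks require a transmitral curve, got {curve.location!r}"
        )
    frac = curve.phase_fractions
    v = curve.values
    i_e = _window_argmax(v, _window_mask(frac, windows.early_diastole), "early-diastolic")

    curve_max = float(v.max())
    peak_idx, _ = find_peaks(v, prominence=prominence_fraction * curve_max)
    late = peak_idx[_window_mask(frac[peak_idx], windows.late_diastole)]
    if late.size:
        # highest local peak; earliest wins on exact ties
        best = late[np.argmax(v[late])]
        v_a, phase_a = float(v[best]), int(best)
    else:
        v_a, phase_a = None, None

    return PeakSet(
        location=curve.location,
        curve_max=curve_max,
        v_e=float(v[i_e]),
        v_a=v_a,
        phase_e=i_e,
        phase_a=phase_a,
    )


def detect_inflow_peaks(
    curve: VelocityCurve, windows: PhaseWindows = PhaseWindows()
) -> PeakSet:
    """Systolic (v_S) and early diastolic (v_D) inflow peaks, as
    window maxima of a pulmonary-venous curve."""
    if curve.location not in INFLOW_LOCATIONS:
        raise ExtractionError(
            f"inflow peaks require a venous curve, got {curve.location!r}"
        )
    frac = curve.phase_fractions
    v = curve.values
    i_s = _window_argmax(v, _window_mask(frac, windows.systole), "systolic")
    i_d = _window_argmax(v, _window_mask(frac, windows.early_diastole), "early-diastolic")
    return PeakSet(
        location=curve.location,
        curve_max=float(v.max()),
        v_s=float(v[i_s]),
        v_d=float(v[i_d]),
        phase_s=i_s,
        phase_d=i_d,
    )


def select_vein(left: PeakSet, right: PeakSet) -> PeakSet:
    """Choose the pulmonary vein exhibiting higher velocities.

    The comparison uses the overall curve maximum; exact ties go to
    the right vein.
    """
    return left if left.curve_max > right.curve_max else right


def extract_max_speed_curve(field: Flow4DToy, plane_id: str) -> VelocityCurve:
    """Per-phase maximal Euclidean speed over the voxels of one
    measurement plane (within its in-plane region of interest)."""
    if plane_id not in field.planes:
        raise ExtractionError(f"unknown plane {plane_id!r}")
    plane = field.planes[plane_id]
    nx, ny, nz, n_ph, _ = field.velocity.shape
    if len(plane.z_indices) != n_ph:
        raise ExtractionError("plane must be defined for every phase")

    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    roi = (x - plane.center_xy[0]) ** 2 + (y - plane.center_xy[1]) ** 2 <= (
        plane.roi_radius_vox**2
    )
    values = np.empty(n_ph)
    for k, z in enumerate(plane.z_indices):
        if not 0 <= z < nz:
            raise ExtractionError("plane z-index outside the grid")
        speed = np.linalg.norm(field.velocity[:, :, z, k, :], axis=-1)
        values[k] = speed[roi].max()

    location = {
        "mitral_junction": "mitral_junction",
        "mitral_tips": "mitral_tips",
        "vein_left": "vein_orifice_left",
        "vein_right": "vein_orifice_right",
        "vein_interior": "vein_interior",
    }.get(plane_id, "vein_interior")
    times = np.arange(n_ph) * field.phase_duration_ms
    return VelocityCurve(location, times, values, field.phase_duration_ms * n_ph)


def peaksets_to_dataframe(
    rows: Sequence[tuple[str, PeakSet]]
) -> pd.DataFrame:
    """PeakSet CSV layout: patient_id, location, vE, vA, vS, vD and
    phase indices."""
    out = []
    for patient_id, ps in rows:
        out.append(
            {
                "patient_id": patient_id,
                "location": ps.location,
                "vE": np.nan if ps.v_e is None else ps.v_e,
                "vA": np.nan if ps.v_a is None else ps.v_a,
                "vS": np.nan if ps.v_s is None else ps.v_s,
                "vD": np.nan if ps.v_d is None else ps.v_d,
                "phase_E": -1 if ps.phase_e is None else ps.phase_e,
                "phase_A": -1 if ps.phase_a is None else ps.phase_a,
                "phase_S": -1 if ps.phase_s is None else ps.phase_s,
                "phase_D": -1 if ps.phase_d is None else ps.phase_d,
            }
        )
    return pd.DataFrame(out)
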