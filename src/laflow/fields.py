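"""Toy 4D velocity fields with planted jets.

A minimal stand-in for a time-resolved, three-directionally
velocity-encoded phase-contrast acquisition of the left atrium:
Gaussian-profile jets cross three measurement planes (the
atrio-ventricular junction and the two inferior pulmonary-vein
orifices), and the per-phase maximal speed within each plane equals
the corresponding sample of the patient's velocity waveform.  Planes
may translate across phases, mirroring time-varying plane tracking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortRecord
from .waveforms import VelocityCurve, WaveformConfig, generate_waveforms

__all__ = [
    "PlaneDefinition",
    "Flow4DToy",
    "FieldError",
    "FieldConfig",
    "generate_flow_field",
    "save_flow_field",
    "load_flow_field",
]


class FieldError(ValueError):
    """Raised for invalid field geometry or aliasing velocities."""


@dataclass(frozen=True)
class PlaneDefinition:
    """An axis-aligned measurement plane, one voxel thick along z.

    ``z_indices`` gives the plane's z position per cardiac phase
    (time-varying planes); ``center_xy`` the in-plane jet-tracking
    centre; ``roi_radius_vox`` the in-plane region of interest within
    which the maximal speed is read.
    """

    plane_id: str
    z_indices: tuple[int, ...]
    center_xy: tuple[float, float]
    roi_radius_vox: float


@dataclass
class Flow4DToy:
    """A (nx, ny, nz, n_phases, 3) velocity array in cm/s with
    acquisition-style metadata."""

    velocity: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    phase_duration_ms: float
    venc_cm_s: float
    planes: dict[str, PlaneDefinition]

    def __post_init__(self) -> None:
        v = np.asarray(self.velocity, dtype=float)
        if v.ndim != 5 or v.shape[-1] != 3:
            raise FieldError("velocity must have shape (x, y, z, phase, 3)")
        if not np.all(np.isfinite(v)):
            raise FieldError("velocity field contains non-finite values")
        speed = np.linalg.norm(v, axis=-1)
        if np.any(speed > self.venc_cm_s * (1 + 1e-9)):
            raise FieldError("speeds exceed the velocity-encoding (VENC) bound")
        self.velocity = v

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[3]

    @property
    def sidecar(self) -> dict:
        return {
            "units": "cm/s",
            "venc_cm_s": self.venc_cm_s,
            "phase_duration_ms": self.phase_duration_ms,
            "voxel_size_mm": list(self.voxel_size_mm),
            "plane_definitions": {
                pid: {
                    "z_indices": list(p.z_indices),
                    "center_xy": list(p.center_xy),
                    "roi_radius_vox": p.roi_radius_vox,
                }
                for pid, p in self.planes.items()
            },
        }


@dataclass(frozen=True)
class FieldConfig:
    """Geometry of the toy acquisition.

    Default VENC 90 cm/s; with ``adapt_venc`` the encoding bound is
    raised to the fastest planted jet, mirroring per-scan VENC
    adaptation used to avoid aliasing near the mitral valve.
    ``offside_vein_scale`` sets the jet amplitude in the pulmonary
    vein that was *not* selected for analysis, as a fraction of the
    selected vein's waveform.
    """

    grid: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (2.4, 1.8, 6.0)
    jet_sigma_vox: float = 1.2
    venc_cm_s: float = 90.0
    adapt_venc: bool = True
    mitral_z: int = 3
    vein_z: int = 8
    mitral_center: tuple[float, float] = (12.0, 12.0)
    left_vein_center: tuple[float, float] = (6.0, 12.0)
    right_vein_center: tuple[float, float] = (18.0, 12.0)
    roi_radius_vox: float = 5.0
    offside_vein_scale: float = 0.85
    plane_motion: bool = True


def _add_jet(
    speed_slab: np.ndarray,
    center: tuple[float, float],
    amplitude: float,
    sigma: float,
    nx: int,
    ny: int,
) -> None:
    """Accumulate a Gaussian in-plane speed profile peaking exactly at
    the centre voxel (centres are voxel centres, so the in-plane
    maximum equals ``amplitude``)."""
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    speed_slab += amplitude * np.exp(-r2 / (2.0 * sigma**2))


def generate_flow_field(
    record: CohortRecord,
    wconfig: WaveformConfig = WaveformConfig(),
    fconfig: FieldConfig = FieldConfig(),
) -> Flow4DToy:
    """Plant jets realising the patient's waveforms on a voxel grid.

    The mitral jet points in -z (LA outflow), the vein jets in +z
    (LA inflow); per phase, the maximal speed over each plane's ROI
    equals the corresponding waveform sample.
    """
    nx, ny, nz = fconfig.grid
    n_ph = wconfig.n_phases
    transmitral, venous = generate_waveforms(record, wconfig)

    if fconfig.plane_motion:
        # mitral plane drifts one voxel toward the apex in diastole
        mitral_z = tuple(
            fconfig.mitral_z + (1 if k >= n_ph // 2 else 0) for k in range(n_ph)
        )
    else:
        mitral_z = (fconfig.mitral_z,) * n_ph
    vein_z = (fconfig.vein_z,) * n_ph
    if max(mitral_z) >= nz or fconfig.vein_z >= nz:
        raise FieldError("plane z-index outside the grid")
    min_sep = np.hypot(
        fconfig.right_vein_center[0] - fconfig.left_vein_center[0],
        fconfig.right_vein_center[1] - fconfig.left_vein_center[1],
    )
    if min_sep < 2 * fconfig.roi_radius_vox:
        raise FieldError("vein regions of interest overlap")

    used_left = record.vein_used == "left_inferior"
    amp_scale = {
        "vein_left": 1.0 if used_left else fconfig.offside_vein_scale,
        "vein_right": fconfig.offside_vein_scale if used_left else 1.0,
    }

    peak = float(
        max(transmitral.values.max(initial=0.0), venous.values.max(initial=0.0))
    )
    venc = fconfig.venc_cm_s
    if peak > venc:
        if fconfig.adapt_venc:
            venc = float(np.ceil(peak / 10.0) * 10.0)
        else:
            raise FieldError(
                f"planted jet speed {peak:.1f} cm/s exceeds VENC {venc:.0f} cm/s"
            )

    vel = np.zeros((nx, ny, nz, n_ph, 3))
    for k in range(n_ph):
        mitral_speed = np.zeros((nx, ny))
        _add_jet(
            mitral_speed, fconfig.mitral_center, float(transmitral.values[k]),
            fconfig.jet_sigma_vox, nx, ny,
        )
        vel[:, :, mitral_z[k], k, 2] -= mitral_speed

        vein_speed = np.zeros((nx, ny))
        _add_jet(
            vein_speed, fconfig.left_vein_center,
            amp_scale["vein_left"] * float(venous.values[k]),
            fconfig.jet_sigma_vox, nx, ny,
        )
        _add_jet(
            vein_speed, fconfig.right_vein_center,
            amp_scale["vein_right"] * float(venous.values[k]),
            fconfig.jet_sigma_vox, nx, ny,
        )
        vel[:, :, vein_z[0], k, 2] += vein_speed

    planes = {
        "mitral_junction": PlaneDefinition(
            "mitral_junction", mitral_z, fconfig.mitral_center, fconfig.roi_radius_vox
        ),
        "vein_left": PlaneDefinition(
            "vein_left", vein_z, fconfig.left_vein_center, fconfig.roi_radius_vox
        ),
        "vein_right": PlaneDefinition(
            "vein_right", vein_z, fconfig.right_vein_center, fconfig.roi_radius_vox
        ),
    }
    return Flow4DToy(
        velocity=vel,
        voxel_size_mm=fconfig.voxel_size_mm,
        phase_duration_ms=wconfig.rr_interval_ms / n_ph,
        venc_cm_s=venc,
        planes=planes,
    )


def save_flow_field(toy: Flow4DToy, nifti_path, sidecar_path) -> None:
    """NIfTI array container plus JSON sidecar."""
    import nibabel as nib

    affine = np.diag(list(toy.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(toy.velocity.astype(np.float32), affine)
    nib.save(img, str(nifti_path))
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(toy.sidecar, fh, indent=2, sort_keys=True)


def load_flow_field(nifti_path, sidecar_path) -> Flow4DToy:
    import nibabel as nib

    img = nib.load(str(nifti_path))
    with open(sidecar_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    planes = {
        pid: PlaneDefinition(
            pid,
            tuple(int(z) for z in p["z_indices"]),
            tuple(float(c) for c in p["center_xy"]),
            float(p["roi_radius_vox"]),
        )
        for pid, p in meta["plane_definitions"].items()
    }
    return Flow4DToy(
        velocity=np.asarray(img.dataobj, dtype=float),
        voxel_size_mm=tuple(float(s) for s in meta["voxel_size_mm"]),
        phase_duration_ms=float(meta["phase_duration_ms"]),
        venc_cm_s=float(meta["venc_cm_s"]),
        planes=planes,
    )
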