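"""File formats and run configuration.

Conventions, stated once and enforced everywhere:

* angles are stored in **degrees** in files and converted to radians
  internally; times are seconds;
* detector positions in files are **pixels** (0-based, pixel centers at
  index + 0.5); lengths in configs are centimeters;
* a projection stack on disk is a multi-page TIFF plus CSV sidecars sharing
  the stem: ``<stem>_meta.csv`` (frame, time_s, theta_deg),
  ``<stem>_geometry.yaml`` and optionally ``<stem>_truth.csv``;
* tracks, traces and shift maps are CSV; fits and reports are JSON;
  volumes are NIfTI (mm units).

The run configuration is schema-validated (unknown keys rejected) and the
seed is mandatory: every stochastic stage draws from it, so two runs with
identical config are bit-identical in every output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .geometry import PatientPoint, ScanGeometry
from .synthetic import (
    DEFAULT_BACKGROUND,
    DEFAULT_CONTRAST,
    DEFAULT_NOISE_SIGMA,
    MarkerSpec,
    MotionWaveform,
    ProjectionStack,
)

__all__ = [
    "read_stack",
    "write_stack",
    "write_volume",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# projection stacks


def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_name(path.stem + suffix)


def write_stack(stack: ProjectionStack, path) -> Path:
    """Write a stack as multi-page TIFF + metadata/geometry/truth sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    stack.meta[["frame", "time_s", "theta_deg"]].to_csv(_sidecar(path, "_meta.csv"), index=False)
    stack.geom.to_yaml(_sidecar(path, "_geometry.yaml"))
    if stack.truth is not None:
        stack.truth.to_csv(_sidecar(path, "_truth.csv"), index=False)
    return path


def read_stack(path) -> ProjectionStack:
    """Read a stack written by :func:`write_stack`; lossless round trip.

    Raises if the TIFF page count disagrees with the metadata row count
    (the error names the first frame without metadata) or if the time
    column is not strictly increasing.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = pd.read_csv(_sidecar(path, "_meta.csv"))
    if len(meta) != len(frames):
        bad = min(len(meta), len(frames))
        raise ValueError(
            f"{len(frames)} TIFF pages but {len(meta)} metadata rows "
            f"(first unmatched frame: {bad})"
        )
    t = meta["time_s"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("metadata time_s column is not strictly increasing")
    geom_path = _sidecar(path, "_geometry.yaml")
    if geom_path.exists():
        geom = ScanGeometry.from_yaml(geom_path)
    else:  # minimal geometry from the frames + metadata alone
        geom = ScanGeometry(
            det_cols=frames.shape[2],
            det_rows=frames.shape[1],
            schedule=meta[["frame", "time_s", "theta_deg"]],
        )
    truth_path = _sidecar(path, "_truth.csv")
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return ProjectionStack(frames=frames, meta=meta, geom=geom, truth=truth)


def write_volume(volume, path) -> Path:
    """Write a reconstructed volume as NIfTI; spacing in mm, origin at center."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vox_mm = volume.voxel_cm * 10.0
    affine = np.diag([vox_mm, vox_mm, vox_mm, 1.0])
    for a in range(3):
        affine[a, 3] = -(volume.data.shape[a] - 1) / 2.0 * vox_mm
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))
    return path


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# run configuration (schema-validated YAML)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    preset: Literal["clinical", "reduced"] = "reduced"
    sad_cm: Optional[float] = None
    sid_cm: Optional[float] = None
    det_cols: Optional[int] = None
    det_rows: Optional[int] = None
    det_width_cm: Optional[float] = None
    det_height_cm: Optional[float] = None
    n_frames: Optional[int] = None
    duration_s: Optional[float] = None
    scan_mode: Literal["full_fan", "half_fan"] = "full_fan"

    def build(self) -> ScanGeometry:
        base = (
            ScanGeometry.clinical(self.n_frames or 650, self.duration_s or 60.0)
            if self.preset == "clinical"
            else ScanGeometry.reduced(self.n_frames or 360, self.duration_s or 60.0)
        )
        over = {
            k: getattr(self, k)
            for k in ("sad_cm", "sid_cm", "det_cols", "det_rows", "det_width_cm", "det_height_cm")
            if getattr(self, k) is not None
        }
        return ScanGeometry(
            schedule=base.schedule,
            scan_mode=self.scan_mode,
            **{
                "sad_cm": base.sad_cm,
                "sid_cm": base.sid_cm,
                "det_cols": base.det_cols,
                "det_rows": base.det_rows,
                "det_width_cm": base.det_width_cm,
                "det_height_cm": base.det_height_cm,
                **over,
            },
        )


class WaveformConfig(_Strict):
    ax_cm: float = 0.0
    ay_cm: float = 0.0
    az_cm: float = 0.0
    fx: float = 0.0
    fy: float = 0.0
    fz: float = 0.0
    freq_unit: Literal["hz", "cpm"] = "cpm"
    dx_rad: float = 0.0
    dy_rad: float = 0.0
    dz_rad: float = 0.0

    def build(self) -> MotionWaveform:
        s = 1.0 / 60.0 if self.freq_unit == "cpm" else 1.0
        return MotionWaveform(
            ax_cm=self.ax_cm,
            ay_cm=self.ay_cm,
            az_cm=self.az_cm,
            fx_hz=self.fx * s,
            fy_hz=self.fy * s,
            fz_hz=self.fz * s,
            dx_rad=self.dx_rad,
            dy_rad=self.dy_rad,
            dz_rad=self.dz_rad,
        )


class MarkerConfig(_Strict):
    id: str = "m0"
    label: Literal["internal", "external"] = "internal"
    # rest position: either Cartesian cm or spherical (cm, degrees)
    x_cm: Optional[float] = None
    y_cm: Optional[float] = None
    z_cm: Optional[float] = None
    r_cm: Optional[float] = None
    alpha_deg: Optional[float] = None
    beta_deg: Optional[float] = None
    diameter_mm: float = 1.0
    length_mm: float = 2.0
    contrast: float = DEFAULT_CONTRAST
    waveform: WaveformConfig = WaveformConfig()

    @model_validator(mode="after")
    def _one_position(self):
        cart = all(v is not None for v in (self.x_cm, self.y_cm, self.z_cm))
        sph = all(v is not None for v in (self.r_cm, self.alpha_deg, self.beta_deg))
        if cart == sph:
            raise ValueError(
                f"marker {self.id}: give exactly one of (x_cm,y_cm,z_cm) or "
                f"(r_cm,alpha_deg,beta_deg)"
            )
        return self

    def build(self) -> MarkerSpec:
        if self.x_cm is not None:
            rest = PatientPoint(self.x_cm, self.y_cm, self.z_cm)
        else:
            rest = PatientPoint.from_spherical(
                self.r_cm, np.deg2rad(self.alpha_deg), np.deg2rad(self.beta_deg)
            )
        return MarkerSpec(
            rest=rest,
            diameter_mm=self.diameter_mm,
            length_mm=self.length_mm,
            contrast=self.contrast,
            waveform=self.waveform.build(),
            label=self.label,
            marker_id=self.id,
        )


class NoiseConfig(_Strict):
    background: float = DEFAULT_BACKGROUND
    sigma: float = DEFAULT_NOISE_SIGMA


class TrackingConfig(_Strict):
    score_threshold: float = 0.5
    search_halfwidth_px: Optional[int] = None
    outlier_window: int = 11
    outlier_n_mad: float = 5.0
    max_gap_s: float = 5.0
    roi_halfsize_px: int = 8


class FitConfig(_Strict):
    blind_deg: float = 3.0


class ReconConfig(_Strict):
    size: int = 64
    voxel_cm: float = 0.2


class RunConfig(_Strict):
    """Top-level run description: all stages, one mandatory seed."""

    seed: int
    geometry: GeometryConfig = GeometryConfig()
    markers: List[MarkerConfig] = []
    noise: NoiseConfig = NoiseConfig()
    tracking: TrackingConfig = TrackingConfig()
    fit: FitConfig = FitConfig()
    recon: ReconConfig = ReconConfig()
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def build_markers(self) -> List[MarkerSpec]:
        return [m.build() for m in self.markers]
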