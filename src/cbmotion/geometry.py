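"""Cone-beam projection geometry.

A kV on-board imager rotates a point X-ray source and a flat-panel detector
around the patient.  The patient frame is fixed: Z is the superior-inferior
axis, X-Y the transverse plane, origin at the isocenter.  At gantry angle
``theta`` the source sits at ``S(theta) = SAD * (sin(theta), cos(theta), 0)``
and the detector plane lies perpendicular to the central ray at distance SID
from the source.  Detector coordinates (j, k) are continuous centimeters with
origin on the central ray (the ray through isocenter): j is the in-plane
(transverse) axis, k the axial (superior-inferior) axis.

For a point at cylindrical radius ``rho = sqrt(x^2 + y^2)``, polar angle
``alpha = atan2(x, y)`` and height ``z``, the pinhole projection is::

    d = SAD - rho * cos(alpha - theta)      # depth along the central ray
    j = SID * rho * sin(alpha - theta) / d
    k = SID * z / d

so a point at the isocenter maps to (0, 0) in every view, a point displaced
purely along Z maps to a constant k = SID*z/SAD, and an in-plane point traces
a sinogram in j over the rotation.  The scaling factor ``c = SAD/SID``
demagnifies detector lengths to the isocenter plane.

Angles are radians internally; schedules and files carry degrees.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeometryError",
    "ScanGeometry",
    "PatientPoint",
    "DetectorCoord",
    "SinogramTrack",
    "project_point",
    "stationary_track",
    "isocenter_pixel_pitch",
    "px_to_cm",
    "cm_to_px",
]


class GeometryError(ValueError):
    """Invalid geometry or a point outside the projectable domain."""


def _default_schedule(n_frames: int, duration_s: float, arc_deg: float) -> pd.DataFrame:
    i = np.arange(n_frames)
    return pd.DataFrame(
        {
            "frame": i,
            "time_s": duration_s * i / n_frames,
            "theta_deg": arc_deg * i / n_frames,
        }
    )


@dataclass
class ScanGeometry:
    """Scanner geometry plus the (frame, time, angle) acquisition schedule.

    Parameters
    ----------
    sad_cm, sid_cm:
        Source-to-isocenter and source-to-imager distances.  Clinical OBI
        defaults are 100 cm and 150 cm.
    det_width_cm, det_height_cm, det_cols, det_rows:
        Physical panel size and pixel matrix; the full panel is ~40x30 cm
        at 1024x768 px.
    schedule:
        DataFrame with columns ``frame, time_s, theta_deg``; times strictly
        increasing.
    scan_mode:
        ``"full_fan"`` or ``"half_fan"`` (metadata only).
    """

    sad_cm: float = 100.0
    sid_cm: float = 150.0
    det_width_cm: float = 40.0
    det_height_cm: float = 30.0
    det_cols: int = 1024
    det_rows: int = 768
    schedule: pd.DataFrame = field(default_factory=lambda: _default_schedule(650, 60.0, 360.0))
    scan_mode: str = "full_fan"

    def __post_init__(self) -> None:
        if not (self.sid_cm > self.sad_cm > 0):
            raise GeometryError(f"need SID > SAD > 0, got SAD={self.sad_cm}, SID={self.sid_cm}")
        if self.det_cols <= 0 or self.det_rows <= 0:
            raise GeometryError("detector pixel counts must be positive")
        if self.det_width_cm <= 0 or self.det_height_cm <= 0:
            raise GeometryError("detector physical size must be positive")
        if self.scan_mode not in ("full_fan", "half_fan"):
            raise GeometryError(f"unknown scan_mode {self.scan_mode!r}")
        sched = pd.DataFrame(self.schedule)
        missing = {"frame", "time_s", "theta_deg"} - set(sched.columns)
        if missing:
            raise GeometryError(f"schedule missing columns {sorted(missing)}")
        t = sched["time_s"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise GeometryError("schedule times must be strictly increasing")
        self.schedule = sched.reset_index(drop=True)

    # -- derived quantities -------------------------------------------------
    @property
    def c(self) -> float:
        """Scaling factor SAD/SID in (0, 1): detector -> isocenter demagnification."""
        return self.sad_cm / self.sid_cm

    @property
    def pitch_j_cm(self) -> float:
        return self.det_width_cm / self.det_cols

    @property
    def pitch_k_cm(self) -> float:
        return self.det_height_cm / self.det_rows

    @property
    def n_frames(self) -> int:
        return len(self.schedule)

    @property
    def theta_rad(self) -> np.ndarray:
        return np.deg2rad(self.schedule["theta_deg"].to_numpy(float))

    @property
    def times_s(self) -> np.ndarray:
        return self.schedule["time_s"].to_numpy(float)

    # -- constructors -------------------------------------------------------
    @classmethod
    def clinical(cls, n_frames: int = 650, duration_s: float = 60.0) -> "ScanGeometry":
        """Full clinical acquisition: 1024x768 panel, ~650 views over 360 deg/60 s."""
        return cls(schedule=_default_schedule(n_frames, duration_s, 360.0))

    @classmethod
    def reduced(cls, n_frames: int = 360, duration_s: float = 60.0) -> "ScanGeometry":
        """Reduced test geometry: 256x192 panel (same physical size), 360 views."""
        return cls(
            det_cols=256,
            det_rows=192,
            schedule=_default_schedule(n_frames, duration_s, 360.0),
        )

    def with_schedule_from_csv(self, path) -> "ScanGeometry":
        sched = pd.read_csv(path)[["frame", "time_s", "theta_deg"]]
        return ScanGeometry(
            sad_cm=self.sad_cm,
            sid_cm=self.sid_cm,
            det_width_cm=self.det_width_cm,
            det_height_cm=self.det_height_cm,
            det_cols=self.det_cols,
            det_rows=self.det_rows,
            schedule=sched,
            scan_mode=self.scan_mode,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sad_cm": self.sad_cm,
            "sid_cm": self.sid_cm,
            "det_width_cm": self.det_width_cm,
            "det_height_cm": self.det_height_cm,
            "det_cols": self.det_cols,
            "det_rows": self.det_rows,
            "scan_mode": self.scan_mode,
            "schedule": {
                "frame": self.schedule["frame"].astype(int).tolist(),
                "time_s": self.schedule["time_s"].astype(float).tolist(),
                "theta_deg": self.schedule["theta_deg"].astype(float).tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        d = dict(d)
        sched = d.pop("schedule", None)
        if sched is not None:
            d["schedule"] = pd.DataFrame(sched)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScanGeometry":
        if isinstance(path, _io.IOBase):
            return cls.from_dict(yaml.safe_load(path))
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class PatientPoint:
    """A point in the fixed patient frame, lengths in cm (Z = superior-inferior)."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0

    @property
    def rho(self) -> float:
        """Transverse (X-Y plane) distance from the rotation axis."""
        return float(np.hypot(self.x, self.y))

    @property
    def r(self) -> float:
        return float(np.sqrt(self.x**2 + self.y**2 + self.z**2))

    @property
    def alpha(self) -> float:
        """In-plane polar angle, atan2(x, y): measured from +Y toward +X, radians."""
        return float(np.arctan2(self.x, self.y))

    @property
    def beta(self) -> float:
        """Angle between the position vector and the +Z axis, in [0, pi]."""
        if self.r == 0.0:
            return 0.0
        return float(np.arctan2(self.rho, self.z))

    @classmethod
    def from_spherical(cls, r: float, alpha: float, beta: float) -> "PatientPoint":
        """Build from (r, alpha, beta) in cm/radians; beta measured from +Z."""
        rho = r * np.sin(beta)
        return cls(x=rho * np.sin(alpha), y=rho * np.cos(alpha), z=r * np.cos(beta))


@dataclass(frozen=True)
class DetectorCoord:
    """Continuous detector coordinates in cm, origin on the central ray."""

    j: float
    k: float


@dataclass
class SinogramTrack:
    """Predicted detector trace of one stationary patient point over a schedule."""

    theta_deg: np.ndarray
    j_cm: np.ndarray
    k_cm: np.ndarray
    in_fov: np.ndarray  # bool per frame


# ---------------------------------------------------------------------------


def _project_arrays(rho, alpha, z, theta_rad, geom: ScanGeometry):
    """Vectorized pinhole projection; returns (j_cm, k_cm, depth d)."""
    psi = np.asarray(alpha) - np.asarray(theta_rad)
    d = geom.sad_cm - np.asarray(rho) * np.cos(psi)
    j = geom.sid_cm * np.asarray(rho) * np.sin(psi) / d
    k = geom.sid_cm * np.asarray(z) / d
    return j, k, d


def project_point(p: PatientPoint, theta: float, geom: ScanGeometry) -> DetectorCoord:
    """Project a patient point onto the detector at gantry angle ``theta`` (radians).

    Raises :class:`GeometryError` if the point lies at or behind the source
    plane (depth d = SAD - rho*cos(alpha-theta) <= 0).
    """
    j, k, d = _project_arrays(p.rho, p.alpha, p.z, theta, geom)
    if np.any(d <= 0):
        raise GeometryError(f"point {p} at or behind the source plane at theta={theta}")
    return DetectorCoord(float(j), float(k))


def stationary_track(p: PatientPoint, geom: ScanGeometry) -> SinogramTrack:
    """Detector trace of a stationary point over the full acquisition schedule.

    Frames whose projection falls outside the physical panel are marked
    ``in_fov=False`` (this is what makes markers invisible in roughly half
    of the views of a half-fan scan of a lateral marker).
    """
    theta = geom.theta_rad
    j, k, d = _project_arrays(p.rho, p.alpha, p.z, theta, geom)
    if np.any(d <= 0):
        raise GeometryError(f"point {p} at or behind the source plane for some view")
    in_fov = (np.abs(j) <= geom.det_width_cm / 2) & (np.abs(k) <= geom.det_height_cm / 2)
    return SinogramTrack(
        theta_deg=geom.schedule["theta_deg"].to_numpy(float),
        j_cm=j,
        k_cm=k,
        in_fov=in_fov,
    )


def isocenter_pixel_pitch(geom: ScanGeometry) -> float:
    """Detector pixel pitch demagnified to the isocenter plane, in mm.

    With the clinical 40 cm / 1024 px panel at SAD 100 / SID 150 this is
    0.26 mm, so a 0.5 px localization error corresponds to 0.13 mm of
    motion at the isocenter.
    """
    return geom.pitch_j_cm * geom.c * 10.0


def px_to_cm(j_px, k_px, geom: ScanGeometry):
    """Pixel indices (0-based, pixel centers at index+0.5) -> detector cm."""
    j_cm = (np.asarray(j_px, float) + 0.5) * geom.pitch_j_cm - geom.det_width_cm / 2
    k_cm = (np.asarray(k_px, float) + 0.5) * geom.pitch_k_cm - geom.det_height_cm / 2
    return j_cm, k_cm


def cm_to_px(coord, geom: ScanGeometry, k_cm=None):
    """Detector cm -> pixel indices; inverse of :func:`px_to_cm`.

    Accepts either a :class:`DetectorCoord` or two arrays ``(j_cm, k_cm)``.
    """
    if isinstance(coord, DetectorCoord):
        j_cm, k_cm = coord.j, coord.k
    else:
        j_cm = coord
    j_px = (np.asarray(j_cm, float) + geom.det_width_cm / 2) / geom.pitch_j_cm - 0.5
    k_px = (np.asarray(k_cm, float) + geom.det_height_cm / 2) / geom.pitch_k_cm - 0.5
    return j_px, k_px
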