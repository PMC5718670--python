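"""Synthetic cone-beam acquisitions of moving seed-marker phantoms.

Emulates a kV on-board imager scanning a phantom that carries small
radio-opaque seed markers (nominally 1 mm diameter x 2 mm length) driven by a
programmable motion platform.  The reference protocol moves the phantom
sinusoidally along the superior-inferior axis at 15 cycles/min with 1.75 cm
amplitude — roughly the period and excursion of free breathing.

Markers are rendered as dark anisotropic Gaussian blobs (attenuators) on a
uniform bright background with optional additive Gaussian noise, rather than
ray-traced cylinders: the tracking stages only need a compact high-contrast
shadow whose centroid sits exactly at the pinhole projection of the marker
center, and the ground-truth table stores those projections to float
precision for every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import PatientPoint, ScanGeometry, _project_arrays, cm_to_px

__all__ = [
    "MotionWaveform",
    "MarkerSpec",
    "ProjectionStack",
    "waveform_displacement",
    "render_projection",
    "generate_scan",
]

# Rendering defaults (16-bit counts).
DEFAULT_BACKGROUND = 3000.0
DEFAULT_CONTRAST = 1200.0
DEFAULT_NOISE_SIGMA = 50.0


@dataclass
class MotionWaveform:
    """Per-axis sinusoidal displacement d_a(t) = A_a * sin(2*pi*f_a*t - delta_a).

    Amplitudes in cm, frequencies stored in Hz (use ``from_cycles_per_min``
    for the breathing-rate convention), phases in radians.  ``drift_cm_s``
    adds a linear baseline drift per axis; ``dropout_windows`` lists
    (t_start, t_end) intervals during which the oscillation is suppressed
    (a crude model of breath-hold / irregular breathing).
    """

    ax_cm: float = 0.0
    ay_cm: float = 0.0
    az_cm: float = 0.0
    fx_hz: float = 0.0
    fy_hz: float = 0.0
    fz_hz: float = 0.0
    dx_rad: float = 0.0
    dy_rad: float = 0.0
    dz_rad: float = 0.0
    drift_cm_s: tuple = (0.0, 0.0, 0.0)
    dropout_windows: Sequence[tuple] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for a in (self.ax_cm, self.ay_cm, self.az_cm):
            if a < 0:
                raise ValueError("amplitudes must be >= 0")
        for f in (self.fx_hz, self.fy_hz, self.fz_hz):
            if f < 0:
                raise ValueError("frequencies must be >= 0")

    @classmethod
    def from_cycles_per_min(
        cls,
        ax_cm: float = 0.0,
        ay_cm: float = 0.0,
        az_cm: float = 0.0,
        fx_cpm: float = 0.0,
        fy_cpm: float = 0.0,
        fz_cpm: float = 0.0,
        dx_rad: float = 0.0,
        dy_rad: float = 0.0,
        dz_rad: float = 0.0,
        **kw,
    ) -> "MotionWaveform":
        """Frequencies given in cycles per minute (breathing-rate convention)."""
        return cls(
            ax_cm=ax_cm,
            ay_cm=ay_cm,
            az_cm=az_cm,
            fx_hz=fx_cpm / 60.0,
            fy_hz=fy_cpm / 60.0,
            fz_hz=fz_cpm / 60.0,
            dx_rad=dx_rad,
            dy_rad=dy_rad,
            dz_rad=dz_rad,
            **kw,
        )

    def displacement(self, t):
        """Displacement (dx, dy, dz) in cm at time(s) ``t`` (seconds)."""
        t = np.asarray(t, float)
        gate = np.ones_like(t)
        for t0, t1 in self.dropout_windows:
            gate = np.where((t >= t0) & (t < t1), 0.0, gate)
        out = []
        for a, f, d, dr in (
            (self.ax_cm, self.fx_hz, self.dx_rad, self.drift_cm_s[0]),
            (self.ay_cm, self.fy_hz, self.dy_rad, self.drift_cm_s[1]),
            (self.az_cm, self.fz_hz, self.dz_rad, self.drift_cm_s[2]),
        ):
            out.append(gate * a * np.sin(2 * np.pi * f * t - d) + dr * t)
        return tuple(out)


def waveform_displacement(w: MotionWaveform, t):
    """Functional alias for :meth:`MotionWaveform.displacement`."""
    return w.displacement(t)


@dataclass
class MarkerSpec:
    """A seed marker: rest position, physical size, contrast and motion.

    ``contrast`` is the attenuation depth of the rendered shadow relative to
    the background, in detector counts.  ``label`` distinguishes implanted
    (internal) from skin-attached (external) markers.
    """

    rest: PatientPoint
    diameter_mm: float = 1.0
    length_mm: float = 2.0
    contrast: float = DEFAULT_CONTRAST
    waveform: MotionWaveform = field(default_factory=MotionWaveform)
    label: str = "internal"
    marker_id: str = "m0"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.length_mm <= 0:
            raise ValueError("marker size must be positive")
        if self.label not in ("internal", "external"):
            raise ValueError("label must be 'internal' or 'external'")

    def position(self, t) -> PatientPoint:
        dx, dy, dz = self.waveform.displacement(t)
        return PatientPoint(self.rest.x + float(dx), self.rest.y + float(dy), self.rest.z + float(dz))


@dataclass
class ProjectionStack:
    """An ordered stack of 2D projection frames with per-frame metadata.

    ``frames`` has shape (n_frames, det_rows, det_cols), dtype uint16; row
    index is the detector k axis, column index the j axis.  ``truth`` is an
    optional ground-truth table of exact marker detector positions
    (columns: frame, marker_id, time_s, theta_deg, j_px, k_px, in_fov).
    """

    frames: np.ndarray
    meta: pd.DataFrame  # frame, time_s, theta_deg
    geom: ScanGeometry
    truth: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if len(self.frames) != len(self.meta):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.meta)} metadata rows"
            )
        t = self.meta["time_s"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("metadata times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return self.frames.shape


def _render_markers(
    frame: np.ndarray,
    markers: Sequence[MarkerSpec],
    t: float,
    theta: float,
    geom: ScanGeometry,
) -> None:
    """Subtract each marker's Gaussian shadow from ``frame`` in place (float)."""
    rows, cols = frame.shape
    kk, jj = np.arange(rows), np.arange(cols)
    for m in markers:
        p = m.position(t)
        j_cm, k_cm, d = _project_arrays(p.rho, p.alpha, p.z, theta, geom)
        if d <= 0:
            continue
        mag = geom.sid_cm / float(d)
        j_px, k_px = cm_to_px(float(j_cm), geom, float(k_cm))
        if not (-1 <= j_px <= cols and -1 <= k_px <= rows):
            continue  # outside the panel: marker simply absent in this view
        # sigma from physical footprint (diameter across j, length along k),
        # magnified to the detector; floor keeps the blob trackable (>=2x2 px).
        sig_j = max(0.5 * m.diameter_mm * mag / (geom.pitch_j_cm * 10.0), 1.0)
        sig_k = max(0.5 * m.length_mm * mag / (geom.pitch_k_cm * 10.0), 1.0)
        gj = np.exp(-0.5 * ((jj - j_px) / sig_j) ** 2)
        gk = np.exp(-0.5 * ((kk - k_px) / sig_k) ** 2)
        frame -= m.contrast * np.outer(gk, gj)


def render_projection(
    markers: Sequence[MarkerSpec],
    t: float,
    theta: float,
    geom: ScanGeometry,
    background: float = DEFAULT_BACKGROUND,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one projection frame at time ``t`` and gantry angle ``theta`` (rad).

    Returns a uint16 frame: uniform ``background`` minus the marker shadows,
    plus additive Gaussian noise of standard deviation ``noise_sigma`` (pass
    0 for a noise-free frame; ``rng`` is required when noise_sigma > 0).
    """
    frame = np.full((geom.det_rows, geom.det_cols), float(background))
    _render_markers(frame, markers, t, theta, geom)
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sigma > 0")
        frame = frame + rng.normal(0.0, noise_sigma, size=frame.shape)
    return np.clip(np.rint(frame), 0, 65535).astype(np.uint16)


def generate_scan(
    markers: Sequence[MarkerSpec],
    geom: ScanGeometry,
    background: float = DEFAULT_BACKGROUND,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> ProjectionStack:
    """Simulate a full scan of the phantom over the geometry's schedule.

    Deterministic for a given ``seed``.  The returned stack carries a
    ground-truth table with the exact projected detector position of every
    marker in every frame (float pixels) and an ``in_fov`` flag.
    """
    rng = np.random.default_rng(seed)
    times = geom.times_s
    thetas = geom.theta_rad
    frames = np.empty((geom.n_frames, geom.det_rows, geom.det_cols), dtype=np.uint16)
    truth_rows = []
    for i, (t, th) in enumerate(zip(times, thetas)):
        frames[i] = render_projection(
            markers, t, th, geom, background=background, noise_sigma=noise_sigma, rng=rng
        )
        for m in markers:
            p = m.position(t)
            j_cm, k_cm, d = _project_arrays(p.rho, p.alpha, p.z, th, geom)
            j_px, k_px = cm_to_px(float(j_cm), geom, float(k_cm))
            in_fov = bool(
                d > 0
                and abs(j_cm) <= geom.det_width_cm / 2
                and abs(k_cm) <= geom.det_height_cm / 2
            )
            truth_rows.append(
                {
                    "frame": i,
                    "marker_id": m.marker_id,
                    "time_s": t,
                    "theta_deg": float(geom.schedule["theta_deg"].iloc[i]),
                    "j_px": float(j_px),
                    "k_px": float(k_px),
                    "in_fov": in_fov,
                }
            )
    return ProjectionStack(
        frames=frames,
        meta=geom.schedule[["frame", "time_s", "theta_deg"]].copy(),
        geom=geom,
        truth=pd.DataFrame(truth_rows),
        provenance={"seed": seed, "background": background, "noise_sigma": noise_sigma},
    )
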