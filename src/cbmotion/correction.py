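"""Projection-domain motion correction.

Every pixel of each projection frame is shifted by the tracked marker's
detector-frame motion offsets (u, v) = (dj, dk), mapping the frame onto the
marker's stationary position: I'(js, ks, theta) = I(jm - u, km - v, theta).
The whole frame moves rigidly — the body region around the marker is assumed
to move with it — so the correction is a pure per-frame 2D translation with
bilinear resampling and edge padding.  Corrected stacks feed the FDK
reconstruction unchanged in format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .synthetic import ProjectionStack

__all__ = ["ShiftMap", "shiftmap_from_residuals", "remap_projection", "correct_stack"]


@dataclass
class ShiftMap:
    """Per-frame detector shifts (u, v) in pixels, one row per stack frame.

    ``data`` columns: frame, u_px, v_px, filled (True where the shift was
    interpolated in time rather than measured).
    """

    data: pd.DataFrame
    marker_id: str = "m0"

    def __post_init__(self) -> None:
        missing = {"frame", "u_px", "v_px", "filled"} - set(self.data.columns)
        if missing:
            raise ValueError(f"shift map missing columns {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, marker_id: str = "m0") -> "ShiftMap":
        return cls(pd.read_csv(path), marker_id=marker_id)


def shiftmap_from_residuals(
    residuals: pd.DataFrame, schedule: pd.DataFrame, marker_id: str = "m0"
) -> ShiftMap:
    """Build a full-schedule shift map from measured detector residuals.

    ``residuals`` (columns frame, time_s, dj_px, dk_px — the output of
    :func:`cbmotion.motion.detector_residuals`) must cover at least half of
    the schedule's frames.  Frames without a measurement are filled by
    linear interpolation in time, with the endpoint values held beyond the
    measured support, and flagged ``filled``.
    """
    n = len(schedule)
    if len(residuals) < n / 2:
        raise ValueError(
            f"residuals cover {len(residuals)} of {n} frames (< half): refusing to extrapolate"
        )
    t_all = schedule["time_s"].to_numpy(float)
    have = np.isin(schedule["frame"].to_numpy(), residuals["frame"].to_numpy())
    t_m = residuals["time_s"].to_numpy(float)
    u = np.interp(t_all, t_m, residuals["dj_px"].to_numpy(float))
    v = np.interp(t_all, t_m, residuals["dk_px"].to_numpy(float))
    return ShiftMap(
        pd.DataFrame(
            {
                "frame": schedule["frame"].to_numpy(int),
                "u_px": u,
                "v_px": v,
                "filled": ~have,
            }
        ),
        marker_id=marker_id,
    )


def remap_projection(frame: np.ndarray, u: float, v: float) -> np.ndarray:
    """Shift a frame by (-u, -v) pixels: output(j, k) = input(j + u, k + v).

    Bilinear resampling with edge padding; an integer (u, v) is an exact
    pixel shift.  u moves along columns (j), v along rows (k).
    """
    if not (np.isfinite(u) and np.isfinite(v)):
        raise ValueError(f"non-finite shift ({u}, {v})")
    rows, cols = frame.shape
    if abs(u) > cols or abs(v) > rows:
        raise ValueError(f"shift ({u}, {v}) exceeds frame size {frame.shape}")
    if u == 0 and v == 0:
        return frame.copy()
    rr, cc = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
    out = map_coordinates(
        np.asarray(frame, float), [rr + v, cc + u], order=1, mode="nearest"
    )
    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(frame.dtype)


def correct_stack(stack: ProjectionStack, shiftmap: ShiftMap) -> ProjectionStack:
    """Apply a shift map framewise; metadata are preserved, provenance recorded."""
    if len(shiftmap.data) != stack.n_frames:
        raise ValueError(
            f"shift map has {len(shiftmap.data)} rows for a {stack.n_frames}-frame stack"
        )
    if not np.array_equal(
        shiftmap.data["frame"].to_numpy(int), stack.meta["frame"].to_numpy(int)
    ):
        raise ValueError("shift map frame indices do not match the stack")
    frames = np.empty_like(stack.frames)
    u = shiftmap.data["u_px"].to_numpy(float)
    v = shiftmap.data["v_px"].to_numpy(float)
    for i in range(stack.n_frames):
        frames[i] = remap_projection(stack.frames[i], u[i], v[i])
    prov = dict(stack.provenance)
    prov["motion_corrected_with"] = shiftmap.marker_id
    return ProjectionStack(
        frames=frames,
        meta=stack.meta.copy(),
        geom=stack.geom,
        truth=stack.truth,
        provenance=prov,
    )
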