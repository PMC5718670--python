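"""Marker localization in projection frames by normalized cross-correlation.

A template patch of the marker shadow is cut from one projection (a
user-drawn ROI); every frame is then searched for the position of maximum
zero-normalized cross-correlation (ZNCC) with the template.  The integer
peak is refined to subpixel precision by fitting a 1D quadratic to the 3x3
score neighborhood along each axis.  A localization precision of about
+-0.5 px is expected — about +-0.13 mm at the isocenter for the clinical
panel — and the subpixel refinement typically does considerably better on
clean marker shadows.

Two robustness passes clean the raw track: a moving-median/MAD rule flags
frames where the correlator locked onto a look-alike shadow (outliers), and
piecewise-cubic interpolation fills interior gaps where the marker was
missing or rejected (e.g. views where a lateral marker leaves the half-fan
field of view).  Leading and trailing gaps are never extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from skimage.feature import match_template

__all__ = [
    "Template",
    "MarkerTrack",
    "TrackParams",
    "MatchResult",
    "extract_template",
    "ncc_match",
    "track_stack",
    "flag_outliers",
    "interpolate_gaps",
]

STATUS_DETECTED = "detected"
STATUS_OUTLIER = "outlier"
STATUS_INTERPOLATED = "interpolated"
STATUS_MISSING = "missing"

TRACK_COLUMNS = ["frame", "time_s", "theta_deg", "jm_px", "km_px", "score", "status"]


@dataclass
class Template:
    """A mean-subtracted marker patch with odd dimensions.

    ``centroid_offset`` is the (row, col) offset of the marker's intensity
    centroid from the patch's geometric center: an ROI is cut on the integer
    pixel grid, so the marker's subpixel position inside it is generally not
    the patch center, and matched positions are reported relative to the
    marker centroid rather than the ROI center.
    """

    patch: np.ndarray
    source_frame: int
    center: Tuple[float, float]  # (row, col) of the ROI center in the source frame
    centroid_offset: Tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self):
        return self.patch.shape


@dataclass
class MarkerTrack:
    """Per-frame marker detector positions with status flags.

    Wraps a DataFrame with columns
    ``frame, time_s, theta_deg, jm_px, km_px, score, status``;
    ``status`` is one of detected / outlier / interpolated / missing, and
    positions are NaN for missing frames.
    """

    data: pd.DataFrame
    marker_id: str = "m0"

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"track missing columns {sorted(missing)}")
        f = self.data["frame"].to_numpy()
        if len(f) and (len(np.unique(f)) != len(f) or np.any(np.diff(f) <= 0)):
            raise ValueError("track frames must be unique and increasing")
        self.data = self.data.reset_index(drop=True)

    def mask(self, *statuses: str) -> np.ndarray:
        return self.data["status"].isin(statuses).to_numpy()

    @property
    def detected(self) -> np.ndarray:
        return self.mask(STATUS_DETECTED)

    @property
    def usable(self) -> np.ndarray:
        """Frames that carry a position estimate (detected or interpolated)."""
        return self.mask(STATUS_DETECTED, STATUS_INTERPOLATED)

    def copy(self) -> "MarkerTrack":
        return MarkerTrack(self.data.copy(), marker_id=self.marker_id)

    def to_csv(self, path) -> None:
        self.data[TRACK_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, marker_id: str = "m0") -> "MarkerTrack":
        return cls(pd.read_csv(path), marker_id=marker_id)


@dataclass
class TrackParams:
    """Tunables for :func:`track_stack` and the cleanup passes."""

    search_halfwidth_px: Optional[int] = None  # default: 2x the template extent
    score_threshold: float = 0.5
    seed_position: Optional[Tuple[float, float]] = None  # (j_px, k_px) for frame 0
    # window short relative to a breathing period (~24 frames at 15 cycles/min
    # and 6 fps) so the median can follow the motion extrema
    outlier_window: int = 5
    outlier_n_mad: float = 5.0
    max_gap_s: float = 5.0


@dataclass
class MatchResult:
    j_px: float
    k_px: float
    score: float
    on_border: bool = False


def extract_template(stack, frame: int, roi: Tuple[int, int, int, int]) -> Template:
    """Cut a template from ``stack`` frame ``frame`` at ROI (row0, row1, col0, col1).

    The patch is mean-subtracted and trimmed to odd dimensions (so it has an
    unambiguous center pixel).  A flat ROI (no intensity variance) is
    rejected: ZNCC is undefined there.
    """
    img = np.asarray(stack.frames[frame], float)
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
        raise ValueError(f"ROI {roi} not inside frame of shape {img.shape}")
    if (r1 - r0) % 2 == 0:
        r1 -= 1
    if (c1 - c0) % 2 == 0:
        c1 -= 1
    patch = img[r0:r1, c0:c1]
    if patch.std() == 0:
        raise ValueError("flat ROI: template has no intensity variance")
    # marker centroid inside the patch: markers are attenuators, so weight by
    # the attenuation depth below the local background (the patch maximum)
    depth = patch.max() - patch
    rows = np.arange(patch.shape[0])
    cols = np.arange(patch.shape[1])
    total = depth.sum()
    if total > 0:
        cr = float((depth.sum(axis=1) * rows).sum() / total)
        cc = float((depth.sum(axis=0) * cols).sum() / total)
    else:
        cr, cc = (patch.shape[0] - 1) / 2.0, (patch.shape[1] - 1) / 2.0
    return Template(
        patch=patch - patch.mean(),
        source_frame=frame,
        center=((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0),
        centroid_offset=(
            cr - (patch.shape[0] - 1) / 2.0,
            cc - (patch.shape[1] - 1) / 2.0,
        ),
    )


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    """Subpixel offset of a quadratic through three samples; clipped to [-0.5, 0.5]."""
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def ncc_match(frame: np.ndarray, template: Template, window=None) -> MatchResult:
    """Locate the template in ``frame`` (optionally within a search window).

    ``window`` is (row0, row1, col0, col1) bounds of the subimage searched;
    it must be at least as large as the template and lie inside the frame.
    Returns the subpixel-refined position of the ZNCC maximum (j_px = column,
    k_px = row) and the integer-peak score.  If the peak lies on the border
    of the search region the refinement is skipped and ``on_border`` is set.
    """
    frame = np.asarray(frame, float)
    if window is None:
        r0, r1, c0, c1 = 0, frame.shape[0], 0, frame.shape[1]
    else:
        r0, r1, c0, c1 = window
    if not (0 <= r0 < r1 <= frame.shape[0] and 0 <= c0 < c1 <= frame.shape[1]):
        raise ValueError(f"search window {window} not inside frame {frame.shape}")
    sub = frame[r0:r1, c0:c1]
    th, tw = template.shape
    if sub.shape[0] < th or sub.shape[1] < tw:
        raise ValueError("search window smaller than the template")
    ncc = match_template(sub, template.patch)  # valid-mode ZNCC map
    pr, pc = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    score = float(ncc[pr, pc])
    on_border = pr == 0 or pc == 0 or pr == ncc.shape[0] - 1 or pc == ncc.shape[1] - 1
    dr = dc = 0.0
    if not on_border:
        dr = _parabolic_offset(ncc[pr - 1, pc], ncc[pr, pc], ncc[pr + 1, pc])
        dc = _parabolic_offset(ncc[pr, pc - 1], ncc[pr, pc], ncc[pr, pc + 1])
    # peak indexes the template's top-left corner within the subimage;
    # report the position of the template's marker centroid
    k_px = r0 + pr + dr + (th - 1) / 2.0 + template.centroid_offset[0]
    j_px = c0 + pc + dc + (tw - 1) / 2.0 + template.centroid_offset[1]
    return MatchResult(j_px=j_px, k_px=k_px, score=score, on_border=on_border)


def track_stack(stack, template: Template, params: Optional[TrackParams] = None) -> MarkerTrack:
    """Track one marker through every frame of a projection stack.

    The search window for each frame is centered on the last accepted
    position (first frame: the whole image, or ``params.seed_position``).
    Frames whose best score falls below ``score_threshold``, or whose peak
    sits on the window border, are recorded as missing; failures never raise.
    """
    params = params or TrackParams()
    th, tw = template.shape
    half = params.search_halfwidth_px
    if half is None:
        half = 2 * max(th, tw)  # window = 4x template extent
    rows_n, cols_n = stack.frames.shape[1:]
    last: Optional[Tuple[float, float]] = params.seed_position  # (j, k)
    records = []
    for i in range(stack.n_frames):
        frame = stack.frames[i]
        if last is None:
            window = None
        else:
            jc, kc = last
            r0 = int(np.floor(kc)) - half
            c0 = int(np.floor(jc)) - half
            r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
            r0, c0 = max(r0, 0), max(c0, 0)
            r1, c1 = min(r1, rows_n), min(c1, cols_n)
            # keep the window at least template-sized after clipping
            if r1 - r0 < th:
                r0, r1 = (0, th) if r0 == 0 else (rows_n - th, rows_n)
            if c1 - c0 < tw:
                c0, c1 = (0, tw) if c0 == 0 else (cols_n - tw, cols_n)
            window = (r0, r1, c0, c1)
        m = ncc_match(frame, template, window)
        meta = stack.meta.iloc[i]
        rec = {
            "frame": int(meta["frame"]),
            "time_s": float(meta["time_s"]),
            "theta_deg": float(meta["theta_deg"]),
        }
        if m.score >= params.score_threshold and not m.on_border:
            rec.update(jm_px=m.j_px, km_px=m.k_px, score=m.score, status=STATUS_DETECTED)
            last = (m.j_px, m.k_px)
        else:
            rec.update(jm_px=np.nan, km_px=np.nan, score=np.nan, status=STATUS_MISSING)
        records.append(rec)
    data = pd.DataFrame(records, columns=TRACK_COLUMNS)
    if not len(records):
        data = pd.DataFrame({c: [] for c in TRACK_COLUMNS})
    return MarkerTrack(data)


def flag_outliers(track: MarkerTrack, params: Optional[TrackParams] = None) -> MarkerTrack:
    """Relabel detected points that jump away from the local track as outliers.

    A moving median (window ``outlier_window`` detected frames, centered) of
    jm and km defines the local track; points whose residual on either axis
    exceeds ``outlier_n_mad`` robust standard deviations (1.4826*MAD, floored
    at the tracker's 0.5 px localization precision so smooth-track curvature
    is never flagged) are relabeled ``outlier``.  With fewer than 5 detected
    points the track is returned unchanged with a warning.
    """
    params = params or TrackParams()
    out = track.copy()
    det = out.detected
    if det.sum() < 5:
        warnings.warn("fewer than 5 detected points: outlier pass skipped")
        return out
    sel = out.data.loc[det, ["jm_px", "km_px"]]
    bad = np.zeros(len(sel), dtype=bool)
    for col in ("jm_px", "km_px"):
        s = sel[col]
        # full windows only: partial edge windows lag the track and would
        # produce spurious residuals at the scan ends
        med = s.rolling(params.outlier_window, center=True, min_periods=params.outlier_window).median()
        resid = np.nan_to_num((s - med).to_numpy())
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = max(1.4826 * mad, 0.5)
        bad |= np.abs(resid) > params.outlier_n_mad * scale
    idx = sel.index[bad]
    out.data.loc[idx, "status"] = STATUS_OUTLIER
    return out


def interpolate_gaps(track: MarkerTrack, params: Optional[TrackParams] = None) -> MarkerTrack:
    """Fill interior missing/outlier frames by cubic interpolation in time.

    jm(t) and km(t) are interpolated through the detected points with a
    cubic spline.  Only gaps strictly inside the detected support are filled
    (no extrapolation at the ends), and only where the bracketing detected
    points are at most ``max_gap_s`` apart.  Filled frames get status
    ``interpolated`` and no score.
    """
    params = params or TrackParams()
    out = track.copy()
    det = out.detected
    if det.sum() < 2:
        return out
    t_det = out.data.loc[det, "time_s"].to_numpy(float)
    fill = out.mask(STATUS_MISSING, STATUS_OUTLIER)
    t_all = out.data["time_s"].to_numpy(float)
    interior = (t_all > t_det[0]) & (t_all < t_det[-1])
    # gap length between the detected points bracketing each candidate frame
    right = np.searchsorted(t_det, t_all)
    ok_gap = np.zeros(len(t_all), dtype=bool)
    inside = interior & fill
    ri = np.clip(right[inside], 1, len(t_det) - 1)
    ok_gap[inside] = (t_det[ri] - t_det[ri - 1]) <= params.max_gap_s
    target = inside & ok_gap
    if not target.any():
        return out
    for col in ("jm_px", "km_px"):
        spl = CubicSpline(t_det, out.data.loc[det, col].to_numpy(float))
        out.data.loc[target, col] = spl(t_all[target])
    out.data.loc[target, "score"] = np.nan
    out.data.loc[target, "status"] = STATUS_INTERPOLATED
    return out
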