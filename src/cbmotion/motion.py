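"""Recovery of 3D marker motion from a tracked detector trace.

The measured track (jm, km) of a moving marker is the superposition of two
effects: the sinogram of the marker's mean (stationary) position, which is a
closed elliptical curve in the (j, k) plane over a full rotation, and the
detector-frame offsets caused by patient motion.  This module

1. fits the stationary spherical coordinates (r, alpha, beta) of the marker
   by nonlinear least squares of the pinhole sinogram model to the track
   (coarse grid initialization + damped least squares, so the elliptical
   component is removed without assuming anything about the motion);
2. subtracts the fitted stationary track to obtain per-frame detector
   offsets (dj, dk) — these are the (u, v) shifts consumed by the
   projection-domain correction;
3. inverts the projection per frame to patient-frame displacements
   (dx', dy', dz');
4. fits each displacement axis with A*sin(2*pi*f*t - delta) to summarize
   amplitude, frequency and phase, and correlates traces of different
   markers (e.g. implanted vs skin-attached).

Monoscopic depth assumption
---------------------------
A single 2D view cannot determine a 3D displacement (2 measurements, 3
unknowns).  Following the fitted-geometry structure of the method, the
in-plane inversion j -> rho uses the *fitted* stationary angle alpha, i.e.
the in-plane displacement is resolved along the marker's radial direction,
and z = k*d/SID uses the depth implied by that inversion.  This is exact
for superior-inferior (Z) motion and for in-plane motion along the radial
direction; a transverse in-plane component is a genuine monoscopic blind
spot.  Views where the ray is nearly parallel to the radial direction
(|sin(alpha-theta)| below a small threshold) are blind for the in-plane
axes: they get NaN in-plane displacements and use the stationary depth for
z, so no near-singular amplification enters the traces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import correlate

from .geometry import (
    PatientPoint,
    ScanGeometry,
    _project_arrays,
    cm_to_px,
    px_to_cm,
)
from .tracking import MarkerTrack

__all__ = [
    "FitError",
    "IdentifiabilityError",
    "StationaryFit",
    "MotionTrace",
    "SinusoidFit",
    "fit_stationary",
    "detector_residuals",
    "to_patient_displacements",
    "fit_sinusoid",
    "fit_trace",
    "correlate_tracks",
    "subtract_sag",
]

INTERPOLATED_WEIGHT = 0.5  # cost weight of interpolated points in the stationary fit


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best parameters so far."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class IdentifiabilityError(ValueError):
    """Track geometry too poor to constrain the fit (e.g. angular span < 90 deg)."""


@dataclass
class StationaryFit:
    """Fitted stationary marker position in spherical coordinates.

    ``js_px``/``ks_px`` give the fitted stationary track over the full
    schedule; they satisfy the projection equations of the implied
    :class:`~cbmotion.geometry.PatientPoint` exactly by construction.
    """

    r_cm: float
    alpha_rad: float
    beta_rad: float
    js_px: np.ndarray
    ks_px: np.ndarray
    residual_rms_px: float
    n_iter: int
    cost: float
    grid_cost: float

    @property
    def point(self) -> PatientPoint:
        return PatientPoint.from_spherical(self.r_cm, self.alpha_rad, self.beta_rad)

    def summary(self) -> dict:
        return {
            "r_cm": float(self.r_cm),
            "alpha_deg": float(np.rad2deg(self.alpha_rad)),
            "beta_deg": float(np.rad2deg(self.beta_rad)),
            "residual_rms_px": float(self.residual_rms_px),
            "n_iter": int(self.n_iter),
            "cost": float(self.cost),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass
class SinusoidFit:
    """Parameters of d(t) = A*sin(2*pi*f*t - delta) fitted to one axis."""

    amplitude_cm: float
    freq_hz: float
    phase_rad: float
    rms_cm: float
    flat: bool = False

    @property
    def freq_cpm(self) -> float:
        """Frequency in cycles per minute (breathing-rate convention)."""
        return self.freq_hz * 60.0

    def summary(self) -> dict:
        return {
            "amplitude_cm": float(self.amplitude_cm),
            "freq_hz": float(self.freq_hz),
            "freq_cpm": float(self.freq_cpm),
            "phase_rad": float(self.phase_rad),
            "rms_cm": float(self.rms_cm),
            "flat": bool(self.flat),
        }


@dataclass
class MotionTrace:
    """Per-frame patient-frame displacements plus detector-frame offsets.

    ``data`` columns: frame, time_s, theta_deg, dx_cm, dy_cm, dz_cm,
    dj_px, dk_px, flag (ok / blind / dropped).  ``fits`` holds per-axis
    :class:`SinusoidFit` results once :func:`fit_trace` has run.
    """

    data: pd.DataFrame
    marker_id: str = "m0"
    fits: dict = field(default_factory=dict)

    def axis(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        """(t, d) samples for axis 'x' | 'y' | 'z', NaN rows dropped."""
        col = {"x": "dx_cm", "y": "dy_cm", "z": "dz_cm"}[name]
        t = self.data["time_s"].to_numpy(float)
        d = self.data[col].to_numpy(float)
        good = np.isfinite(d)
        return t[good], d[good]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def fit_summary(self) -> dict:
        return {ax: f.summary() for ax, f in self.fits.items()}


# ---------------------------------------------------------------------------
# stationary-track fitting


def _model_px(r, alpha, beta, theta_rad, geom: ScanGeometry):
    rho = r * np.sin(beta)
    z = r * np.cos(beta)
    j_cm, k_cm, d = _project_arrays(rho, alpha, z, theta_rad, geom)
    return cm_to_px(j_cm, geom, k_cm)


def _usable_arrays(track: MarkerTrack):
    use = track.usable
    d = track.data.loc[use]
    w = np.where(d["status"] == "interpolated", INTERPOLATED_WEIGHT, 1.0)
    return (
        np.deg2rad(d["theta_deg"].to_numpy(float)),
        d["jm_px"].to_numpy(float),
        d["km_px"].to_numpy(float),
        w,
    )


DEFAULT_GRID = (
    np.deg2rad(np.arange(0.0, 360.0, 10.0)),  # alpha
    np.deg2rad(np.arange(10.0, 171.0, 10.0)),  # beta
    np.arange(1.0, 25.1, 2.0),  # r (cm)
)


def _grid_search(theta, jm, km, w, geom) -> Tuple[np.ndarray, float]:
    alphas, betas, rs = DEFAULT_GRID
    best = (np.inf, None)
    # vectorize over (alpha, beta) for each r to bound memory
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    A, B = A.ravel(), B.ravel()
    for r in rs:
        rho = r * np.sin(B)[:, None]
        z = r * np.cos(B)[:, None]
        psi = A[:, None] - theta[None, :]
        d = geom.sad_cm - rho * np.cos(psi)
        j_cm = geom.sid_cm * rho * np.sin(psi) / d
        k_cm = geom.sid_cm * z / d
        j_px, k_px = cm_to_px(j_cm, geom, k_cm)
        cost = np.sum(w * ((j_px - jm) ** 2 + (k_px - km) ** 2), axis=1)
        i = int(np.argmin(cost))
        if cost[i] < best[0]:
            best = (float(cost[i]), np.array([r, A[i], B[i]]))
    return best[1], best[0]


def fit_stationary(
    track: MarkerTrack,
    geom: ScanGeometry,
    init: Optional[Tuple[float, float, float]] = None,
) -> StationaryFit:
    """Fit the stationary spherical coordinates (r, alpha, beta) of a marker.

    Minimizes ``sum w * [(jm - js)^2 + (km - ks)^2]`` (pixels) over the
    usable points of the track by damped least squares; interpolated points
    are down-weighted (cost weight 0.5).  ``init`` is an optional
    (r_cm, alpha_rad, beta_rad) starting point; by default a coarse grid
    search over alpha x beta x r seeds the solver to avoid local minima.

    Raises :class:`IdentifiabilityError` with fewer than 10 usable points or
    an angular span below 90 degrees; :class:`FitError` (carrying the best
    parameters so far) on solver failure.
    """
    theta, jm, km, w = _usable_arrays(track)
    if len(theta) < 10:
        raise IdentifiabilityError(f"only {len(theta)} usable points (need >= 10)")
    span = np.rad2deg(theta.max() - theta.min())
    if span < 90.0:
        raise IdentifiabilityError(f"angular span {span:.1f} deg < 90 deg: geometry ill-conditioned")
    sw = np.sqrt(w)

    def resid(x):
        j, k = _model_px(x[0], x[1], x[2], theta, geom)
        return np.concatenate([sw * (j - jm), sw * (k - km)])

    if init is not None:
        x0 = np.array([init[0], init[1], init[2]], float)
        grid_cost = float(np.sum(resid(x0) ** 2))
    else:
        x0, grid_cost = _grid_search(theta, jm, km, w, geom)
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, -np.inf, 0.0], [0.95 * geom.sad_cm, np.inf, np.pi]),
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    cost = float(np.sum(sol.fun**2))
    r, alpha, beta = sol.x
    alpha = float(np.mod(alpha, 2 * np.pi))
    js_px, ks_px = _model_px(r, alpha, beta, geom.theta_rad, geom)
    fit = StationaryFit(
        r_cm=float(r),
        alpha_rad=alpha,
        beta_rad=float(beta),
        js_px=np.asarray(js_px, float),
        ks_px=np.asarray(ks_px, float),
        residual_rms_px=float(np.sqrt(np.mean(resid(sol.x) ** 2))),
        n_iter=int(sol.nfev),
        cost=cost,
        grid_cost=grid_cost,
    )
    if not sol.success:
        raise FitError(f"stationary fit did not converge: {sol.message}", best=fit)
    # the refined optimum can never be worse than its own starting node
    assert cost <= grid_cost + 1e-9, "refinement worsened the grid cost"
    return fit


def detector_residuals(track: MarkerTrack, fit: StationaryFit) -> pd.DataFrame:
    """Detector-frame motion offsets dj = jm - js, dk = km - ks (pixels).

    Returns one row per usable frame of the track; these are the (u, v)
    shifts consumed by the projection-domain correction.
    """
    use = track.usable
    d = track.data.loc[use]
    idx = d.index.to_numpy()
    return pd.DataFrame(
        {
            "frame": d["frame"].to_numpy(int),
            "time_s": d["time_s"].to_numpy(float),
            "theta_deg": d["theta_deg"].to_numpy(float),
            "dj_px": d["jm_px"].to_numpy(float) - fit.js_px[idx],
            "dk_px": d["km_px"].to_numpy(float) - fit.ks_px[idx],
        }
    )


def to_patient_displacements(
    track: MarkerTrack,
    fit: StationaryFit,
    geom: ScanGeometry,
    blind_deg: float = 3.0,
) -> MotionTrace:
    """Invert the projection per frame to patient-frame displacements.

    Uses the fitted stationary angle alpha for the in-plane inversion
    (monoscopic depth assumption, see module docstring).  Frames within
    ``blind_deg`` of the in-plane blind spot get NaN dx/dy and use the
    stationary depth for dz; frames whose inverted depth is non-positive
    are dropped (flag ``dropped``).
    """
    use = track.usable
    d = track.data.loc[use]
    idx = d.index.to_numpy()
    theta = np.deg2rad(d["theta_deg"].to_numpy(float))
    alpha, r, beta = fit.alpha_rad, fit.r_cm, fit.beta_rad
    psi = alpha - theta
    sinpsi, cospsi = np.sin(psi), np.cos(psi)

    jm_cm, km_cm = px_to_cm(d["jm_px"].to_numpy(float), d["km_px"].to_numpy(float), geom)
    js_cm, ks_cm = px_to_cm(fit.js_px[idx], fit.ks_px[idx], geom)

    rho_s = r * np.sin(beta)
    d_s = geom.sad_cm - rho_s * cospsi

    blind = np.abs(sinpsi) < np.sin(np.deg2rad(blind_deg))
    denom = geom.sid_cm * sinpsi + jm_cm * cospsi
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_m = geom.sad_cm * jm_cm / denom
    rho_m = np.where(blind, rho_s, rho_m)
    d_m = geom.sad_cm - rho_m * cospsi
    dropped = d_m <= 0

    x_m, y_m = rho_m * np.sin(alpha), rho_m * np.cos(alpha)
    x_s, y_s = rho_s * np.sin(alpha), rho_s * np.cos(alpha)
    z_m = km_cm * d_m / geom.sid_cm
    z_s = ks_cm * d_s / geom.sid_cm

    dx = x_m - x_s
    dy = y_m - y_s
    dz = z_m - z_s
    dx[blind] = np.nan
    dy[blind] = np.nan
    for arr in (dx, dy, dz):
        arr[dropped] = np.nan
    flag = np.where(dropped, "dropped", np.where(blind, "blind", "ok"))

    data = pd.DataFrame(
        {
            "frame": d["frame"].to_numpy(int),
            "time_s": d["time_s"].to_numpy(float),
            "theta_deg": d["theta_deg"].to_numpy(float),
            "dx_cm": dx,
            "dy_cm": dy,
            "dz_cm": dz,
            "dj_px": d["jm_px"].to_numpy(float) - fit.js_px[idx],
            "dk_px": d["km_px"].to_numpy(float) - fit.ks_px[idx],
            "flag": flag,
        }
    )
    return MotionTrace(data=data, marker_id=track.marker_id)


# ---------------------------------------------------------------------------
# sinusoid fitting and track correlation


def fit_sinusoid(t, d) -> SinusoidFit:
    """Fit d(t) = A*sin(2*pi*f*t - delta) by nonlinear least squares.

    The frequency is initialized from the dominant peak of the discrete
    spectrum (samples linearly resampled to a uniform grid), amplitude and
    phase from the linear sine/cosine solve at that frequency, then all
    three are refined jointly.  A is canonicalized >= 0 and delta to
    [0, 2*pi).  A flat signal returns A=0 with ``flat=True`` (f undefined).
    """
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    good = np.isfinite(t) & np.isfinite(d)
    t, d = t[good], d[good]
    if len(t) < 8:
        raise ValueError(f"too few samples ({len(t)}) for a sinusoid fit")
    if np.ptp(d) == 0:
        return SinusoidFit(0.0, np.nan, 0.0, 0.0, flat=True)

    # frequency seed from the spectrum on a uniform resampling
    tu = np.linspace(t[0], t[-1], len(t))
    du = np.interp(tu, t, d)
    spec = np.abs(np.fft.rfft(du - du.mean()))
    if len(spec) < 2:
        raise ValueError("signal too short for a spectral frequency seed")
    kpk = 1 + int(np.argmax(spec[1:]))
    f0 = kpk / (tu[-1] - tu[0])
    duration = t[-1] - t[0]
    if duration * f0 < 2.0:
        warnings.warn("fewer than 2 full periods sampled: sinusoid fit may be unreliable")

    def linear_ab(f):
        s, c = np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)
        M = np.column_stack([s, c])
        ab, *_ = np.linalg.lstsq(M, d, rcond=None)
        return ab

    a0, b0 = linear_ab(f0)

    def resid(x):
        a, b, f = x
        return a * np.sin(2 * np.pi * f * t) + b * np.cos(2 * np.pi * f * t) - d

    sol = least_squares(resid, np.array([a0, b0, f0]), method="lm", xtol=1e-14, ftol=1e-14)
    a, b, f = sol.x
    f = abs(f)
    amp = float(np.hypot(a, b))
    # A*sin(2*pi*f*t - delta) = A*cos(delta)*sin(.) - A*sin(delta)*cos(.)
    delta = float(np.mod(np.arctan2(-b, a), 2 * np.pi))
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return SinusoidFit(amplitude_cm=amp, freq_hz=float(f), phase_rad=delta, rms_cm=rms)


def fit_trace(trace: MotionTrace) -> MotionTrace:
    """Fit all three axes of a trace in place; results land in ``trace.fits``."""
    for ax in ("x", "y", "z"):
        t, d = trace.axis(ax)
        trace.fits[ax] = fit_sinusoid(t, d)
    return trace


@dataclass
class CorrelationResult:
    pearson_r: float
    lag_s: float
    phase_diff_rad: float


def correlate_tracks(a: MotionTrace, b: MotionTrace, axis: str = "z") -> CorrelationResult:
    """Quantify agreement between two motion traces on one axis.

    Both traces are resampled to a common uniform timebase over their
    overlapping support.  Returns the Pearson correlation at zero lag, the
    lag maximizing the cross-correlation, and the phase difference
    delta_a - delta_b of the per-trace sinusoid fits (wrapped to (-pi, pi]).
    Raises on overlap shorter than two periods of the slower trace.
    """
    ta, da = a.axis(axis)
    tb, db = b.axis(axis)
    t0, t1 = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if t1 <= t0:
        raise ValueError("traces do not overlap in time")
    fa = a.fits.get(axis) or fit_sinusoid(ta, da)
    fb = b.fits.get(axis) or fit_sinusoid(tb, db)
    freqs = [f.freq_hz for f in (fa, fb) if np.isfinite(f.freq_hz) and f.freq_hz > 0]
    if freqs and (t1 - t0) * min(freqs) < 2.0:
        raise ValueError("overlapping support shorter than two motion periods")
    dt = float(np.median(np.diff(ta)))
    tu = np.arange(t0, t1, dt)
    ua = np.interp(tu, ta, da)
    ub = np.interp(tu, tb, db)
    ua, ub = ua - ua.mean(), ub - ub.mean()
    denom = np.sqrt(np.sum(ua**2) * np.sum(ub**2))
    r = float(np.sum(ua * ub) / denom) if denom > 0 else np.nan
    xc = correlate(ua, ub, mode="full")
    lag = (int(np.argmax(xc)) - (len(tu) - 1)) * dt
    dphi = float(np.mod(fa.phase_rad - fb.phase_rad + np.pi, 2 * np.pi) - np.pi)
    return CorrelationResult(pearson_r=r, lag_s=float(lag), phase_diff_rad=dphi)


def subtract_sag(track: MarkerTrack, sag_table: pd.DataFrame) -> MarkerTrack:
    """Subtract tabulated gantry-sag shifts from a track.

    ``sag_table`` columns: theta_deg, dj_px, dk_px; values are interpolated
    linearly in theta and must cover the track's theta range.  Gantry sag is
    a reproducible mechanical deflection of the source/panel arms during the
    rotation; subtracting it isolates the respiratory component.
    """
    tab = sag_table.sort_values("theta_deg")
    th_tab = tab["theta_deg"].to_numpy(float)
    out = track.copy()
    has = out.data["jm_px"].notna().to_numpy()
    th = out.data.loc[has, "theta_deg"].to_numpy(float)
    if len(th) and (th.min() < th_tab[0] - 1e-9 or th.max() > th_tab[-1] + 1e-9):
        raise ValueError("sag table does not cover the track's theta range")
    out.data.loc[has, "jm_px"] -= np.interp(th, th_tab, tab["dj_px"].to_numpy(float))
    out.data.loc[has, "km_px"] -= np.interp(th, th_tab, tab["dk_px"].to_numpy(float))
    return out
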