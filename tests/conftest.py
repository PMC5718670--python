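"""Shared fixtures: reduced-geometry synthetic scans reused across modules.

Everything is generated at test time from fixed seeds; the heavy scans are
session-scoped so simulation and tracking run once.
"""

from __future__ import annotations

import numpy as np
import pytest

import cbmotion as cb


def roi_around(truth_row, half: int = 8):
    """Integer ROI (row0, row1, col0, col1) centered on a ground-truth position."""
    k, j = int(round(truth_row.k_px)), int(round(truth_row.j_px))
    return (k - half, k + half + 1, j - half, j + half + 1)


def template_from_truth(stack, marker_id: str = "m0", half: int = 8):
    """Template cut at a frame where the marker sits well inside the panel."""
    tr = stack.truth.query("marker_id == @marker_id")
    rows, cols = stack.frames.shape[1:]
    good = tr[
        (tr.j_px > 4 * half)
        & (tr.j_px < cols - 4 * half)
        & (tr.k_px > 4 * half)
        & (tr.k_px < rows - 4 * half)
    ]
    r0 = good.iloc[0]
    return cb.extract_template(stack, int(r0.frame), roi_around(r0, half)), r0


@pytest.fixture(scope="session")
def reduced_geom():
    return cb.ScanGeometry.reduced()


@pytest.fixture(scope="session")
def z_phantom_marker():
    """The reference phantom protocol: 1.75 cm, 15 cycles/min along Z."""
    wf = cb.MotionWaveform.from_cycles_per_min(az_cm=1.75, fz_cpm=15.0)
    rest = cb.PatientPoint.from_spherical(10.0, np.deg2rad(40.0), np.deg2rad(90.0))
    return cb.MarkerSpec(rest=rest, waveform=wf, marker_id="m0")


@pytest.fixture(scope="session")
def z_motion_scan(reduced_geom, z_phantom_marker):
    """Noise-free 360-frame scan of the phantom-protocol marker."""
    return cb.generate_scan([z_phantom_marker], reduced_geom, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def z_motion_track(z_motion_scan):
    tmpl, _ = template_from_truth(z_motion_scan)
    return cb.track_stack(z_motion_scan, tmpl)


@pytest.fixture(scope="session")
def z_motion_fit(z_motion_track, reduced_geom):
    return cb.fit_stationary(z_motion_track, reduced_geom)


@pytest.fixture(scope="session")
def stationary_scan(reduced_geom):
    """Noise-free scan of one motionless marker at (r, alpha, beta) = (10, 40, 40)."""
    rest = cb.PatientPoint.from_spherical(10.0, np.deg2rad(40.0), np.deg2rad(40.0))
    m = cb.MarkerSpec(rest=rest, marker_id="m0")
    return cb.generate_scan([m], reduced_geom, noise_sigma=0.0, seed=2)


def analytic_track(point, geom, status="detected") -> cb.MarkerTrack:
    """Exact noise-free MarkerTrack of a stationary point (no rendering)."""
    import pandas as pd

    st = cb.stationary_track(point, geom)
    j_px, k_px = cb.cm_to_px(st.j_cm, geom, st.k_cm)
    return cb.MarkerTrack(
        pd.DataFrame(
            {
                "frame": geom.schedule["frame"].to_numpy(int),
                "time_s": geom.times_s,
                "theta_deg": st.theta_deg,
                "jm_px": j_px,
                "km_px": k_px,
                "score": 1.0,
                "status": status,
            }
        )
    )
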