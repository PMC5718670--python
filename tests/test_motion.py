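"""Stationary-track fitting, displacement decomposition, sinusoid fits."""

import numpy as np
import pandas as pd
import pytest

import cbmotion as cb
from cbmotion.motion import IdentifiabilityError

from conftest import analytic_track


def dense_grid_oracle(track, geom, center, spans=(0.5, 2.0, 2.0), steps=(0.05, 0.2, 0.2)):
    """Brute-force refinement of the stationary-fit cost on a dense local grid.

    Independent of the solver: evaluates the same weighted least-squares cost
    at every node of a dense (r, alpha_deg, beta_deg) grid around ``center``
    and returns the best node and its cost.
    """
    from cbmotion.motion import _model_px, _usable_arrays

    theta, jm, km, w = _usable_arrays(track)
    r0, a0, b0 = center
    best = (np.inf, None)
    for r in np.arange(r0 - spans[0], r0 + spans[0] + 1e-9, steps[0]):
        for a in np.deg2rad(np.arange(a0 - spans[1], a0 + spans[1] + 1e-9, steps[1])):
            for b in np.deg2rad(np.arange(b0 - spans[2], b0 + spans[2] + 1e-9, steps[2])):
                j, k = _model_px(r, a, b, theta, geom)
                cost = float(np.sum(w * ((j - jm) ** 2 + (k - km) ** 2)))
                if cost < best[0]:
                    best = (cost, (r, a, b))
    return best


class TestStationaryFit:
    @pytest.mark.parametrize("r,a,b", [(10.0, 40.0, 40.0), (20.0, 30.0, 30.0), (30.0, 20.0, 20.0)])
    def test_recovers_stationary_point_to_numerical_precision(self, reduced_geom, r, a, b):
        p = cb.PatientPoint.from_spherical(r, np.deg2rad(a), np.deg2rad(b))
        trk = analytic_track(p, reduced_geom)
        fit = cb.fit_stationary(trk, reduced_geom)
        assert fit.residual_rms_px < 1e-6
        assert fit.r_cm == pytest.approx(r, abs=1e-6)
        assert np.rad2deg(fit.alpha_rad) == pytest.approx(a, abs=1e-5)
        assert np.rad2deg(fit.beta_rad) == pytest.approx(b, abs=1e-5)

    def test_isocenter_track_degenerates_to_r_zero(self, reduced_geom):
        trk = analytic_track(cb.PatientPoint(0, 0, 0), reduced_geom)
        fit = cb.fit_stationary(trk, reduced_geom)
        assert fit.r_cm == pytest.approx(0.0, abs=1e-3)
        assert fit.residual_rms_px < 1e-6

    def test_optimum_not_worse_than_dense_grid_oracle(self, z_motion_track, z_motion_fit, reduced_geom):
        """The solver's optimum must beat a brute-force dense grid of the same
        cost, and land within one oracle grid step of the oracle's node."""
        cost_o, (r_o, a_o, b_o) = dense_grid_oracle(
            z_motion_track, reduced_geom, center=(10.0, 40.0, 90.0)
        )
        assert z_motion_fit.cost <= cost_o + 1e-9
        assert abs(z_motion_fit.r_cm - r_o) <= 0.05
        assert abs(z_motion_fit.alpha_rad - a_o) <= np.deg2rad(0.2)
        assert abs(z_motion_fit.beta_rad - b_o) <= np.deg2rad(0.2)

    def test_moving_marker_fit_stays_near_rest_position(self, z_motion_fit):
        # zero-mean 1.75 cm Z sinusoid: fitted rest within a small fraction
        assert z_motion_fit.r_cm == pytest.approx(10.0, abs=0.05)
        assert np.rad2deg(z_motion_fit.alpha_rad) == pytest.approx(40.0, abs=0.2)
        assert np.rad2deg(z_motion_fit.beta_rad) == pytest.approx(90.0, abs=1.0)

    def test_fitted_track_satisfies_projection_equations(self, z_motion_fit, reduced_geom):
        st = cb.stationary_track(z_motion_fit.point, reduced_geom)
        j_px, k_px = cb.cm_to_px(st.j_cm, reduced_geom, st.k_cm)
        assert np.allclose(z_motion_fit.js_px, j_px, atol=1e-9)
        assert np.allclose(z_motion_fit.ks_px, k_px, atol=1e-9)

    def test_small_angular_span_rejected(self, reduced_geom):
        trk = analytic_track(cb.PatientPoint(5, 2, 1), reduced_geom)
        trk.data.loc[80:, "status"] = "missing"  # 80 frames = 80 degrees
        with pytest.raises(IdentifiabilityError, match="span"):
            cb.fit_stationary(trk, reduced_geom)

    def test_too_few_points_rejected(self, reduced_geom):
        trk = analytic_track(cb.PatientPoint(5, 2, 1), reduced_geom)
        trk.data.loc[5:, "status"] = "missing"
        with pytest.raises(IdentifiabilityError):
            cb.fit_stationary(trk, reduced_geom)


class TestDetectorResiduals:
    def test_stationary_track_residuals_are_zero(self, reduced_geom):
        p = cb.PatientPoint.from_spherical(10, np.deg2rad(40), np.deg2rad(40))
        trk = analytic_track(p, reduced_geom)
        fit = cb.fit_stationary(trk, reduced_geom)
        res = cb.detector_residuals(trk, fit)
        assert np.max(np.abs(res[["dj_px", "dk_px"]].to_numpy())) < 1e-6

    def test_pure_z_motion_separates_onto_k_axis(self, z_motion_track, z_motion_fit, reduced_geom):
        res = cb.detector_residuals(z_motion_track, z_motion_fit)
        # j residuals stay at the tracking noise floor, k residuals carry the motion
        assert np.max(np.abs(res["dj_px"])) < 0.25
        expected_amp = 1.75 * reduced_geom.sid_cm / reduced_geom.sad_cm / reduced_geom.pitch_k_cm
        assert np.max(res["dk_px"]) == pytest.approx(expected_amp, rel=0.12)
        assert np.min(res["dk_px"]) == pytest.approx(-expected_amp, rel=0.12)


class TestPatientDisplacements:
    def test_stationary_marker_gives_zero_displacements(self, reduced_geom):
        p = cb.PatientPoint.from_spherical(10, np.deg2rad(40), np.deg2rad(40))
        trk = analytic_track(p, reduced_geom)
        fit = cb.fit_stationary(trk, reduced_geom)
        trace = cb.to_patient_displacements(trk, fit, reduced_geom)
        ok = trace.data["flag"] == "ok"
        assert np.nanmax(np.abs(trace.data.loc[ok, ["dx_cm", "dy_cm", "dz_cm"]].to_numpy())) < 1e-6

    def test_z_trace_matches_injected_waveform(self, z_motion_scan, z_motion_track, z_motion_fit, reduced_geom):
        trace = cb.to_patient_displacements(z_motion_track, z_motion_fit, reduced_geom)
        t, dz = trace.axis("z")
        truth = 1.75 * np.sin(2 * np.pi * 0.25 * t)
        # within twice the 0.5 px isocenter scale (0.26 mm) everywhere
        assert np.max(np.abs(dz - truth)) < 2 * 0.5 * cb.isocenter_pixel_pitch(reduced_geom) / 10.0

    def test_radial_in_plane_motion_recovered_with_blind_spot_gaps(self, reduced_geom):
        # motion along the marker's own radial direction (+X at alpha=90 deg):
        # per-frame inversion is exact away from the blind spots
        wf = cb.MotionWaveform.from_cycles_per_min(ax_cm=1.0, fx_cpm=12.0)
        rest = cb.PatientPoint.from_spherical(8.0, np.deg2rad(90), np.deg2rad(90))
        stack = cb.generate_scan([cb.MarkerSpec(rest=rest, waveform=wf)], reduced_geom,
                                 noise_sigma=0.0, seed=9)
        from conftest import template_from_truth

        tmpl, _ = template_from_truth(stack)
        trk = cb.track_stack(stack, tmpl)
        fit = cb.fit_stationary(trk, reduced_geom)
        trace = cb.to_patient_displacements(trk, fit, reduced_geom)
        assert (trace.data["flag"] == "blind").any()
        assert trace.data.loc[trace.data["flag"] == "blind", "dx_cm"].isna().all()
        cb.fit_trace(trace)
        assert trace.fits["x"].amplitude_cm == pytest.approx(1.0, rel=0.01)
        assert trace.fits["x"].freq_cpm == pytest.approx(12.0, rel=0.005)
        # cross-axis leakage below 5% of the injected amplitude
        assert trace.fits["z"].amplitude_cm < 0.05

    @pytest.mark.parametrize("az,fcpm", [(0.8, 10.0), (2.0, 20.0)])
    def test_end_to_end_z_recovery_within_one_percent(self, reduced_geom, az, fcpm):
        wf = cb.MotionWaveform.from_cycles_per_min(az_cm=az, fz_cpm=fcpm)
        rest = cb.PatientPoint.from_spherical(12.0, np.deg2rad(70), np.deg2rad(80))
        stack = cb.generate_scan([cb.MarkerSpec(rest=rest, waveform=wf)], reduced_geom,
                                 noise_sigma=0.0, seed=13)
        from conftest import template_from_truth

        tmpl, _ = template_from_truth(stack)
        trk = cb.track_stack(stack, tmpl)
        fit = cb.fit_stationary(trk, reduced_geom)
        trace = cb.fit_trace(cb.to_patient_displacements(trk, fit, reduced_geom))
        assert trace.fits["z"].amplitude_cm == pytest.approx(az, rel=0.01)
        assert trace.fits["z"].freq_cpm == pytest.approx(fcpm, rel=0.005)
        # cross-axis amplitudes below 5% of the injected one
        assert trace.fits["x"].amplitude_cm < 0.05 * az
        assert trace.fits["y"].amplitude_cm < 0.05 * az


class TestSinusoidFit:
    def test_exact_on_noise_free_protocol_samples(self):
        t = np.arange(0, 60, 1 / 6)
        d = 1.75 * np.sin(2 * np.pi * 0.25 * t)
        f = cb.fit_sinusoid(t, d)
        assert f.amplitude_cm == pytest.approx(1.75, abs=1e-6)
        assert f.freq_hz == pytest.approx(0.25, abs=1e-6)
        assert f.freq_cpm == pytest.approx(15.0, abs=1e-4)

    def test_flat_signal_flagged_with_zero_amplitude(self):
        f = cb.fit_sinusoid(np.arange(20.0), np.zeros(20))
        assert f.amplitude_cm == 0.0 and f.flat and np.isnan(f.freq_hz)

    def test_phase_canonicalized(self):
        t = np.arange(0, 40, 0.1)
        for delta in (0.7, 3.9, 5.5):
            f = cb.fit_sinusoid(t, 1.2 * np.sin(2 * np.pi * 0.3 * t - delta))
            assert f.amplitude_cm == pytest.approx(1.2, abs=1e-6)
            assert 0 <= f.phase_rad < 2 * np.pi
            assert f.phase_rad == pytest.approx(delta, abs=1e-6)

    def test_monte_carlo_amplitude_unbiased_under_noise(self):
        """Across 100 seeded noisy replicates the mean fitted amplitude stays
        within 3 standard errors of the truth (sigma=0.05 cm, n=300)."""
        rng = np.random.default_rng(42)
        t = np.linspace(0, 30, 300)
        truth = 1.0
        amps = []
        for _ in range(100):
            d = truth * np.sin(2 * np.pi * 0.25 * t - 1.0) + rng.normal(0, 0.05, t.size)
            amps.append(cb.fit_sinusoid(t, d).amplitude_cm)
        amps = np.asarray(amps)
        se = amps.std(ddof=1) / np.sqrt(len(amps))
        assert abs(amps.mean() - truth) < 3 * se


class TestCorrelateTracks:
    def _trace(self, amp, delta, f_hz=0.25, n=360):
        t = np.linspace(0, 60, n)
        d = amp * np.sin(2 * np.pi * f_hz * t - delta)
        data = pd.DataFrame(
            {"frame": np.arange(n), "time_s": t, "theta_deg": np.linspace(0, 359, n),
             "dx_cm": 0.0, "dy_cm": 0.0, "dz_cm": d, "dj_px": 0.0, "dk_px": 0.0, "flag": "ok"}
        )
        return cb.MotionTrace(data=data)

    def test_self_correlation_is_perfect(self):
        a = self._trace(1.0, 0.3)
        c = cb.correlate_tracks(a, a)
        assert c.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert c.lag_s == 0.0 and c.phase_diff_rad == pytest.approx(0.0, abs=1e-6)

    def test_quadrature_traces_decorrelate_at_zero_lag(self):
        a, b = self._trace(1.0, 0.0), self._trace(1.0, np.pi / 2)
        c = cb.correlate_tracks(a, b)
        assert abs(c.pearson_r) < 0.1
        assert c.phase_diff_rad == pytest.approx(-np.pi / 2, abs=1e-3)

    def test_internal_vs_external_amplitude_ratio(self):
        # internal marker near the diaphragm (9 mm) vs skin marker (1.5 mm)
        a, b = self._trace(0.9, 1.0), self._trace(0.15, 1.0)
        c = cb.correlate_tracks(a, b)
        assert c.pearson_r == pytest.approx(1.0, abs=1e-6)
        fa, fb = cb.fit_sinusoid(*a.axis("z")), cb.fit_sinusoid(*b.axis("z"))
        assert fa.amplitude_cm / fb.amplitude_cm == pytest.approx(6.0, rel=1e-6)

    def test_disjoint_supports_rejected(self):
        a, b = self._trace(1.0, 0.0), self._trace(1.0, 0.0)
        b.data["time_s"] += 120.0
        with pytest.raises(ValueError):
            cb.correlate_tracks(a, b)


class TestSagSubtraction:
    def test_zero_table_is_identity(self, z_motion_track):
        table = pd.DataFrame({"theta_deg": [0.0, 360.0], "dj_px": [0.0, 0.0], "dk_px": [0.0, 0.0]})
        out = cb.subtract_sag(z_motion_track, table)
        pd.testing.assert_frame_equal(out.data, z_motion_track.data)

    def test_constant_offset_shifts_j_only(self, z_motion_track):
        table = pd.DataFrame({"theta_deg": [0.0, 360.0], "dj_px": [1.0, 1.0], "dk_px": [0.0, 0.0]})
        out = cb.subtract_sag(z_motion_track, table)
        assert np.allclose(out.data["jm_px"], z_motion_track.data["jm_px"] - 1.0)
        assert np.allclose(out.data["km_px"], z_motion_track.data["km_px"])

    def test_injected_sag_removed_round_trip(self, reduced_geom):
        p = cb.PatientPoint.from_spherical(10, np.deg2rad(40), np.deg2rad(40))
        clean = analytic_track(p, reduced_geom)
        th = clean.data["theta_deg"].to_numpy()
        sag_j = 1.5 * np.sin(np.deg2rad(th))  # one-cycle-per-rotation gantry flex
        sag_k = 0.8 * np.cos(np.deg2rad(th))
        sagged = clean.copy()
        sagged.data["jm_px"] += sag_j
        sagged.data["km_px"] += sag_k
        table = pd.DataFrame({"theta_deg": th, "dj_px": sag_j, "dk_px": sag_k})
        restored = cb.subtract_sag(sagged, table)
        fit = cb.fit_stationary(restored, reduced_geom)
        assert fit.residual_rms_px < 1e-9

    def test_uncovered_theta_range_rejected(self, z_motion_track):
        table = pd.DataFrame({"theta_deg": [0.0, 180.0], "dj_px": [0.0, 1.0], "dk_px": [0.0, 0.0]})
        with pytest.raises(ValueError, match="cover"):
            cb.subtract_sag(z_motion_track, table)
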