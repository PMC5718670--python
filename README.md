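# cbmotion

Marker-based 3D respiratory-motion extraction and projection-domain motion
correction for kV cone-beam CT (CBCT).

A linac-mounted on-board imager acquires ~650 kV projections over a full
gantry rotation in about one minute — 10–20 breathing cycles.  Respiratory
motion therefore smears the reconstruction: blurring, spatial distortion and
loss of contrast around moving tumors.  `cbmotion` implements, end to end,
an algorithm that turns that problem into a signal: it tracks the shadow of
a small radio-opaque seed marker (implanted in or near the lesion, or taped
to the skin) through every projection, separates the marker's *parallax*
(the sinogram of its stationary position) from its *motion*, reports the 3D
motion trajectory, and then shifts every projection so the marker — and the
rigidly co-moving anatomy around it — is stationary before reconstruction.

The package is aimed at medical-physics and image-guided-radiotherapy
researchers who want a self-contained, testable implementation: a synthetic
cone-beam simulator with exact ground truth replaces scanner data, so every
stage can be validated quantitatively on a laptop.

## The model

With the patient frame fixed at the isocenter (Z = superior–inferior) and
the source at angle θ on a circle of radius SAD, a point at cylindrical
coordinates (ρ, α, z) projects onto detector coordinates (cm, at
source–imager distance SID):

    j = SID · ρ sin(α − θ) / (SAD − ρ cos(α − θ))
    k = SID · z            / (SAD − ρ cos(α − θ))

Over a rotation a stationary marker traces a closed elliptical curve in
(j, k) — its sinogram.  The pipeline is:

1. **Track** (jm, km) per frame by zero-normalized cross-correlation against
   a template cut from one projection, with subpixel peak refinement,
   robust outlier flagging and cubic gap interpolation (markers leave the
   field of view in roughly half the views of a half-fan scan).
2. **Fit** the stationary spherical coordinates (r, α, β) by damped least
   squares of the sinogram model to the track (coarse grid initialization
   avoids local minima); the fitted track (js, ks) is the parallax-only
   component.
3. **Decompose** the residuals (Δj, Δk) = (jm − js, km − ks) into
   patient-frame displacements (Δx′, Δy′, Δz′) by inverting the projection
   per frame, and summarize each axis with A·sin(2πf·t − δ).
4. **Correct**: shift every pixel of frame θ by (u, v) = (Δj, Δk),
   i.e. I′(js, ks, θ) = I(jm − u, km − v, θ), then reconstruct with a
   Feldkamp (FDK) filtered back-projection and quantify the artifact
   reduction with centroid and 20–80% edge-width metrics.

At clinical geometry (SAD 100 cm, SID 150 cm, 40 cm/1024 px panel) one
detector pixel is 0.26 mm at the isocenter, so the tracker's ±0.5 px
precision is ±0.13 mm of motion.

## Worked example

Simulate the reference moving-platform protocol — a seed marker at
(r, α, β) = (10 cm, 40°, 90°) oscillating 1.75 cm along Z at 15 cycles/min —
and recover the motion from the projections alone:

```python
import numpy as np
import cbmotion as cb

geom = cb.ScanGeometry.reduced()                      # 256x192 panel, 360 views / 60 s
waveform = cb.MotionWaveform.from_cycles_per_min(az_cm=1.75, fz_cpm=15.0)
rest = cb.PatientPoint.from_spherical(10.0, np.deg2rad(40.0), np.deg2rad(90.0))
marker = cb.MarkerSpec(rest=rest, waveform=waveform, marker_id="m0")
stack = cb.generate_scan([marker], geom, seed=1)      # noisy 16-bit projections

first = stack.truth[stack.truth.in_fov].iloc[0]       # place the template ROI
k, j = int(round(first.k_px)), int(round(first.j_px))
template = cb.extract_template(stack, int(first.frame), (k - 8, k + 9, j - 8, j + 9))
track = cb.interpolate_gaps(cb.flag_outliers(cb.track_stack(stack, template)))

fit = cb.fit_stationary(track, geom)
print(f"stationary fit: r = {fit.r_cm:.3f} cm, alpha = {np.rad2deg(fit.alpha_rad):.2f} deg, "
      f"beta = {np.rad2deg(fit.beta_rad):.2f} deg")

trace = cb.fit_trace(cb.to_patient_displacements(track, fit, geom))
z = trace.fits["z"]
print(f"Z motion: A = {z.amplitude_cm:.4f} cm, f = {z.freq_cpm:.3f} cycles/min, "
      f"delta = {z.phase_rad:.3f} rad (rms {z.rms_cm*10:.3f} mm)")
```

Output:

```
stationary fit: r = 10.000 cm, alpha = 40.00 deg, beta = 89.76 deg
Z motion: A = 1.7500 cm, f = 15.000 cycles/min, delta = 6.283 rad (rms 0.056 mm)
```

The fitted rest position matches the configured marker, and the recovered
amplitude and frequency reproduce the platform settings; the 0.06 mm fit
rms is the tracking noise floor mapped to the isocenter.  The phase 2π ≡ 0
matches the injected δ = 0.

The same workflow is available from the shell:

```sh
cbmotion simulate --config run.yaml --out run/
cbmotion track --stack run/stack.tif --marker m0 --out run/track.csv
cbmotion extract --track run/track.csv --geometry run/stack_geometry.yaml --out-prefix run/m0
cbmotion correct --stack run/stack.tif --track run/track.csv --out run/corrected.tif
cbmotion reconstruct --stack run/corrected.tif --out run/volume.nii
cbmotion report --rundir run/
```

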