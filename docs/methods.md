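# Methods

This note records the models, conventions, parameter choices and
limitations behind `cbmotion`.  Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Projection geometry

The patient frame is fixed with origin at the isocenter and Z along the
superior–inferior axis.  The source moves on a circle of radius SAD in the
X–Y plane; at gantry angle θ it sits at S(θ) = SAD·(sin θ, cos θ, 0), i.e.
on +Y at θ = 0, moving toward +X with increasing θ.  The in-plane polar
angle of a point is α = atan2(x, y) (quadrant-safe), β is the angle from
+Z, ρ = r·sin β.  A pinhole ray through the point hits the flat detector
(perpendicular to the central ray at distance SID from the source) at

    d = SAD − ρ·cos(α − θ)        (depth along the central ray, must be > 0)
    j = SID·ρ·sin(α − θ) / d
    k = SID·z / d

Both equations share the same depth denominator — the single-ray
(self-consistent) form.  Consequences used throughout: the isocenter maps
to (0, 0) in every view; a purely axial point has constant k = SID·z/SAD;
the magnification of lengths at the isocenter is SID/SAD, so the detector
pixel pitch demagnified to the isocenter is `pitch · SAD/SID` (0.26 mm for
the clinical 40 cm/1024 px panel, hence 0.5 px ≙ 0.13 mm).

The sense of rotation is an internal convention with no observable
consequence — every stage (simulation, fitting, correction, FDK) shares
it, and only differences of detector positions enter the outputs.

Detector coordinates are continuous cm with origin on the central ray;
pixel indices are 0-based with pixel centers at (index + 0.5)·pitch −
half-width.  Files store degrees, seconds and pixels; the API uses radians
and cm internally.

## Synthetic acquisitions

The simulator emulates a clinical on-board imager: 650 frames over 360° in
60 s on a 1024×768, 16-bit panel (`ScanGeometry.clinical()`), and a reduced
geometry for fast tests — same physical panel sampled at 256×192 with 360
frames over 60 s (`ScanGeometry.reduced()`).  The reference phantom
protocol drives a seed marker (1 mm diameter × 2 mm length) sinusoidally
along Z with 1.75 cm amplitude at 15 cycles/min, a realistic breathing
excursion and rate.  Waveforms are per-axis A·sin(2πf·t − δ) with optional
linear drift and dropout windows (crude irregular breathing); frequencies
can be given in Hz or cycles/min — the latter is the physiological
convention.

Markers are rendered as dark anisotropic Gaussian blobs on a uniform
background (default 3000 counts) with additive Gaussian noise (default
σ = 50): σ of the blob is the physical half-size magnified to the
detector, floored at 1 px so the footprint stays trackable.  This is *not*
a ray-traced cylinder: there is no orientation-dependent footprint, no
scatter, bowtie filter, beam hardening or anatomical texture.  Passing
tests therefore demonstrate the pipeline's geometric and numerical
correctness on compact high-contrast shadows, not robustness to low
contrast or structured clutter in patient images.  The ground-truth table
stores the exact pinhole projection of every marker in every frame, which
is what all accuracy tests compare against.  All randomness flows from one
mandatory seed; identical configuration gives bit-identical stacks.

## Tracking

Zero-normalized cross-correlation (ZNCC) of a template patch against each
frame; the score is invariant under affine intensity rescaling and lies in
[−1, 1].  The integer peak is refined by a 1D quadratic fit to the 3×3
score neighborhood per axis (offsets clipped to ±0.5 px).  Two details
matter for accuracy:

* **Template centroid calibration.**  An ROI cut on the integer grid puts
  the marker's subpixel centroid off the patch center, which would bias
  every reported position by a constant of up to 0.5 px.  The template
  therefore stores its attenuation-weighted centroid offset and matches
  are reported relative to the marker centroid.  With it, noise-free
  tracking error on the reference scan is ~0.03 px; the method's working
  claim remains the conservative ±0.5 px.
* **Search-window propagation.**  Each frame is searched in a window
  centered on the last accepted position (default half-width twice the
  template extent, i.e. a 4× template window); the first frame uses the
  whole image or a user seed.  Scores below threshold (default 0.5) or
  peaks on the window border give status `missing` — this is how markers
  that leave the field of view are handled, and the window parked at the
  exit edge reacquires them on re-entry.

**Outlier flagging** relabels detected points whose residual from a
centered moving median exceeds n·(1.4826·MAD) on either axis (n = 5).  The
window is 5 frames: at the study frame rates a breathing period is ~24–43
frames, so a window must stay well below half a period for the median to
follow the motion extrema (an 11-frame window misses them and flags large
parts of a clean track).  The MAD scale is floored at the 0.5 px
localization precision so smooth-track curvature is never flagged, and
partial windows at the scan ends are excluded.

**Gap interpolation** fills interior missing/outlier frames on jm(t) and
km(t) with a cubic spline through the detected points — the robust
realization of piecewise polynomial prediction of cyclic breathing.  Gaps
whose bracketing detections are more than `max_gap_s` apart (default 5 s)
stay missing, and leading/trailing gaps are never extrapolated: breathing
is predictable inside the cycle, sudden relaxation is not.

## Stationary fit and motion decomposition

The stationary coordinates (r, α, β) minimize
Σ w·[(jm − js)² + (km − ks)²] (pixels) over usable points, where (js, ks)
is the sinogram model above.  Interpolated points get cost weight 0.5 —
they carry information but are model predictions, not measurements.
Initialization is a coarse grid (α every 10°, β 10–170° every 10°,
r 1–25 cm every 2 cm); the damped least-squares refinement (bounded
trust-region) is asserted never to end worse than its starting node, and a
dense-grid oracle in the tests confirms the optimum.  Identifiability
guards: ≥ 10 usable points spanning ≥ 90° of gantry arc (a short arc
cannot separate r, α, β).  The isocenter track is degenerate — the fit
returns r ≈ 0 with α, β arbitrary, which is correct and harmless since
the fitted *track* is what downstream stages consume.

**Monoscopic inversion.**  A single view measures two numbers (j, k) but a
displacement has three components, so per-frame decomposition needs an
assumption.  The in-plane inversion uses the *fitted* α: ρ(j) =
SAD·j / (SID·sin(α−θ) + j·cos(α−θ)), i.e. in-plane displacement is
resolved along the marker's radial direction, and z = k·d/SID with the
depth implied by that ρ.  This is exact for superior–inferior motion
(the dominant respiratory axis, and the phantom protocol) and for
in-plane motion along the radial direction; an in-plane component
transverse to it is a genuine blind spot of monoscopic imaging and is
*not* recoverable per frame.  Views with |sin(α − θ)| < sin(3°) are
blind for the in-plane axes: there the inversion would amplify tracking
noise by ~1/sin, so dx/dy are set to NaN (excluded from fits) and z uses
the stationary depth.  Frames whose inverted depth is non-positive are
dropped with a flag.  The detector-frame residuals (Δj, Δk) do not involve
any of this and are always available.

**Sinusoid fits** d(t) = A·sin(2πf·t − δ) are solved by a linear
sine/cosine solve at the dominant spectral frequency (signal resampled to
a uniform grid for the FFT seed) followed by joint nonlinear refinement of
(a, b, f).  A is canonicalized ≥ 0 and δ to [0, 2π); a flat signal returns
A = 0 with f undefined and a flag.  Fits with fewer than two sampled
periods warn.  Track correlation resamples two traces onto a common
uniform timebase and reports the zero-lag Pearson r, the lag maximizing
the cross-correlation, and δa − δb from the per-trace fits.

**Gantry sag**: a user-supplied per-θ table of (Δj, Δk) shifts is linearly
interpolated and subtracted from the track before fitting; the package
does not measure sag itself.

## Correction and reconstruction

Correction is a rigid per-frame translation: every pixel of frame θ is
shifted by the tracked marker's (u, v) = (Δj, Δk), bilinear resampling
with edge padding (integer shifts are exact).  Frames without an estimate
get shifts linearly interpolated in time (endpoints held) and are flagged;
at least half the frames must carry estimates.  The rigid-body assumption
is accurate for the region moving with the marker — which is why the seed
is implanted in or near the lesion; differential multi-ROI correction is
out of scope.  Because the detector shift of a point depends on its depth,
correcting with a marker far from the object of interest leaves residual
motion proportional to the depth mismatch.

FDK reconstruction: −log(I/I₀) line integrals (I₀ estimated from the
frame border or given), cosine ray-weighting, row-wise ramp filter with
Hann apodization (FFT, zero-padded to the next power of two), voxel-driven
back-projection with (SAD/d)² weighting and bilinear sampling.  Full-fan
circular orbit only; absolute CT numbers are not calibrated.  Image
quality is summarized by the intensity-weighted centroid error (voxels
above half the background-subtracted maximum) and the mean 20–80%
edge-spread width of a profile through the object; the Gaussian-blurred
edge width is validated against the closed-form normal-CDF value
(1.683σ).

## Problem sizes and defaults

| Quantity | Default | Why |
| --- | --- | --- |
| SAD / SID | 100 / 150 cm | clinical on-board-imager geometry |
| Panel | 40×30 cm², 1024×768 px (clinical), 256×192 (reduced) | reduced grid keeps full pipeline runs at seconds while leaving blobs ≥ 2×2 px |
| Schedule | 650 frames/60 s (clinical), 360/60 s (reduced) | one gantry rotation per minute |
| Phantom protocol | 1.75 cm, 15 cycles/min along Z | realistic breathing excursion and rate |
| Background / contrast / noise σ | 3000 / 1200 / 50 counts | high-contrast seed shadow, SNR comparable to kV projections |
| NCC threshold / window | 0.5 / 4× template | rejects background matches; tolerates inter-frame motion |
| Outlier rule | median window 5, n = 5, scale floor 0.5 px | see Tracking |
| Gap limit | 5 s | about one breathing period |
| Blind-spot guard | 3° | keeps 1/sin noise amplification below ~20× |
| Stationary-fit grid | α×β×r = 36×17×13 | coarse enough to be fast, fine enough to land in the global basin |
| Reconstruction | 64³ voxels, 0.15–0.2 cm | artifact comparisons, not diagnostic resolution |

Tests and the acceptance script use the reduced geometry (360 or fewer
views, 256×192 panel, 24³–64³ volumes), which keeps the full suite around
half a minute; the clinical geometry is available unchanged via
configuration.

## Known limitations

* Per-frame in-plane displacement transverse to the marker's radial
  direction is unobservable monoscopically; traces of markers whose
  motion is strongly non-radial in-plane will under- or mis-report those
  components (superior–inferior motion is unaffected).
* The simulator's Gaussian-blob markers omit orientation effects, scatter
  and anatomical clutter; tracking robustness on patient data is a
  claim the synthetic tests cannot make.
* One marker corrects the whole frame; anatomy moving differently from
  the marker retains its motion.
* Half-fan offset-detector reconstruction, phase-sorted (4D) binning,
  scatter/bowtie physics and vendor-format ingestion are out of scope.
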