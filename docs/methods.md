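# Methods

This note documents the models implemented in `exmkit`, the defaults that
matter, what the synthetic data does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Coordinate and unit conventions

Images use 0-based pixel indices with pixel centers at integer coordinates,
x = column, y = row, y increasing downward. Pixel sizes are stored in
nanometers. Lengths are reported at **biological scale** — expanded-space
measurements divided by the linear expansion factor (EF) — whenever an EF is
supplied; every biological-scale number is reported alongside the EF used.

## Blinking-emitter model (synthgen)

Each emitter is an isotropic 2D Gaussian PSF parameterized by FWHM
(FWHM = 2√(2 ln 2)·σ ≈ 2.3548 σ), with a two-state ON/OFF telegraph process
for its brightness. The telegraph is **continuous-time** with exponential
dwell times (means `mean_on_frames`, `mean_off_frames`, in frame units) and
is integrated over each unit frame, as a camera exposure would. This choice
matters: a frame-discrete Markov chain with on-fraction 1/2 and mean dwell
2 frames has exactly zero lag-1 autocorrelation (its eigenvalue is
1 − 1/2 − 1/2 = 0), which would make lag-1 cross-correlation SOFI vanish for
fast blinkers; the integrated continuous-time process has lag-1 covariance
p(1−p)·τ_c²(1−e^(−1/τ_c))² > 0 with τ_c = 1/(1/mean_on + 1/mean_off), and
its frame variance p(1−p)·2(x−1+e^(−x))/x², x = 1/τ_c, both available in
closed form (`telegraph_frame_variance`, `telegraph_frame_lag1_cov`) and
used as test oracles. Default dwell times are 20/20 frames — slow blinking
for which the frame-integrated variance is within 4% of the Bernoulli limit
p(1−p)A². Fluorophore photophysics are free parameters of the simulation,
not literature values.

Movies add, in order: static background, exponential bleaching, per-frame
linear drift of emitter positions, Poisson shot noise, Gaussian read noise,
and a clamp at zero. Defaults: 100 frames (within the usual 50–100-frame
SOFI acquisition range), no background, no bleaching, no drift, shot noise
on. The generator is seed-deterministic and returns per-frame integrated ON
fractions as ground truth.

What the generator does **not** emulate: vectorial or depth-varying PSFs,
refractive-index mismatch, sCMOS fixed-pattern noise, emitter photobleaching
heterogeneity, or 3D PSF structure. Passing tests therefore demonstrate
estimator correctness under the stated model, not robustness to every
instrumental artifact of real acquisitions.

## SOFI reconstruction (sofi)

Fixed stage order: drift correction → intensity correction → optional crop →
second-order cross-cumulant → distance-factor flattening → Richardson–Lucy
deconvolution. The pipeline is deterministic given the stack.

**Drift correction** phase-correlates every frame against the temporal mean
with 10× subpixel upsampling. Because the mean of a drifting movie is
motion-smeared — which systematically shrinks per-frame estimates by
~15–20% for typical scenes — estimation is iterated (3 passes) against the
progressively sharpened mean; shifts at the upsampling quantization floor
are treated as zero so that estimator jitter on blinking data does not
accumulate. Featureless movies are returned unchanged with a warning.

**Intensity correction** offers per-frame mean equalization
(`global_mean`, preserving the first frame's scale) and exponential
detrending (`exp_fit`, log-linear fit to the frame means). The pipeline
default is `exp_fit`: mean equalization would flatten the very blinking
fluctuations the cumulant needs when a few emitters dominate the frame
mean, whereas a fitted exponential removes only the slow bleaching trend.
If frames are empty (all-zero) the pipeline skips the stage with a log
entry rather than failing.

**Cross-cumulant.** For lag τ ≥ 1 the symmetrized cross-covariance
½⟨δF(r₁,t)δF(r₂,t+τ) + δF(r₂,t)δF(r₁,t+τ)⟩ is computed for every pixel with
itself (physical sites) and for horizontal, vertical and diagonal
nearest-neighbor pairs, assigned to pair midpoints to form a (2Y−1)×(2X−1)
virtual grid with half the pixel pitch. Diagonal midpoints average their
two contributing pairs — a deterministic, symmetric tie-break. The default
lag of 1 frame (never 0) makes delta-correlated shot noise cancel in
expectation; the residual estimator bias from mean subtraction is −var/T,
and the estimator SD over a background region is ≈ var/√(T−1), both
verified by simulation. 3D stacks are processed as per-plane 2D movies
(planes are acquired as separate time series, so cross-plane temporal
correlation is undefined).

**Flattening.** A cross-cumulant between pixels separated by d carries the
analytic attenuation exp(−d²/4σ²) relative to an auto-cumulant (product of
two Gaussians); each virtual-pixel class is divided by its factor
(`analytic_gaussian`, requires the optical σ) or by the measured class-mean
ratio (`self_calibrated`). Raw cumulants are preserved; negative values are
clamped to zero only immediately before deconvolution, keeping estimator
diagnostics intact.

**Deconvolution** is Richardson–Lucy (via scikit-image's multiplicative
update, wrapped with input clamping and PSF normalization) using the
cumulant-domain PSF: optical σ/√2, i.e. σ·√2 in virtual-pixel units.
Default 50 iterations — enough for the ≥2× total resolution gain on point
sources while remaining stable under 100-frame estimator noise. Resolving
borderline point pairs benefits from more (the test suite uses up to 500);
with only 100 frames the outcome for a *single* emitter pair is
seed-dependent, because chance correlation between the two emitters' blink
trajectories perturbs the tiny cumulant dip — the suite therefore asserts
the median over seeds.

## Registration and distortion (regdist)

**Keypoints** are SIFT (scikit-image), matched by mutual nearest descriptor
with a Lowe ratio test (default 0.8). **RANSAC** draws 2-point minimal
samples (two point pairs determine a similarity), scores by inlier count
(default tolerance 2 px in the post frame, 5000 iterations, early exit on a
perfect consensus, min 10 inliers), and refits the consensus set with the
closed-form least-squares similarity (Umeyama/Procrustes, implemented here
and cross-checked against scikit-image in the tests). Fixed seeds make runs
bit-reproducible.

**z-projection matching** evaluates every contiguous window of 8–25 planes
(maximum-intensity projection by default, mean available), scores each by
RANSAC-inlier count against the pre-expansion plane, and returns the
argmax; ties break toward the smaller window, then the lower start index.

**Distortion fields** are estimated on a regular node grid (spacing =
block_size/2, PIV-style 50% overlap) by normalized cross-correlation of
local blocks for the integer displacement, refined to sub-pixel accuracy by
a gradient-based (Lucas–Kanade) least-squares step with a Gaussian center
weight (σ = block/4). The center weight keeps each node's estimate local —
unweighted block matching attenuates displacement variation across the
block by a sinc factor. Because even the weighted estimate is a local
average, the field is refined iteratively (default 3 passes): the current
field is spline-interpolated, the aligned image unwarped by it, and the
residual re-estimated and accumulated; the attenuated remainder shrinks
geometrically. Low-texture nodes (block SD < 10⁻³ of the dynamic range) are
masked invalid. A non-rigid registrar can be substituted for this estimator
behind the same `DistortionField` interface.

**RMS error curves** sample random valid-node pairs (default 10⁵), take the
Euclidean norm of the displacement-vector difference per pair — so any
global translation cancels exactly — and bin by pair separation converted
to biological scale (separation · pixel_nm / EF). Bins with fewer than 50
pairs are flagged invalid rather than reported as zero. If the field is
already in the pre-expansion frame, callers pass the pre pixel size and
EF = 1. For i.i.d. node vectors of per-component SD σ the curve converges
to 2σ (E|v₁−v₂|² = 4σ²), the test oracle. Note that the similarity fit
legitimately absorbs the similarity-like component of any real distortion
field; recovered fields are compared to ground truth through their RMS
curves, which are insensitive to that absorbed translation component and
dominated by genuine local distortion.

## Morphometry

**Nuclear EF**: images are thresholded (Otsu by default; ties resolved by
scikit-image's standard implementation), binarized, labeled with
8-connectivity, area-filtered; EF = √(mean post area / mean pre area).
Areas are 2D section areas in px² (µm² when a pixel size is known).
**Feature EF**: mean of per-pair post/pre distance ratios, with the ratio
spread reported. **Retention**: (post ROI mean − post background)·EF³ /
(pre ROI mean − pre background); background defaults to the per-image
histogram mode, a fixed value is accepted; negative numerators clip to 0,
values above 1 are reported unclipped with a flag. **Radial profiles**
refine the center by intensity centroid, azimuthally average on 0.5 px
radial steps, and detect angular peaks on the circle at the radial-peak
radius with prominence 0.2× the profile's dynamic range and periodic
wrap-around. **Peak-to-peak distances** interpolate a transect (cubic),
find the two most prominent maxima, and refine each with a 3-point
parabolic fit. **Pair distances** detect puncta per channel, pair them by
mutual nearest neighbor within a pairing radius, and measure
center-to-center (intensity centroid by default; optional 2D Gaussian fit
for sub-0.05 px accuracy on clean puncta) or edge-to-center, where the
edge is the 50% of-peak crossing of the first channel's profile along the
inter-punctum axis (the threshold is exposed).

## Resolution estimation

`decorrelation_resolution` implements the parameter-free decorrelation
algorithm: the mean-subtracted image is cosine-apodized (edge fraction 0.1)
to suppress FFT leakage; the decorrelation curve
d(r) = Σ_{|k|<r}|F| / (√(Σ|F|²)·√N_{|k|<r}) is evaluated at 50 mask radii
for the raw spectrum and 10 log-spaced Gaussian high-pass strengths; the
cutoff k_c is the largest interior peak radius across curves, and
resolution = 2·pixel/k_c (Nyquist floor 2·pixel). Pure noise or constant
images have no interior peak and raise "resolution undefined" rather than
returning a number. `effective_resolution` is the arithmetic
diffraction limit / EF / SOFI factor (factor 2 for second-order SOFI with
deconvolution), rounded to whole nanometers with the unrounded value also
returned; (NA, wavelength) inputs convert via the Rayleigh criterion
0.61·λ/NA.

## Defect scoring and statistics

A cross-section is *normal* iff exactly nine outer subunits and two central
subunits are counted; "nine pairs" is operationalized as nine resolvable
outer intensity maxima (a doublet counts as one peak at the package's
working resolution). Outer counts come from the angular profile at the
outer-ring radius; central counts from local maxima within the central disk
(half the ring radius by default). Images the profiler cannot measure are
tallied as *unscorable*, never classified — the normal/defective criterion
presupposes countable subunits. The Pearson chi-square statistic
Σ(O−E)²/E is computed directly (df = (r−1)(c−1), p from the upper tail),
with expected counts below 5 flagged; no continuity correction by default
(Yates available as a flag for 2×2 tables); α = 0.05.

## Problem sizes and tolerances in the test suite

Simulations are sized for quick, repeatable runs on one core: 33²–64²
pixel movies of 100 frames for SOFI checks (10⁴ frames only for closed-form
statistics at tight tolerance), 128²–256² templates for registration
(post-expansion images up to ~1056² at EF 11), 20 seeds for the stochastic
medians, 10⁵ sampled pairs for RMS-curve oracles. Tolerances follow the
statistic being tested: exact arithmetic to machine precision, closed-form
statistics to 2–5%, stochastic recoveries to the sampling error of the
configured run.

## Known limitations

* Only second-order cumulants are implemented; the order parameter is
  reserved in the interface but higher orders (and their brightness
  nonlinearity) are out of scope.
* Cross-cumulants are computed within z-planes; volumetric stacks are
  reconstructed plane by plane.
* The distortion estimator assumes locally smooth fields; displacement
  discontinuities (tears) violate the block model and will be smoothed.
* Decorrelation estimates on very small images (< 64 px) are refused; on
  highly anisotropic content the radially averaged cutoff is a compromise.
* The synthetic scenes are 2D; axial expansion isotropy is not modeled.
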