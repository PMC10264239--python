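# exmkit

Quantification and validation toolkit for **expansion microscopy (ExM)**
combined with **super-resolution optical fluctuation imaging (SOFI)**.

Expansion microscopy physically magnifies a specimen embedded in a swellable
hydrogel by a linear **expansion factor (EF)** of roughly 4–11×, so that a
conventional diffraction-limited microscope resolves nanoscale structure.
Validating such data raises a recurring set of quantitative questions that
this package answers with tested, reusable code:

* **How sharp is the reconstruction?** Second-order cross-correlation SOFI
  computes temporal cumulants of blinking-fluorophore movies; the cumulant
  PSF is the optical PSF squared (Gaussian width /√2), and Richardson–Lucy
  deconvolution pushes the combined gain to ≥ 2×. Achieved resolution is
  estimated parameter-free by decorrelation analysis
  (resolution = 2·pixel/k_c from the peak of Fourier decorrelation curves).
* **How faithful is the expansion?** Pre- and post-expansion images are
  related by a similarity transform p_post = s·R(θ)·p_pre + t whose scale
  *s* is the EF. SIFT keypoints filtered by RANSAC estimate it; residual
  distortion is measured as a displacement vector field and summarized as an
  **RMS length-measurement-error curve**: RMS of |v(p₁) − v(p₂)| over point
  pairs, binned by biological-scale separation.
* **How much signal survives?** Retention = background-subtracted
  post-expansion ROI mean × EF³ / pre-expansion ROI mean, correcting the
  volumetric dilution of fluorophores in the swollen gel.
* **Is the biology intact?** Motile-cilium axonemes are scored against the
  canonical "9+2" architecture (nine outer microtubule doublets, one
  central pair); normal/defective proportions across conditions are compared
  by Pearson chi-square.

Because public raw image data for such studies is typically unavailable,
the package ships a first-class synthetic-data module (`exmkit.synthgen`)
that generates every input with known ground truth: blinking-emitter movies
(telegraph photokinetics, Gaussian PSF, Poisson noise), warped expansion
pairs, nuclei fields, 9+2 ring structures, two-channel punctum pairs, and
retention pairs. Every analysis stage is validated against these truths.

## Worked example

```python
import numpy as np
from exmkit import synthgen, sofi, regdist, morphometry, resolution

# SOFI on a simulated blinking movie (one emitter, 100 frames)
em = synthgen.EmitterField([[16.0, 16.0]], [2000.0], 0.5, 5.0, 5.0, seed=0)
movie, _ = synthgen.gen_blinking_movie(em, psf_fwhm_nm=300, pixel_nm=100,
                                       shape=(33, 33), frames=100, seed=0)
img, log = sofi.sofi_pipeline(movie, psf_fwhm_nm=300)
fwhm_mean = morphometry.fit_gaussian_fwhm(movie.mean_image(), window=8)
fwhm_sofi = morphometry.fit_gaussian_fwhm(img, window=12) / 2  # virtual px
print(f"mean-image FWHM: {fwhm_mean*100:.0f} nm")
print(f"SOFI+RL FWHM:    {fwhm_sofi*100:.0f} nm (gain {fwhm_mean/fwhm_sofi:.1f}x)")

# Expansion factor from a registered pre/post pair
tpl = synthgen.blob_template((128, 128), n_blobs=70, sigma_range=(1.2, 2.5), seed=3)
warp = synthgen.GroundTruthWarp(scale=8.5, rotation_deg=3.0, translation=(12.0, -7.0))
pre, post, _ = synthgen.gen_expansion_pair(tpl, warp)
t, aligned, matches, inliers = regdist.register_expansion_pair(pre, post, seed=0)
print(f"estimated EF: {regdist.ef_from_transform(t):.3f}")

# Theoretical effective resolution: 280 nm optics, 11x expansion, SOFI factor 2
spec = resolution.EffectiveResolutionSpec(diffraction_limit_nm=280, ef=11,
                                          sofi_order_factor=2)
print(f"effective resolution: {resolution.effective_resolution(spec)[0]} nm")
```

prints

```
mean-image FWHM: 300 nm
SOFI+RL FWHM:    74 nm (gain 4.1x)
estimated EF: 8.524
effective resolution: 13 nm
```

The mean image reproduces the 300 nm optical PSF; the SOFI + deconvolution
reconstruction narrows the same emitter to 74 nm (the √2 cumulant gain plus
deconvolution sharpening). Registration recovers the planted 8.5× expansion
to 0.3%, and the effective-resolution arithmetic (diffraction limit / EF /
SOFI factor) yields 13 nm for 280 nm optics at 11-fold expansion.

A command-line surface wraps the same functionality:

```bash
exmkit simulate ring --seed 5 --out scene/      # synthetic scenes + truth JSON
exmkit sofi movie.tif --psf-fwhm-nm 300         # SOFI reconstruction
exmkit register pre.tif post.tif                # similarity EF estimate
exmkit chisq 90,10 60,40                        # Pearson chi-square
exmkit run pipeline.yaml                        # config-driven reproducible run
```

## Layout

| module | contents |
|---|---|
| `exmkit.synthgen` | ground-truth scene generators |
| `exmkit.sofi` | drift/intensity correction, cross-cumulants, flattening, Richardson–Lucy |
| `exmkit.regdist` | SIFT + RANSAC similarity registration, distortion fields, RMS curves |
| `exmkit.morphometry` | nuclear segmentation, EF and retention estimation, profiles, pair distances |
| `exmkit.resolution` | decorrelation resolution estimation, effective-resolution arithmetic |
| `exmkit.defectstats` | axoneme 9+2 scoring, Pearson chi-square |
| `exmkit.io` / `exmkit.cli` | TIFF + sidecar I/O, config-driven runs, CLI |

See `docs/methods.md` for the models, parameter choices and limitations.
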