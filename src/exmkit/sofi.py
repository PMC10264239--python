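"""Fluctuation-based super-resolution reconstruction (second-order SOFI).

Super-resolution optical fluctuation imaging exploits the independent
temporal blinking of fluorophores: the second-order temporal cumulant of a
movie is proportional to the *square* of the PSF at each emitter, shrinking
its Gaussian width by 1/sqrt(2), while any temporally uncorrelated
contribution (static background, shot noise at nonzero lag) has zero
expected cumulant.  Cross-cumulants between neighboring pixels are assigned
to their midpoints, doubling the sampling grid; their pair-distance
attenuation is removed by "distance-factor" flattening, and the result is
sharpened further by Richardson–Lucy deconvolution with the cumulant-domain
PSF.

The processing order is fixed: drift correction -> intensity correction
(-> crop) -> cross-cumulant -> flattening -> deconvolution.  The whole
pipeline is deterministic given the input stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.restoration import richardson_lucy as _skimage_rl


@dataclass
class BlinkingMovie:
    """A T x Y x X stack of nonnegative photon counts with pixel metadata."""

    data: np.ndarray
    pixel_nm: float
    exposure_ms: float = 100.0
    z_index: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be T x Y x X")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in movie")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def mean_image(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class CumulantImage:
    """Second-order cross-cumulant image on the 2x virtual-pixel grid.

    ``data`` has shape (2Y-1, 2X-1): even/even sites are physical pixels
    (lagged auto-covariance), even/odd and odd/even sites are horizontal and
    vertical nearest-neighbor cross-covariances at the pair midpoint, odd/odd
    sites average the two diagonal pairs sharing that midpoint.  Values may
    be negative before clamping; the effective pixel pitch is halved.
    """

    data: np.ndarray
    pixel_nm_effective: float
    order: int = 2
    lag: int = 1
    flattened: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("cumulant image must be 2D")


def correct_drift(movie: BlinkingMovie, reference: str = "mean",
                  upsample: int = 10, passes: int = 3):
    """Estimate and remove per-frame translational drift.

    Each frame is phase-correlated (with sub-pixel upsampling) against the
    reference image — the temporal mean by default, which is robust for
    blinking data — and shifted back via Fourier translation.  Because a
    drifting movie's mean is motion-smeared (which shrinks the estimated
    shifts), estimation is repeated against the progressively sharper mean
    of the corrected movie for ``passes`` rounds, accumulating the shifts.
    Featureless (flat) movies are returned unchanged with a warning and
    zero shifts.

    Returns ``(corrected_movie, shifts)`` with shifts of shape (T, 2) in
    (row, col) pixels: the translation applied to each frame to register it
    to the reference.
    """
    data = movie.data
    n = data.shape[0]
    shifts = np.zeros((n, 2))
    if n == 1:
        return movie, shifts
    ref0 = data.mean(axis=0) if reference == "mean" else data[0]
    if ref0.std() == 0:
        warnings.warn("featureless movie: drift estimate unreliable, "
                      "returning input unchanged")
        return movie, shifts
    cur = data
    for p in range(max(passes, 1)):
        ref = cur.mean(axis=0) if reference == "mean" else cur[0]
        new = np.zeros((n, 2))
        for t in range(n):
            if data[t].std() == 0:
                continue
            s, _, _ = phase_cross_correlation(ref, cur[t],
                                              upsample_factor=upsample,
                                              normalization=None)
            # shifts at the quantization floor are indistinguishable from
            # estimator jitter on blinking data; treat them as zero
            if np.hypot(*s) > 1.0 / upsample:
                new[t] = s
        shifts = shifts + new
        if np.abs(new).max() < 0.5 / upsample and p > 0:
            break
        cur = np.empty_like(data)
        for t in range(n):
            if np.allclose(shifts[t], 0):
                cur[t] = data[t]
            else:
                cur[t] = np.fft.ifftn(
                    ndimage.fourier_shift(np.fft.fftn(data[t]),
                                          shifts[t])).real
    out = np.clip(cur, 0, None)
    corrected = BlinkingMovie(out, movie.pixel_nm, movie.exposure_ms,
                              movie.z_index)
    return corrected, shifts


def correct_intensity(movie: BlinkingMovie, method: str = "global_mean"):
    """Equalize per-frame intensity (bleaching / lamp fluctuation removal).

    ``global_mean`` rescales every frame to the first frame's mean;
    ``exp_fit`` fits an exponential decay to the frame means by log-linear
    least squares and divides out the fitted trend (unit gain at frame 0).
    The first-frame scale is preserved by both methods.
    """
    data = movie.data
    means = data.mean(axis=(1, 2))
    if method == "global_mean":
        if np.any(means <= 0):
            raise ValueError("empty frame: zero mean intensity")
        gain = means[0] / means
    elif method == "exp_fit":
        t = np.arange(len(means))
        pos = means > 0
        if pos.sum() < 2:
            raise ValueError("empty frame: zero mean intensity")
        slope, intercept = np.polyfit(t[pos], np.log(means[pos]), 1)
        gain = np.exp(-slope * t)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = data * gain[:, None, None]
    return BlinkingMovie(out, movie.pixel_nm, movie.exposure_ms, movie.z_index)


def _lagged_cov(a: np.ndarray, b: np.ndarray, lag: int) -> np.ndarray:
    """Symmetrized lag-tau cross-covariance of two mean-subtracted series
    (T, ...): mean over t of (a_t b_{t+lag} + b_t a_{t+lag})/2."""
    if lag == 0:
        return (a * b).mean(axis=0)
    x = a[:-lag] * b[lag:]
    y = b[:-lag] * a[lag:]
    return 0.5 * (x + y).mean(axis=0)


def xc_sofi2(movie: BlinkingMovie, lag: int = 1) -> CumulantImage:
    """Second-order cross-correlation SOFI on the 2x virtual-pixel grid.

    For every physical pixel the lag-tau auto-covariance is computed (lag >= 1
    so that delta-correlated shot noise cancels in expectation); for every
    horizontal/vertical nearest-neighbor pair the cross-covariance is placed
    at the pair midpoint; each diagonal midpoint averages its two diagonal
    pairs.  Output shape (2Y-1, 2X-1); deterministic.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    data = movie.data
    T, ny, nx = data.shape
    if T < lag + 2:
        raise ValueError(f"need at least lag+2={lag + 2} frames, got {T}")
    d = data - data.mean(axis=0)
    out = np.zeros((2 * ny - 1, 2 * nx - 1))
    # physical sites: lagged auto-covariance
    out[::2, ::2] = _lagged_cov(d, d, lag)
    # horizontal midpoints
    out[::2, 1::2] = _lagged_cov(d[:, :, :-1], d[:, :, 1:], lag)
    # vertical midpoints
    out[1::2, ::2] = _lagged_cov(d[:, :-1, :], d[:, 1:, :], lag)
    # diagonal midpoints: average of the two pairs sharing the site
    d1 = _lagged_cov(d[:, :-1, :-1], d[:, 1:, 1:], lag)
    d2 = _lagged_cov(d[:, :-1, 1:], d[:, 1:, :-1], lag)
    out[1::2, 1::2] = 0.5 * (d1 + d2)
    return CumulantImage(out, pixel_nm_effective=movie.pixel_nm / 2.0, lag=lag)


def distance_factors(psf_sigma_px: float) -> dict:
    """Analytic attenuation of each virtual-pixel class for a Gaussian PSF.

    A cross-cumulant between pixels separated by d carries a factor
    exp(-d^2 / (4 sigma^2)) relative to the auto-cumulant (product of two
    Gaussians identity); d = 1 px for horizontal/vertical neighbors and
    sqrt(2) px for diagonals.
    """
    s2 = psf_sigma_px ** 2
    return {
        "phys": 1.0,
        "h": float(np.exp(-1.0 / (4 * s2))),
        "v": float(np.exp(-1.0 / (4 * s2))),
        "d": float(np.exp(-2.0 / (4 * s2))),
    }


def distance_factor_flatten(cum: CumulantImage,
                            calibration: str = "analytic_gaussian",
                            psf_sigma_px: float | None = None,
                            region: tuple | None = None) -> CumulantImage:
    """Remove the virtual-pixel checkerboard by dividing out distance factors.

    ``analytic_gaussian`` uses the closed-form Gaussian-PSF factors and
    requires ``psf_sigma_px`` (optical PSF sigma in physical pixels);
    ``self_calibrated`` estimates one gain per virtual-pixel class from the
    ratio of its mean |value| to the physical class's over ``region``
    (whole image by default).  Physical pixels are never rescaled.
    """
    if cum.order != 2:
        raise ValueError("flattening defined for order-2 cumulants")
    data = cum.data.copy()
    sl = region if region is not None else (slice(None), slice(None))
    if calibration == "analytic_gaussian":
        if psf_sigma_px is None:
            raise ValueError("analytic calibration requires psf_sigma_px")
        f = distance_factors(psf_sigma_px)
        data[::2, 1::2] /= f["h"]
        data[1::2, ::2] /= f["v"]
        data[1::2, 1::2] /= f["d"]
    elif calibration == "self_calibrated":
        sub = cum.data[sl]
        ref = np.abs(sub[::2, ::2]).mean()
        if ref == 0:
            raise ValueError("self-calibration on an empty image")
        for rows, cols in [(slice(0, None, 2), slice(1, None, 2)),
                           (slice(1, None, 2), slice(0, None, 2)),
                           (slice(1, None, 2), slice(1, None, 2))]:
            m = np.abs(sub[rows, cols]).mean()
            if m > 0:
                data[rows, cols] *= ref / m
    else:
        raise ValueError(f"unknown calibration {calibration!r}")
    return CumulantImage(data, cum.pixel_nm_effective, cum.order, cum.lag,
                         flattened=True)


def gaussian_psf(sigma_px: float, size: int | None = None) -> np.ndarray:
    """Unit-sum isotropic Gaussian kernel."""
    if size is None:
        size = 2 * int(np.ceil(4 * sigma_px)) + 1
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sigma_px) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def lucy_richardson(image: np.ndarray, psf: np.ndarray, iterations: int = 50,
                    clamp_nonneg: bool = True) -> np.ndarray:
    """Richardson–Lucy deconvolution (multiplicative update, Poisson model).

    Negative input values are clamped to zero first when ``clamp_nonneg``
    (RL requires nonnegativity); the PSF is normalized to unit sum.  Output
    is nonnegative.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    psf = np.asarray(psf, dtype=float)
    s = psf.sum()
    if s <= 0:
        raise ValueError("psf must have positive sum")
    psf = psf / s
    img = np.asarray(image, dtype=float)
    if clamp_nonneg:
        img = np.clip(img, 0.0, None)
    elif np.any(img < 0):
        raise ValueError("negative input with clamp_nonneg=False")
    out = _skimage_rl(img, psf, num_iter=iterations, clip=False)
    return np.clip(out, 0.0, None)


def sofi_pipeline(movie, psf_fwhm_nm: float, lag: int = 1,
                  rl_iterations: int = 50, drift_correction: bool = True,
                  intensity_correction: str | None = "exp_fit",
                  crop: tuple | None = None, flatten: str = "analytic_gaussian"):
    """Full SOFI reconstruction for one movie (or a list of per-z movies).

    Fixed stage order: drift -> intensity -> crop -> second-order
    cross-cumulant -> distance-factor flattening -> clamp -> Richardson–Lucy
    deconvolution with the cumulant-domain PSF (optical sigma / sqrt(2),
    resampled onto the 2x virtual grid).  Returns ``(image, log)`` for a
    single movie, or ``(stack, logs)`` for a z-series.

    The output pixel pitch is half the input pixel size.
    """
    if isinstance(movie, (list, tuple)):
        results = [sofi_pipeline(m, psf_fwhm_nm, lag, rl_iterations,
                                 drift_correction, intensity_correction,
                                 crop, flatten) for m in movie]
        return np.stack([r[0] for r in results]), [r[1] for r in results]

    log: dict = {"lag": lag, "rl_iterations": rl_iterations}
    m = movie
    if drift_correction:
        m, shifts = correct_drift(m)
        log["drift_shifts"] = shifts
    if intensity_correction:
        try:
            m = correct_intensity(m, method=intensity_correction)
            log["intensity_method"] = intensity_correction
        except ValueError:
            # movies of sparse blinkers can have all-zero frames; the
            # trend fit is undefined there and the stage is skipped
            log["intensity_method"] = "skipped (empty frames)"
    if crop is not None:
        m = BlinkingMovie(m.data[(slice(None),) + tuple(crop)], m.pixel_nm,
                          m.exposure_ms, m.z_index)
        log["crop"] = crop
    cum = xc_sofi2(m, lag=lag)
    sigma_px = psf_fwhm_nm / 2.3548200450309493 / movie.pixel_nm
    if flatten:
        cum = distance_factor_flatten(cum, calibration=flatten,
                                      psf_sigma_px=sigma_px)
    # cumulant-domain PSF: optical sigma / sqrt(2), in virtual-pixel units
    sigma_virtual = sigma_px * np.sqrt(2.0)
    psf = gaussian_psf(sigma_virtual)
    out = lucy_richardson(cum.data, psf, iterations=rl_iterations)
    log["psf_sigma_virtual_px"] = sigma_virtual
    log["pixel_nm_effective"] = cum.pixel_nm_effective
    return out, log
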