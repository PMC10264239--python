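"""Synthetic scene generators with ground truth.

Every generator in this module emulates one class of input the expansion
microscopy / SOFI quantification pipeline consumes, and returns the ground
truth alongside the rendered image(s) so that downstream estimators can be
validated without any experimental data:

* blinking-emitter movies (telegraph photokinetics, Gaussian PSF, Poisson
  noise) for fluctuation-based super-resolution,
* matched pre/post-expansion image pairs related by a similarity transform
  plus a smooth random distortion field,
* nuclei fields at a known linear expansion factor,
* ninefold-symmetric ring structures (axoneme cross-sections) with
  engineered defects,
* two-channel punctum pairs at known separations (synaptic pair distances),
* intensity pairs with a known retention fraction under volume dilution.

Coordinate convention (used throughout the package): 0-based pixel indices,
pixel centers at integer coordinates, x = column, y = row, y increasing
downward.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .sofi import BlinkingMovie

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # FWHM = 2 sqrt(2 ln 2) sigma


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EmitterField:
    """A set of point emitters with two-state (ON/OFF) blinking kinetics.

    positions are continuous (x, y) pixel coordinates; ``amplitudes`` are the
    expected photons per frame at the PSF peak while the emitter is ON.
    ``on_fraction`` is the stationary ON probability and must be consistent
    with the mean dwell times: on_fraction = mean_on / (mean_on + mean_off).
    """

    positions: np.ndarray          # (N, 2) of (x, y), pixels
    amplitudes: np.ndarray         # (N,) photons/frame when ON
    on_fraction: float
    mean_on_frames: float
    mean_off_frames: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.broadcast_to(
            np.asarray(self.amplitudes, dtype=float), (len(self.positions),)
        ).copy()
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")
        if not (0.0 < self.on_fraction <= 1.0):
            raise ValueError("on_fraction must be in (0, 1]")
        if self.on_fraction == 1.0:
            return  # degenerate always-ON emitter; dwell times unused
        if self.mean_on_frames < 1 or self.mean_off_frames < 1:
            raise ValueError("mean dwell times must be >= 1 frame")
        expected = self.mean_on_frames / (self.mean_on_frames + self.mean_off_frames)
        if abs(expected - self.on_fraction) > 1e-6:
            raise ValueError(
                "on_fraction inconsistent with dwell times: "
                f"{self.on_fraction} vs {expected}"
            )

    @classmethod
    def from_dwell_times(cls, positions, amplitudes, mean_on_frames,
                         mean_off_frames, seed=0) -> "EmitterField":
        frac = mean_on_frames / (mean_on_frames + mean_off_frames)
        return cls(positions, amplitudes, frac, mean_on_frames,
                   mean_off_frames, seed)

    @classmethod
    def random(cls, n, shape, amplitude=200.0, mean_on_frames=20.0,
               mean_off_frames=20.0, margin=6.0, seed=0) -> "EmitterField":
        """Uniformly scattered emitters inside ``shape`` with a border margin."""
        rng = np.random.default_rng(seed)
        ny, nx = shape
        xy = np.column_stack([
            rng.uniform(margin, nx - 1 - margin, n),
            rng.uniform(margin, ny - 1 - margin, n),
        ])
        return cls.from_dwell_times(xy, np.full(n, float(amplitude)),
                                    mean_on_frames, mean_off_frames, seed)


@dataclass
class GroundTruthWarp:
    """Similarity transform (scale = true linear expansion factor) plus a
    smooth random residual displacement field.

    ``displacement`` is a (2, H, W) array of (dy, dx) vectors defined on the
    pre-image pixel grid; ``amplitude`` is its RMS magnitude per node (px) and
    ``correlation_length`` the Gaussian smoothing length (px) used to
    synthesize it.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    displacement: np.ndarray | None = None   # (2, H, W): (dy, dx) per pre pixel
    correlation_length: float = 0.0
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.amplitude < 0:
            raise ValueError("displacement amplitude must be >= 0")


def make_displacement_field(shape, amplitude, correlation_length, seed=0):
    """Band-limited zero-mean random 2-vector field with a target RMS amplitude.

    White Gaussian vector noise is smoothed with a Gaussian kernel of the
    stated correlation length, mean-removed per component, and rescaled so
    that the empirical RMS of the vector magnitude equals ``amplitude``.
    """
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((2,) + tuple(shape))
    if correlation_length > 0:
        d = ndimage.gaussian_filter(d, sigma=(0, correlation_length,
                                              correlation_length), mode="wrap")
    d -= d.mean(axis=(1, 2), keepdims=True)
    if amplitude > 0:
        rms = np.sqrt(np.mean(np.sum(d ** 2, axis=0)))
        d *= amplitude / rms
    else:
        d[:] = 0.0
    return d


# ---------------------------------------------------------------------------
# blinking movies
# ---------------------------------------------------------------------------


def _telegraph_on_fractions(n_frames, mean_on, mean_off, rng):
    """Per-frame integrated ON fraction of a continuous-time telegraph process.

    Dwell times are exponential with the given means (in frame units); the
    state is integrated over each unit-length frame, which is what a camera
    exposure records.  Stationary initial condition.
    """
    total = float(n_frames)
    # alternating exponential dwells, stationary start
    state0 = bool(rng.random() < mean_on / (mean_on + mean_off))
    bounds = [0.0]
    states = []
    state = state0
    t = 0.0
    chunk = max(8, int(2 * total / (mean_on + mean_off)) + 8)
    while t < total:
        d_on = rng.exponential(mean_on, chunk)
        d_off = rng.exponential(mean_off, chunk)
        for k in range(chunk):
            d = d_on[k] if state else d_off[k]
            t += d
            states.append(state)
            bounds.append(t)
            state = not state
            if t >= total:
                break
    bounds = np.asarray(bounds)
    states = np.asarray(states, dtype=float)
    # cumulative ON time is piecewise linear in t with slope = state
    cum_on = np.concatenate([[0.0], np.cumsum(np.diff(bounds) * states)])
    edges = np.arange(n_frames + 1, dtype=float)
    c = np.interp(edges, bounds, cum_on)
    return np.diff(c)


def telegraph_frame_variance(on_fraction, mean_on, mean_off):
    """Closed-form variance of the frame-integrated telegraph state.

    The telegraph state has variance p(1-p) and exponential autocorrelation
    with time constant tau_c = 1/(1/mean_on + 1/mean_off); integrating over a
    unit frame multiplies the variance by 2(x - 1 + e^-x)/x^2 with x = 1/tau_c.
    """
    p = on_fraction
    tau_c = 1.0 / (1.0 / mean_on + 1.0 / mean_off)
    x = 1.0 / tau_c
    factor = 2.0 * (x - 1.0 + np.exp(-x)) / x ** 2
    return p * (1 - p) * factor


def telegraph_frame_lag1_cov(on_fraction, mean_on, mean_off):
    """Closed-form lag-1 covariance of the frame-integrated telegraph state:
    p(1-p) * tau_c^2 * (1 - e^{-1/tau_c})^2."""
    p = on_fraction
    tau_c = 1.0 / (1.0 / mean_on + 1.0 / mean_off)
    return p * (1 - p) * (tau_c * (1.0 - np.exp(-1.0 / tau_c))) ** 2


def render_emitters(positions, amplitudes, shape, sigma_px):
    """Render Gaussian PSFs (peak height = amplitude) onto a (Y, X) grid."""
    ny, nx = shape
    img = np.zeros((ny, nx))
    half = max(3, int(np.ceil(4 * sigma_px)))
    for (x, y), a in zip(np.atleast_2d(positions), np.atleast_1d(amplitudes)):
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 2
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 2
        x0, x1 = max(x0, 0), min(x1, nx)
        y0, y1 = max(y0, 0), min(y1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = np.exp(-0.5 * ((xs - x) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((ys - y) / sigma_px) ** 2)
        img[y0:y1, x0:x1] += a * gy[:, None] * gx[None, :]
    return img


def gen_blinking_movie(emitters: EmitterField, psf_fwhm_nm: float,
                       pixel_nm: float, shape=(64, 64), frames: int = 100,
                       background: float = 0.0, bleach_rate: float = 0.0,
                       drift=(0.0, 0.0), poisson: bool = True,
                       gaussian_sd: float = 0.0, exposure_ms: float = 100.0,
                       seed: int | None = None):
    """Simulate a T x Y x X photon-count movie of blinking emitters.

    Each emitter follows an independent two-state telegraph process with
    exponential dwell times (means ``mean_on_frames`` / ``mean_off_frames``),
    integrated over the frame exposure.  The optical response is an isotropic
    Gaussian PSF of the stated FWHM.  ``drift`` is (dx, dy) pixels per frame
    applied to the emitter positions; ``bleach_rate`` is an exponential decay
    of the expected signal per frame.  Poisson shot noise and/or additive
    Gaussian read noise are applied last.

    Returns ``(movie, truth)`` where ``truth`` holds the per-frame per-emitter
    integrated ON fraction and all generation parameters.
    """
    if frames < 2:
        raise ValueError("frames must be >= 2")
    if psf_fwhm_nm <= 0 or pixel_nm <= 0:
        raise ValueError("psf_fwhm_nm and pixel_nm must be > 0")
    for v in (background, bleach_rate, gaussian_sd):
        if not np.isfinite(v):
            raise ValueError("non-finite parameter")
    if len(emitters.positions) == 0 and background == 0:
        raise ValueError("empty scene: no emitters and no background")
    ny, nx = shape
    if np.any(emitters.positions[:, 0] > nx - 1) or np.any(
            emitters.positions[:, 1] > ny - 1) or np.any(emitters.positions < 0):
        raise ValueError("emitter positions outside image bounds")

    rng = np.random.default_rng(emitters.seed if seed is None else seed)
    sigma_px = psf_fwhm_nm * FWHM_TO_SIGMA / pixel_nm
    n_em = len(emitters.positions)

    on_frac = np.empty((n_em, frames))
    for i in range(n_em):
        if emitters.on_fraction == 1.0:
            on_frac[i] = 1.0
        else:
            on_frac[i] = _telegraph_on_fractions(
                frames, emitters.mean_on_frames, emitters.mean_off_frames, rng)

    drift = np.asarray(drift, dtype=float)
    static = not drift.any()
    data = np.empty((frames, ny, nx))
    if static:
        psf_imgs = np.stack([
            render_emitters(emitters.positions[i:i + 1], [1.0], shape, sigma_px)
            for i in range(n_em)
        ]) if n_em else np.zeros((0, ny, nx))
        weights = emitters.amplitudes[:, None] * on_frac  # (N, T)
        data[:] = np.tensordot(weights.T, psf_imgs, axes=(1, 0)) if n_em else 0.0
    else:
        for t in range(frames):
            pos = emitters.positions + drift[None, :] * t
            data[t] = render_emitters(
                pos, emitters.amplitudes * on_frac[:, t], shape, sigma_px)
    data += background
    if bleach_rate != 0.0:
        data *= np.exp(-bleach_rate * np.arange(frames))[:, None, None]
    if poisson:
        data = rng.poisson(data).astype(float)
    if gaussian_sd > 0:
        data = data + rng.normal(0.0, gaussian_sd, data.shape)
    data = np.clip(data, 0.0, None)

    movie = BlinkingMovie(data=data, pixel_nm=pixel_nm, exposure_ms=exposure_ms)
    truth = {
        "on_fractions": on_frac,
        "positions": emitters.positions.copy(),
        "amplitudes": emitters.amplitudes.copy(),
        "psf_sigma_px": sigma_px,
        "psf_fwhm_nm": psf_fwhm_nm,
        "background": background,
        "bleach_rate": bleach_rate,
        "drift": drift,
    }
    return movie, truth


# ---------------------------------------------------------------------------
# expansion pairs
# ---------------------------------------------------------------------------


def blob_template(shape=(256, 256), n_blobs=80, sigma_range=(1.5, 4.0),
                  amplitude_range=(0.5, 1.0), seed=0):
    """A textured template of scattered Gaussian blobs, for registration tests."""
    rng = np.random.default_rng(seed)
    ny, nx = shape
    img = np.zeros(shape)
    for _ in range(n_blobs):
        x = rng.uniform(5, nx - 6)
        y = rng.uniform(5, ny - 6)
        s = rng.uniform(*sigma_range)
        a = rng.uniform(*amplitude_range)
        img += render_emitters([[x, y]], [a], shape, s)
    return img


def warp_coordinates(warp: GroundTruthWarp, shape_post):
    """Inverse-map coordinates for resampling: for every post-image pixel q,
    the pre-image source location S^{-1}(q) - D(S^{-1}(q)).

    D is the warp's displacement field on the pre grid, interpolated
    bilinearly.  Returns (rows, cols) arrays shaped like the post image.
    """
    ny, nx = shape_post
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    th = np.deg2rad(warp.rotation_deg)
    s = warp.scale
    tx, ty = warp.translation
    # inverse similarity: p = R(-th) (q - t) / s
    qx = xx - tx
    qy = yy - ty
    px = (np.cos(th) * qx + np.sin(th) * qy) / s
    py = (-np.sin(th) * qx + np.cos(th) * qy) / s
    if warp.displacement is not None and warp.amplitude > 0:
        coords = np.stack([py.ravel(), px.ravel()])
        dy = ndimage.map_coordinates(warp.displacement[0], coords, order=1,
                                     mode="nearest").reshape(py.shape)
        dx = ndimage.map_coordinates(warp.displacement[1], coords, order=1,
                                     mode="nearest").reshape(px.shape)
        py = py - dy
        px = px - dx
    return py, px


def gen_expansion_pair(template: np.ndarray, warp: GroundTruthWarp,
                       noise_sd: float = 0.0, out_shape=None, seed: int = 0):
    """Resample a pre-expansion template through similarity + distortion.

    The post image at pixel q samples the template at
    ``S^{-1}(q) - D(S^{-1}(q))`` (cubic interpolation), so after registering
    the post image back through S the residual displacement field in the pre
    frame is the warp's ``displacement`` (v such that pre(p) ~ aligned(p+v)).

    Returns ``(pre_image, post_image, warp)``.
    """
    template = np.asarray(template, dtype=float)
    if template.size == 0:
        raise ValueError("empty template")
    if warp.amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if out_shape is None:
        out_shape = (int(round(template.shape[0] * warp.scale)),
                     int(round(template.shape[1] * warp.scale)))
    py, px = warp_coordinates(warp, out_shape)
    post = ndimage.map_coordinates(template, [py.ravel(), px.ravel()],
                                   order=3, mode="constant",
                                   cval=0.0).reshape(out_shape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        post = post + rng.normal(0.0, noise_sd, post.shape)
    return template.copy(), post, warp


# ---------------------------------------------------------------------------
# nuclei fields
# ---------------------------------------------------------------------------


def gen_nuclei_field(n: int, ef: float, shape=(256, 256),
                     radius_mean: float = 10.0, radius_sigma: float = 0.25,
                     eccentricity_max: float = 0.6, intensity: float = 200.0,
                     noise_sd: float = 0.0, max_tries: int = 10000,
                     seed: int = 0):
    """Non-overlapping elliptical 'nuclei' rendered pre- and post-expansion.

    Radii are lognormal (``radius_mean`` px median, ``radius_sigma`` log-sd).
    The post image/masks are the same ellipses with centers and axes scaled
    by the linear expansion factor ``ef``.  Ground truth carries analytic
    areas (pi*a*b) for which post_area = ef^2 * pre_area holds exactly;
    rasterized mask areas approximate these to pixelation accuracy.

    Returns ``(pre_img, pre_labels, post_img, post_labels, truth)`` where
    truth is a dict with per-nucleus centers, axes and analytic areas.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if ef <= 0:
        raise ValueError("ef must be > 0")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    centers, axes, angles = [], [], []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping nuclei in {shape}")
        a = radius_mean * np.exp(rng.normal(0, radius_sigma))
        b = a * rng.uniform(1 - eccentricity_max, 1.0)
        r = max(a, b)
        cx = rng.uniform(r + 2, nx - r - 3)
        cy = rng.uniform(r + 2, ny - r - 3)
        ok = all(np.hypot(cx - ox, cy - oy) > r + max(oa, ob) + 2
                 for (ox, oy), (oa, ob) in zip(centers, axes))
        if ok:
            centers.append((cx, cy))
            axes.append((a, b))
            angles.append(rng.uniform(0, np.pi))

    def render(scale, out_shape):
        lab = np.zeros(out_shape, dtype=np.int32)
        yy, xx = np.mgrid[0:out_shape[0], 0:out_shape[1]].astype(float)
        for i, ((cx, cy), (a, b), th) in enumerate(zip(centers, axes, angles)):
            cx2, cy2, a2, b2 = cx * scale, cy * scale, a * scale, b * scale
            u = (xx - cx2) * np.cos(th) + (yy - cy2) * np.sin(th)
            v = -(xx - cx2) * np.sin(th) + (yy - cy2) * np.cos(th)
            lab[(u / a2) ** 2 + (v / b2) ** 2 <= 1.0] = i + 1
        img = np.where(lab > 0, intensity, 0.0)
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, out_shape)
        return img, lab

    pre_img, pre_lab = render(1.0, shape)
    post_shape = (int(round(ny * ef)), int(round(nx * ef)))
    post_img, post_lab = render(ef, post_shape)
    area_pre = np.array([np.pi * a * b for a, b in axes])
    truth = {
        "centers": np.asarray(centers),
        "axes": np.asarray(axes),
        "angles": np.asarray(angles),
        "area_pre": area_pre,
        "area_post": area_pre * ef ** 2,
        "ef": ef,
    }
    return pre_img, pre_lab, post_img, post_lab, truth


# ---------------------------------------------------------------------------
# ring structures (axoneme cross-sections)
# ---------------------------------------------------------------------------


@dataclass
class RingTruth:
    n_outer: int
    n_central: int
    center: tuple[float, float]
    ring_radius: float
    defect: str = "none"
    unresolvable: bool = False


def gen_ring_structure(n_outer: int = 9, central_pair: bool = True,
                       ring_radius: float = 12.0, subunit_sigma: float = 1.5,
                       central_sep: float = 4.0, defect: str = "none",
                       shape=(64, 64), amplitude: float = 100.0,
                       noise_sd: float = 0.0, phase_deg: float = 0.0,
                       seed: int = 0):
    """A ring of equally spaced Gaussian subunits, emulating the 9+2 axoneme.

    ``defect`` is one of ``none | missing_outer | extra_outer |
    missing_central``; the recorded truth counts reflect the defect.  A
    warning flag ``unresolvable`` is set in the truth when ``subunit_sigma``
    exceeds 0.35x the inter-subunit arc length (subunits then blur together
    by construction).

    Returns ``(image, RingTruth)``.
    """
    if ring_radius <= 2 * subunit_sigma:
        raise ValueError("ring_radius must exceed 2*subunit_sigma")
    if defect not in ("none", "missing_outer", "extra_outer", "missing_central"):
        raise ValueError(f"unknown defect {defect!r}")
    n = n_outer
    if defect == "missing_outer":
        n = n_outer - 1
    elif defect == "extra_outer":
        n = n_outer + 1
    n_cen = 2 if central_pair else 0
    if defect == "missing_central" and central_pair:
        n_cen = 1
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ang = np.deg2rad(phase_deg) + 2 * np.pi * np.arange(n) / max(n, 1)
    pos = [(cx + ring_radius * np.cos(a), cy + ring_radius * np.sin(a))
           for a in ang]
    for k in range(n_cen):
        off = (k - (n_cen - 1) / 2.0) * central_sep
        pos.append((cx + off, cy))
    img = render_emitters(np.asarray(pos), np.full(len(pos), amplitude),
                          shape, subunit_sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, noise_sd, shape)
    arc = 2 * np.pi * ring_radius / max(n, 1)
    truth = RingTruth(n_outer=n, n_central=n_cen, center=(cx, cy),
                      ring_radius=ring_radius, defect=defect,
                      unresolvable=subunit_sigma > 0.35 * arc)
    return img, truth


# ---------------------------------------------------------------------------
# two-channel punctum pairs
# ---------------------------------------------------------------------------


def gen_synapse_pairs(n: int = 50, mean_sep_nm: float = 64.0,
                      sep_sd_nm: float = 10.0, pixel_nm: float = 10.0,
                      punctum_sigma_a_px: float = 2.0,
                      punctum_sigma_b_px: float = 2.0,
                      amplitude: float = 200.0, shape=None,
                      noise_sd: float = 0.0, seed: int = 0):
    """Two-channel punctum pairs at known center-to-center separations.

    Emulates paired pre/postsynaptic protein puncta (e.g. scaffold protein
    pairs): channel A and channel B puncta separated by N(mean_sep, sep_sd)
    nm along a random direction, instances laid out on a jittered grid so
    pairs never overlap.

    Returns ``(img_a, img_b, truth)`` with true separations in nm and the
    true centers of each punctum.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_sep_nm <= 0:
        raise ValueError("mean_sep_nm must be > 0")
    if sep_sd_nm < 0:
        raise ValueError("sep_sd_nm must be >= 0")
    rng = np.random.default_rng(seed)
    sep_px_max = (mean_sep_nm + 6 * sep_sd_nm) / pixel_nm
    cell = int(np.ceil(sep_px_max + 12 * max(punctum_sigma_a_px,
                                             punctum_sigma_b_px) + 8))
    n_side = int(np.ceil(np.sqrt(n)))
    if shape is None:
        shape = (n_side * cell + cell, n_side * cell + cell)
    img_a = np.zeros(shape)
    img_b = np.zeros(shape)
    seps, centers_a, centers_b = [], [], []
    for i in range(n):
        gy, gx = divmod(i, n_side)
        cx = (gx + 1) * cell + rng.uniform(-2, 2)
        cy = (gy + 1) * cell + rng.uniform(-2, 2)
        d_nm = mean_sep_nm if sep_sd_nm == 0 else rng.normal(mean_sep_nm,
                                                             sep_sd_nm)
        d_nm = max(d_nm, 1e-3)
        th = rng.uniform(0, 2 * np.pi)
        d_px = d_nm / pixel_nm
        ax, ay = cx - 0.5 * d_px * np.cos(th), cy - 0.5 * d_px * np.sin(th)
        bx, by = cx + 0.5 * d_px * np.cos(th), cy + 0.5 * d_px * np.sin(th)
        img_a += render_emitters([[ax, ay]], [amplitude], shape,
                                 punctum_sigma_a_px)
        img_b += render_emitters([[bx, by]], [amplitude], shape,
                                 punctum_sigma_b_px)
        seps.append(d_nm)
        centers_a.append((ax, ay))
        centers_b.append((bx, by))
    if noise_sd > 0:
        img_a = img_a + rng.normal(0, noise_sd, shape)
        img_b = img_b + rng.normal(0, noise_sd, shape)
    truth = {
        "separations_nm": np.asarray(seps),
        "centers_a": np.asarray(centers_a),
        "centers_b": np.asarray(centers_b),
        "pixel_nm": pixel_nm,
        "sigma_a_px": punctum_sigma_a_px,
        "sigma_b_px": punctum_sigma_b_px,
    }
    return img_a, img_b, truth


# ---------------------------------------------------------------------------
# retention pairs
# ---------------------------------------------------------------------------


def gen_retention_pair(pre_image: np.ndarray, retention: float, ef: float,
                       background: float = 0.0, noise_sd: float = 0.0,
                       seed: int = 0):
    """Post-expansion counterpart of an intensity image under volume dilution.

    The retained signal is diluted by the cubed linear expansion factor:
    post = pre * retention / ef^3 + background (+ optional Gaussian noise).

    Returns ``(pre_image, post_image)``.
    """
    if not (0.0 <= retention <= 1.0):
        raise ValueError("retention must be in [0, 1]")
    if ef < 1:
        raise ValueError("ef must be >= 1")
    pre = np.asarray(pre_image, dtype=float)
    post = pre * (retention / ef ** 3) + background
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        post = post + rng.normal(0, noise_sd, post.shape)
    return pre.copy(), post
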