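"""Morphometric measurements: expansion factors, retention, profiles, distances.

All length outputs can be expressed at *biological scale* — expanded-space
measurements divided by the linear expansion factor (EF) — which is how
expansion-microscopy results are conventionally reported.  The EF itself is
estimated either from the similarity-registration scale, from the square
root of the mean nuclear area ratio, or from matched feature distances.
Biomolecule retention compares background-subtracted ROI means between pre-
and post-expansion images, scaling the post value by the cubed linear EF to
undo the volumetric dilution of fluorophores in the swollen gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops


@dataclass
class LabeledRegions:
    """Connected components with per-region area, centroid, mean intensity."""

    label_image: np.ndarray
    areas_px2: np.ndarray
    centroids: np.ndarray           # (N, 2) of (x, y)
    mean_intensities: np.ndarray
    pixel_nm: float | None = None
    area_filter: tuple = (0.0, np.inf)

    def __len__(self) -> int:
        return len(self.areas_px2)

    @property
    def areas_um2(self) -> np.ndarray:
        if self.pixel_nm is None:
            raise ValueError("pixel size unknown; cannot convert to um^2")
        return self.areas_px2 * (self.pixel_nm / 1000.0) ** 2

    @classmethod
    def from_areas(cls, areas) -> "LabeledRegions":
        """Construct from known areas only (e.g. generator ground truth)."""
        areas = np.asarray(areas, dtype=float)
        n = len(areas)
        return cls(np.zeros((0, 0), dtype=int), areas,
                   np.zeros((n, 2)), np.zeros(n))


@dataclass
class RetentionResult:
    """Volume-corrected fluorescence retention fraction."""

    pre_mean: float
    post_mean: float
    ef: float
    retention: float
    pre_background: float
    post_background: float
    above_one: bool = False


@dataclass
class RadialProfile:
    """Azimuthally averaged intensity vs radius, plus the angular profile at
    the radial peak and its detected peak angles (degrees)."""

    center: tuple[float, float]
    radii_px: np.ndarray
    radial_mean: np.ndarray
    peak_radius_px: float
    angles_deg: np.ndarray
    angular_profile: np.ndarray
    peak_angles_deg: np.ndarray


@dataclass
class PairDistanceSet:
    """Per-pair punctum distances at biological scale."""

    distances_nm: np.ndarray
    mode: str
    ef: float
    pixel_nm: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances_nm))

    @property
    def sd(self) -> float:
        return float(np.std(self.distances_nm, ddof=1)) if len(
            self.distances_nm) > 1 else 0.0

    @property
    def n(self) -> int:
        return len(self.distances_nm)


# ---------------------------------------------------------------------------
# segmentation + EF
# ---------------------------------------------------------------------------


def segment_nuclei(image: np.ndarray, threshold="otsu", min_area: float = 0,
                   max_area: float = np.inf,
                   pixel_nm: float | None = None) -> LabeledRegions:
    """Threshold, binarize and label nuclei; filter components by area.

    ``threshold`` is 'otsu' or a fixed numeric value; components use
    8-connectivity.  Raises ``ValueError('no regions')`` if nothing survives.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if threshold == "otsu":
        if img.max() == img.min():
            raise ValueError("no regions")
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    lab = sk_label(mask, connectivity=2)
    props = [p for p in regionprops(lab, intensity_image=img)
             if min_area <= p.area <= max_area]
    if not props:
        raise ValueError("no regions")
    out = np.zeros_like(lab)
    areas, cents, means = [], [], []
    for i, p in enumerate(props):
        out[lab == p.label] = i + 1
        areas.append(float(p.area))
        cents.append((p.centroid[1], p.centroid[0]))
        means.append(float(p.intensity_mean))
    return LabeledRegions(out, np.asarray(areas), np.asarray(cents),
                          np.asarray(means), pixel_nm, (min_area, max_area))


def ef_from_areas(pre: LabeledRegions, post: LabeledRegions) -> float:
    """Linear EF from nuclear areas: sqrt(mean post area / mean pre area)."""
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("no regions")
    return float(np.sqrt(post.areas_px2.mean() / pre.areas_px2.mean()))


def ef_from_features(pre_distances, post_distances):
    """Linear EF from matched feature distances: mean per-pair ratio.

    Returns ``(ef, ratios)``; the SD of the ratios is ``ratios.std(ddof=1)``.
    """
    pre = np.atleast_1d(np.asarray(pre_distances, dtype=float))
    post = np.atleast_1d(np.asarray(post_distances, dtype=float))
    if len(pre) == 0:
        raise ValueError("need at least one matched distance pair")
    if np.any(pre == 0):
        raise ValueError("zero pre-expansion distance")
    ratios = post / pre
    return float(ratios.mean()), ratios


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------


def _mode_background(img: np.ndarray, bins: int = 256) -> float:
    """Histogram-peak (mode) background estimate."""
    hist, edges = np.histogram(img.ravel(), bins=bins)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def retention(pre_img: np.ndarray, post_img: np.ndarray, ef: float,
              roi_pre=None, roi_post=None,
              background="mode") -> RetentionResult:
    """Fluorescence retention with volume correction.

    retention = (post ROI mean - post bg) * ef^3 / (pre ROI mean - pre bg).
    ``roi_*`` may be boolean masks or index tuples (whole image if None);
    ``background`` is 'mode' (per-image histogram peak) or a fixed value
    (scalar or (pre, post) pair).  Negative numerators clip to 0; values
    above 1 are reported unclipped with the ``above_one`` flag set.
    """
    if ef <= 0:
        raise ValueError("ef must be > 0")
    pre = np.asarray(pre_img, dtype=float)
    post = np.asarray(post_img, dtype=float)
    if background == "mode":
        bg_pre, bg_post = _mode_background(pre), _mode_background(post)
    elif np.isscalar(background):
        bg_pre = bg_post = float(background)
    else:
        bg_pre, bg_post = (float(b) for b in background)
    pre_roi = pre if roi_pre is None else pre[roi_pre]
    post_roi = post if roi_post is None else post[roi_post]
    pre_mean = float(pre_roi.mean())
    post_mean = float(post_roi.mean())
    pre_sig = pre_mean - bg_pre
    if pre_sig <= 0:
        raise ValueError("no pre signal above background")
    post_sig = max(post_mean - bg_post, 0.0)
    r = post_sig * ef ** 3 / pre_sig
    return RetentionResult(pre_mean, post_mean, ef, r, bg_pre, bg_post,
                           above_one=r > 1.0)


def fit_gaussian_fwhm(image: np.ndarray, window: int = 10) -> float:
    """FWHM (px) of the brightest spot by 2D Gaussian least-squares fit.

    Fits amplitude, center, isotropic sigma and offset within a square
    window around the intensity maximum.
    """
    from scipy.optimize import curve_fit

    img = np.asarray(image, dtype=float)
    y0, x0 = np.unravel_index(np.argmax(img), img.shape)
    y0 = int(np.clip(y0, window, img.shape[0] - window - 1))
    x0 = int(np.clip(x0, window, img.shape[1] - window - 1))
    sub = img[y0 - window:y0 + window + 1, x0 - window:x0 + window + 1]
    yy, xx = np.mgrid[0:sub.shape[0], 0:sub.shape[1]]

    def model(xy, a, cx, cy, s, b):
        return (a * np.exp(-((xy[0] - cx) ** 2 + (xy[1] - cy) ** 2)
                           / (2 * s ** 2)) + b).ravel()

    p0 = (float(sub.max() - sub.min()), float(window), float(window), 2.0,
          float(sub.min()))
    popt, _ = curve_fit(model, (xx, yy), sub.ravel(), p0=p0, maxfev=10000)
    return float(2 * np.sqrt(2 * np.log(2)) * abs(popt[3]))


# ---------------------------------------------------------------------------
# radial / angular profiles
# ---------------------------------------------------------------------------


def refine_center(image: np.ndarray, center_init, window: int = 15):
    """Intensity-centroid center refinement within a square window."""
    img = np.asarray(image, dtype=float)
    cx, cy = center_init
    h = window // 2
    x0, x1 = int(round(cx)) - h, int(round(cx)) + h + 1
    y0, y1 = int(round(cy)) - h, int(round(cy)) + h + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    sub = img[y0:y1, x0:x1]
    sub = sub - sub.min()
    if sub.sum() == 0:
        return float(cx), float(cy)
    yy, xx = np.mgrid[y0:y0 + sub.shape[0], x0:x0 + sub.shape[1]]
    return (float((sub * xx).sum() / sub.sum()),
            float((sub * yy).sum() / sub.sum()))


def radial_profile(image: np.ndarray, center_init=None,
                   radius_range=(2.0, None), n_angle_bins: int = 360,
                   peak_prominence: float = 0.2,
                   radial_band_px: float = 1.0) -> RadialProfile:
    """Azimuthally averaged radial profile and angular peak detection.

    The center is refined by intensity centroid; the radial profile is the
    mean intensity over angle at each radius (0.5 px steps); the angular
    profile is sampled on a circle at the radial-peak radius (averaged over
    a small radial band) and its local maxima above ``peak_prominence`` x
    the profile's dynamic range are returned, with periodic wrap-around.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    if img.max() == img.min():
        raise ValueError("no radial peak: flat image")
    if center_init is None:
        center_init = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    cx, cy = refine_center(img, center_init)
    r_min = radius_range[0]
    r_max = radius_range[1] or min(cx, cy, nx - 1 - cx, ny - 1 - cy) - 1
    radii = np.arange(r_min, r_max, 0.5)
    ang = np.linspace(0, 2 * np.pi, n_angle_bins, endpoint=False)
    cosa, sina = np.cos(ang), np.sin(ang)
    prof = np.empty(len(radii))
    for k, r in enumerate(radii):
        xs = cx + r * cosa
        ys = cy + r * sina
        prof[k] = ndimage.map_coordinates(img, [ys, xs], order=1).mean()
    pk, _ = find_peaks(prof)
    if len(pk) == 0:
        raise ValueError("no radial peak")
    peak_r = float(radii[pk[np.argmax(prof[pk])]])
    band = np.arange(peak_r - radial_band_px, peak_r + radial_band_px + 1e-9,
                     0.5)
    aprof = np.zeros(n_angle_bins)
    for r in band:
        xs = cx + r * cosa
        ys = cy + r * sina
        aprof += ndimage.map_coordinates(img, [ys, xs], order=1)
    aprof /= len(band)
    # periodic peak detection: triplicate and detect in the middle copy
    ext = np.concatenate([aprof, aprof, aprof])
    dyn = aprof.max() - aprof.min()
    pk, _ = find_peaks(ext, prominence=peak_prominence * dyn)
    pk = pk[(pk >= n_angle_bins) & (pk < 2 * n_angle_bins)] - n_angle_bins
    return RadialProfile((cx, cy), radii, prof, peak_r,
                         np.degrees(ang), aprof, np.degrees(ang[pk]))


# ---------------------------------------------------------------------------
# line-profile distances
# ---------------------------------------------------------------------------


def peak_to_peak(image: np.ndarray, p0, p1, ef: float = 1.0,
                 pixel_nm: float = 1.0, n_samples: int | None = None,
                 prominence: float = 0.1) -> float:
    """Peak-to-peak distance along a transect, at biological scale (nm).

    The intensity is sampled along the line p0 -> p1 (cubic interpolation);
    the two most prominent local maxima are refined by 3-point parabolic
    fits and their separation is converted by pixel_nm / ef.
    """
    img = np.asarray(image, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if n_samples is None:
        n_samples = max(int(np.ceil(length * 4)), 16)
    ts = np.linspace(0.0, 1.0, n_samples)
    xs = p0[0] + ts * (p1[0] - p0[0])
    ys = p0[1] + ts * (p1[1] - p0[1])
    prof = ndimage.map_coordinates(img, [ys, xs], order=3)
    dyn = prof.max() - prof.min()
    if dyn == 0:
        raise ValueError("flat transect: fewer than 2 peaks")
    pk, props = find_peaks(prof, prominence=prominence * dyn)
    if len(pk) < 2:
        raise ValueError("fewer than 2 peaks above prominence")
    top2 = pk[np.argsort(prof[pk])[-2:]]
    step = length / (n_samples - 1)
    pos = []
    for k in sorted(top2):
        off = 0.0
        if 0 < k < n_samples - 1:
            denom = prof[k - 1] - 2 * prof[k] + prof[k + 1]
            if denom != 0:
                off = float(np.clip(0.5 * (prof[k - 1] - prof[k + 1]) / denom,
                                    -1, 1))
        pos.append((k + off) * step)
    return abs(pos[1] - pos[0]) * pixel_nm / ef


# ---------------------------------------------------------------------------
# two-channel pair distances
# ---------------------------------------------------------------------------


def _gaussian_center(img, cx, cy, window=7):
    """Refine one punctum center by a 2D Gaussian least-squares fit."""
    from scipy.optimize import curve_fit

    h = window
    x0, x1 = int(round(cx)) - h, int(round(cx)) + h + 1
    y0, y1 = int(round(cy)) - h, int(round(cy)) + h + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, img.shape[1]), min(y1, img.shape[0])
    sub = img[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]

    def model(xy, a, mx, my, s, b):
        return (a * np.exp(-((xy[0] - mx) ** 2 + (xy[1] - my) ** 2)
                           / (2 * s ** 2)) + b).ravel()

    try:
        p, _ = curve_fit(model, (xx, yy), sub.ravel(),
                         p0=(float(sub.max() - sub.min()), cx, cy, 2.0,
                             float(sub.min())), maxfev=5000)
        if abs(p[1] - cx) < h and abs(p[2] - cy) < h:
            return float(p[1]), float(p[2])
    except RuntimeError:
        pass
    return float(cx), float(cy)


def detect_puncta(image: np.ndarray, threshold="otsu", center: str = "centroid"):
    """Punctum centers by thresholded connected components.

    ``center`` is 'centroid' (intensity-weighted, robust default) or
    'gaussian' (2D Gaussian fit refinement, highest accuracy on clean
    symmetric puncta).  Returns (centers (N,2) xy, peak values).
    """
    img = np.asarray(image, dtype=float)
    thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    lab = sk_label(img > thr, connectivity=2)
    centers, peaks = [], []
    for p in regionprops(lab, intensity_image=img):
        cy, cx = p.centroid_weighted
        if center == "gaussian":
            cx, cy = _gaussian_center(img, cx, cy)
        centers.append((cx, cy))
        peaks.append(float(p.intensity_max))
    return np.asarray(centers).reshape(-1, 2), np.asarray(peaks)


def pair_distance(chan_a: np.ndarray, chan_b: np.ndarray,
                  mode: str = "center_center", edge_threshold: float = 0.5,
                  ef: float = 1.0, pixel_nm: float = 1.0,
                  pairing_radius: float = 20.0, threshold="otsu",
                  center: str = "centroid") -> PairDistanceSet:
    """Distances between paired puncta in two channels, biological nm.

    Puncta are detected per channel and paired by mutual nearest neighbor
    within ``pairing_radius`` px.  ``center_center`` measures centroid to
    centroid; ``edge_center`` measures from the point on the A->B axis where
    channel A's interpolated intensity falls to ``edge_threshold`` x its
    peak, to the B centroid.
    """
    if mode not in ("center_center", "edge_center"):
        raise ValueError(f"unknown mode {mode!r}")
    ca, pa = detect_puncta(chan_a, threshold, center=center)
    cb, pb = detect_puncta(chan_b, threshold, center=center)
    if len(ca) == 0 or len(cb) == 0:
        raise ValueError("no puncta detected")
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    nn_ab = np.argmin(d, axis=1)
    nn_ba = np.argmin(d, axis=0)
    dists = []
    img_a = np.asarray(chan_a, dtype=float)
    for i, j in enumerate(nn_ab):
        if nn_ba[j] != i or d[i, j] > pairing_radius:
            continue
        if mode == "center_center":
            dists.append(d[i, j])
        else:
            a, b = ca[i], cb[j]
            u = (b - a) / d[i, j]
            ts = np.linspace(0.0, d[i, j], 200)
            xs = a[0] + ts * u[0]
            ys = a[1] + ts * u[1]
            prof = ndimage.map_coordinates(img_a, [ys, xs], order=3)
            peak = prof[0:100].max()
            target = edge_threshold * peak
            below = np.nonzero(prof <= target)[0]
            if len(below) == 0:
                continue
            k = below[0]
            if k == 0:
                t_edge = 0.0
            else:
                frac = (prof[k - 1] - target) / (prof[k - 1] - prof[k])
                t_edge = ts[k - 1] + frac * (ts[k] - ts[k - 1])
            dists.append(d[i, j] - t_edge)
    if not dists:
        raise ValueError("no mutual punctum pairs")
    return PairDistanceSet(np.asarray(dists) * pixel_nm / ef, mode, ef,
                           pixel_nm)
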