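"""Pre/post-expansion registration and distortion quantification.

Pre-expansion and post-expansion images of the same field of view are
related, to first order, by a similarity transform — rotation, translation
and one uniform scale, whose scale *is* the linear expansion factor (EF).
This module estimates that transform from SIFT keypoint matches filtered by
RANSAC, selects the post-expansion z-projection that best matches a
pre-expansion plane, measures the residual (non-similarity) displacement
field by block matching, and summarizes it as an RMS measurement-error
curve: the RMS of |v(p1) - v(p2)| over point pairs, binned by their
biological-scale separation.  A global translation of the field cancels in
the pairwise differences, so the curve captures genuine distortion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT, match_descriptors, match_template


@dataclass
class SimilarityTransform2D:
    """p_post = s * R(theta) * p_pre + t, points as (x, y) columns.

    Exactly four degrees of freedom; ``scale`` is dimensionless and equals
    the linear expansion factor when mapping pre- to post-expansion
    coordinates.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        s = self.scale
        tx, ty = self.translation
        return np.array([
            [s * np.cos(th), -s * np.sin(th), tx],
            [s * np.sin(th), s * np.cos(th), ty],
            [0.0, 0.0, 1.0],
        ])

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        return p @ m[:2, :2].T + m[:2, 2]

    def inverse(self) -> "SimilarityTransform2D":
        th = np.deg2rad(self.rotation_deg)
        s = self.scale
        tx, ty = self.translation
        # p_pre = R(-th)/s (p_post - t)
        itx = -(np.cos(th) * tx + np.sin(th) * ty) / s
        ity = -(-np.sin(th) * tx + np.cos(th) * ty) / s
        return SimilarityTransform2D(1.0 / s, -self.rotation_deg, (itx, ity))

    def compose(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        """self ∘ other: apply ``other`` first."""
        m = self.matrix @ other.matrix
        s = float(np.hypot(m[0, 0], m[1, 0]))
        th = float(np.degrees(np.arctan2(m[1, 0], m[0, 0])))
        return SimilarityTransform2D(s, th, (float(m[0, 2]), float(m[1, 2])))


@dataclass
class KeypointMatches:
    """Matched keypoint coordinates, (x, y) in each image's frame."""

    pre: np.ndarray        # (N, 2)
    post: np.ndarray       # (N, 2)
    distances: np.ndarray  # (N,) descriptor distances
    detector: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pre)


@dataclass
class DistortionField:
    """Residual displacement vectors v(x, y) on a regular grid of nodes.

    ``nodes`` are (x, y) positions in the pre-image frame; ``vectors`` are
    (vx, vy) in px such that pre(p) corresponds to aligned(p + v(p));
    ``valid`` masks nodes with enough local texture for a reliable estimate.
    """

    nodes: np.ndarray      # (M, 2)
    vectors: np.ndarray    # (M, 2)
    valid: np.ndarray      # (M,) bool
    grid_shape: tuple[int, int] = (0, 0)
    spacing: float = 0.0


@dataclass
class RMSCurve:
    """RMS pairwise measurement error vs measurement length (biological um)."""

    length_um: np.ndarray
    rms_um: np.ndarray
    counts: np.ndarray
    valid: np.ndarray
    min_count: int = 50


# ---------------------------------------------------------------------------
# keypoints
# ---------------------------------------------------------------------------


def detect_and_match_keypoints(img_pre: np.ndarray, img_post: np.ndarray,
                               ratio_threshold: float = 0.8) -> KeypointMatches:
    """SIFT keypoints in both images, matched with Lowe-ratio filtering.

    Matching is mutual-nearest-neighbor on descriptors with a max-ratio
    test, so no pre-keypoint maps to more than one post-keypoint.
    Raises ``ValueError("insufficient features")`` with < 3 matches.
    """
    results = []
    for img in (img_pre, img_post):
        img = np.asarray(img, dtype=float)
        if not np.all(np.isfinite(img)):
            raise ValueError("non-finite image")
        det = SIFT()
        try:
            det.detect_and_extract(img)
            results.append((det.keypoints.copy(), det.descriptors.copy()))
        except RuntimeError:
            results.append((np.zeros((0, 2)), np.zeros((0, 128))))
    (kp1, d1), (kp2, d2) = results
    if len(kp1) < 3 or len(kp2) < 3:
        raise ValueError("insufficient features")
    matches = match_descriptors(d1, d2, cross_check=True,
                                max_ratio=ratio_threshold)
    if len(matches) < 3:
        raise ValueError("insufficient features")
    dist = np.linalg.norm(d1[matches[:, 0]].astype(float)
                          - d2[matches[:, 1]].astype(float), axis=1)
    # skimage keypoints are (row, col) -> (x, y)
    pre = kp1[matches[:, 0]][:, ::-1].astype(float)
    post = kp2[matches[:, 1]][:, ::-1].astype(float)
    return KeypointMatches(pre, post, dist,
                           detector={"type": "SIFT",
                                     "ratio_threshold": ratio_threshold})


# ---------------------------------------------------------------------------
# similarity estimation
# ---------------------------------------------------------------------------


def fit_similarity(pre: np.ndarray, post: np.ndarray) -> SimilarityTransform2D:
    """Closed-form least-squares similarity (Procrustes/Umeyama) fit."""
    pre = np.atleast_2d(np.asarray(pre, dtype=float))
    post = np.atleast_2d(np.asarray(post, dtype=float))
    mu_p = pre.mean(axis=0)
    mu_q = post.mean(axis=0)
    p = pre - mu_p
    q = post - mu_q
    var_p = (p ** 2).sum() / len(p)
    if var_p == 0:
        raise ValueError("degenerate configuration")
    # complex formulation: q = a p, a = s e^{i theta}
    zp = p[:, 0] + 1j * p[:, 1]
    zq = q[:, 0] + 1j * q[:, 1]
    a = np.vdot(zp, zq) / np.vdot(zp, zp)
    s = float(np.abs(a))
    if s == 0:
        raise ValueError("degenerate configuration")
    th = float(np.degrees(np.angle(a)))
    r = np.array([[np.cos(np.deg2rad(th)), -np.sin(np.deg2rad(th))],
                  [np.sin(np.deg2rad(th)), np.cos(np.deg2rad(th))]])
    t = mu_q - s * (r @ mu_p)
    return SimilarityTransform2D(s, th, (float(t[0]), float(t[1])))


def ransac_similarity(matches: KeypointMatches, inlier_tol: float = 2.0,
                      max_iter: int = 5000, min_inliers: int = 10,
                      seed: int = 0):
    """RANSAC fit of a similarity transform to keypoint matches.

    Two-point minimal samples (a similarity is determined by two point
    pairs); the consensus transform is refit on all inliers by the
    closed-form similarity Procrustes.  Reproducible for a fixed seed.

    Returns ``(SimilarityTransform2D, inlier_mask)``.
    """
    pre = matches.pre
    post = matches.post
    n = len(pre)
    if n < 2:
        raise ValueError("need at least 2 matches")
    if np.allclose(pre, pre[0]):
        raise ValueError("degenerate configuration")
    rng = np.random.default_rng(seed)
    best_count = -1
    best_mask = None
    for _ in range(max_iter):
        i, j = rng.choice(n, size=2, replace=False)
        if np.allclose(pre[i], pre[j]) or np.allclose(post[i], post[j]):
            continue
        try:
            t = fit_similarity(pre[[i, j]], post[[i, j]])
        except ValueError:
            continue
        resid = np.linalg.norm(t.apply(pre) - post, axis=1)
        mask = resid < inlier_tol
        count = int(mask.sum())
        if count > best_count:
            best_count = count
            best_mask = mask
            if count == n:
                break
    if best_mask is None or best_count < max(min_inliers, 2):
        raise ValueError("registration failed: too few inliers")
    t = fit_similarity(pre[best_mask], post[best_mask])
    # one refinement pass with the refit transform
    resid = np.linalg.norm(t.apply(pre) - post, axis=1)
    mask = resid < inlier_tol
    if mask.sum() >= 2:
        t = fit_similarity(pre[mask], post[mask])
    else:
        mask = best_mask
    return t, mask


def ef_from_transform(t: SimilarityTransform2D) -> float:
    """The linear expansion factor is the similarity scale."""
    return float(t.scale)


# ---------------------------------------------------------------------------
# z-projection selection
# ---------------------------------------------------------------------------


def select_best_zprojection(pre_plane: np.ndarray, post_stack: np.ndarray,
                            window_min: int = 8, window_max: int = 25,
                            projection: str = "max",
                            ratio_threshold: float = 0.8,
                            inlier_tol: float = 2.0, min_inliers: int = 10,
                            seed: int = 0):
    """Find the post-expansion z-window whose projection best matches a
    pre-expansion plane.

    All contiguous windows of width in [window_min, window_max] are
    projected (maximum-intensity by default), matched against the pre plane
    and scored by RANSAC-inlier keypoint count; the argmax is returned, ties
    broken by smaller window then lower start index.

    Returns ``(window, projection_image, matches, transform)`` with
    ``window = (start, stop)`` exclusive of stop.
    """
    post_stack = np.asarray(post_stack, dtype=float)
    nz = post_stack.shape[0]
    if nz < window_min:
        raise ValueError(f"stack depth {nz} < window_min {window_min}")
    proj_fn = {"max": np.max, "mean": np.mean}[projection]
    best = None  # (score, width, start, window, proj, matches, transform)
    for width in range(window_min, min(window_max, nz) + 1):
        for start in range(0, nz - width + 1):
            proj = proj_fn(post_stack[start:start + width], axis=0)
            try:
                m = detect_and_match_keypoints(pre_plane, proj,
                                               ratio_threshold)
                t, mask = ransac_similarity(m, inlier_tol=inlier_tol,
                                            min_inliers=min_inliers,
                                            seed=seed)
            except ValueError:
                continue
            score = int(mask.sum())
            key = (-score, width, start)
            if best is None or key < best[0]:
                best = (key, (start, start + width), proj, m, t)
    if best is None:
        raise ValueError("no z-window achieved the minimum inlier count")
    return best[1], best[2], best[3], best[4]


# ---------------------------------------------------------------------------
# distortion field
# ---------------------------------------------------------------------------


def _parabolic_offset(c_m, c_0, c_p):
    """Sub-pixel peak offset from three samples; Gaussian (log-parabolic)
    fit when all samples are positive — exact for Gaussian-shaped
    correlation peaks — plain parabola otherwise."""
    if c_m > 0 and c_0 > 0 and c_p > 0:
        c_m, c_0, c_p = np.log(c_m), np.log(c_0), np.log(c_p)
    denom = c_m - 2 * c_0 + c_p
    if denom == 0:
        return 0.0
    off = 0.5 * (c_m - c_p) / denom
    return float(np.clip(off, -1.0, 1.0))


def _lk_refine(post, tpl, cy, cx, vy, vx, half, n_iter=15, tol=1e-3):
    """Gradient-based (Lucas–Kanade) sub-pixel refinement of one block's
    displacement, starting from the integer NCC estimate."""
    from scipy.ndimage import map_coordinates

    by, bx = np.mgrid[cy - half:cy + half + 1, cx - half:cx + half + 1]
    by = by.astype(float)
    bx = bx.astype(float)
    gy_t, gx_t = np.gradient(tpl)
    # center-weighting keeps the estimate local to the node, reducing the
    # attenuation of displacement variation across the block
    ax = np.arange(2 * half + 1) - half
    g1 = np.exp(-0.5 * (ax / (half / 2.0)) ** 2)
    w = np.outer(g1, g1)
    a11 = (w * gx_t * gx_t).sum()
    a12 = (w * gx_t * gy_t).sum()
    a22 = (w * gy_t * gy_t).sum()
    det = a11 * a22 - a12 ** 2
    if det <= 0:
        return vy, vx, False
    for _ in range(n_iter):
        blk = map_coordinates(post, [(by + vy).ravel(), (bx + vx).ravel()],
                              order=1, mode="nearest").reshape(tpl.shape)
        e = blk - tpl
        b1 = (w * gx_t * e).sum()
        b2 = (w * gy_t * e).sum()
        dx = -(a22 * b1 - a12 * b2) / det
        dy = -(-a12 * b1 + a11 * b2) / det
        vx += dx
        vy += dy
        if abs(dx) < tol and abs(dy) < tol:
            break
    return vy, vx, True


def _block_match_pass(pre, post, xs, ys, half, search_radius, min_texture,
                      dyn):
    pad = half + search_radius
    vectors, valid = [], []
    for cy in ys:
        for cx in xs:
            tpl = pre[cy - half:cy + half + 1, cx - half:cx + half + 1]
            if tpl.std() < min_texture * dyn:
                vectors.append((np.nan, np.nan))
                valid.append(False)
                continue
            win = post[cy - pad:cy + pad + 1, cx - pad:cx + pad + 1]
            ncc = match_template(win, tpl)  # (2r+1, 2r+1)
            iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
            vy = float(iy - search_radius)
            vx = float(ix - search_radius)
            vy2, vx2, ok = _lk_refine(post, tpl, cy, cx, vy, vx, half)
            if ok and abs(vy2 - vy) <= 2 and abs(vx2 - vx) <= 2:
                vy, vx = vy2, vx2
            else:
                if 0 < iy < ncc.shape[0] - 1:
                    vy += _parabolic_offset(ncc[iy - 1, ix], ncc[iy, ix],
                                            ncc[iy + 1, ix])
                if 0 < ix < ncc.shape[1] - 1:
                    vx += _parabolic_offset(ncc[iy, ix - 1], ncc[iy, ix],
                                            ncc[iy, ix + 1])
            vectors.append((vx, vy))
            valid.append(True)
    return np.asarray(vectors, dtype=float), np.asarray(valid)


def estimate_distortion_field(pre: np.ndarray, post_aligned: np.ndarray,
                              block_size: int = 32, search_radius: int = 8,
                              min_texture: float = 1e-3, iterations: int = 3,
                              node_spacing: int | None = None) -> DistortionField:
    """Residual displacement field by local normalized cross-correlation.

    ``post_aligned`` must already be mapped into the pre-image frame by the
    similarity transform.  On a regular grid of nodes, the pre-image block
    around each node is matched within a search window of the aligned image;
    the NCC peak, refined to sub-pixel accuracy by 3-point parabolic
    interpolation, gives v(node) such that pre(p) ~ aligned(p + v).

    A single block-matching pass attenuates displacement variation within a
    block (block averaging), so the estimate is refined iteratively: the
    current field is spline-interpolated, the aligned image is unwarped by
    it, and the residual is re-estimated and accumulated — the attenuated
    remainder shrinks geometrically with each pass.  Nodes whose pre block
    has standard deviation below ``min_texture`` (relative to the dynamic
    range) are masked invalid.
    """
    from scipy.interpolate import RectBivariateSpline
    from scipy.ndimage import map_coordinates

    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post_aligned, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and aligned post must have the same shape")
    ny, nx = pre.shape
    half = block_size // 2
    pad = half + search_radius
    dyn = pre.max() - pre.min()
    if dyn == 0:
        raise ValueError("no texture")
    if node_spacing is None:
        node_spacing = max(block_size // 2, 4)  # PIV-style 50% overlap
    xs = np.arange(pad, nx - pad, node_spacing)
    ys = np.arange(pad, ny - pad, node_spacing)
    nodes = np.array([(cx, cy) for cy in ys for cx in xs], dtype=float)

    total = np.zeros((len(nodes), 2))
    valid = None
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    can_refine = len(ys) >= 2 and len(xs) >= 2
    for it in range(max(iterations, 1)):
        if it == 0:
            cur_post = post
        else:
            # unwarp: cur(p) = aligned(p + V(p)) with V the accumulated field
            shape2 = (len(ys), len(xs))
            grid_ok = valid.reshape(shape2)
            vx = np.where(grid_ok, total[:, 0].reshape(shape2), 0.0)
            vy = np.where(grid_ok, total[:, 1].reshape(shape2), 0.0)
            k = min(3, len(ys) - 1, len(xs) - 1)
            sx = RectBivariateSpline(ys, xs, vx, kx=k, ky=k)
            sy = RectBivariateSpline(ys, xs, vy, kx=k, ky=k)
            cur_post = map_coordinates(
                post, [(yy + sy.ev(yy, xx)).ravel(),
                       (xx + sx.ev(yy, xx)).ravel()],
                order=3, mode="nearest").reshape(ny, nx)
        vec, ok = _block_match_pass(pre, cur_post, xs, ys, half,
                                    search_radius, min_texture, dyn)
        if valid is None:
            valid = ok
            if not valid.any():
                raise ValueError("no texture")
        vec = np.where(np.isfinite(vec), vec, 0.0)
        total[valid] += vec[valid]
        if not can_refine:
            break
    out = np.where(valid[:, None], total, np.nan)
    return DistortionField(nodes, out, valid,
                           grid_shape=(len(ys), len(xs)),
                           spacing=float(node_spacing))


def rms_error_curve(fld: DistortionField, n_pairs: int = 100000,
                    bin_edges_um: np.ndarray | None = None,
                    pixel_nm: float = 100.0, ef: float = 1.0,
                    min_count: int = 50, seed: int = 0) -> RMSCurve:
    """RMS length-measurement error vs biological-scale measurement length.

    Random pairs of valid nodes are sampled; the error of measuring the
    distance between two points is the norm of the difference of their
    residual displacement vectors, |v(p1) - v(p2)|.  Pairs are binned by
    their biological separation |p1 - p2| * pixel_nm / ef and the RMS error
    (same scale conversion) is reported per bin.  If the field lives in the
    pre-expansion (biological) frame already, pass the pre pixel size and
    ef=1.  Bins with fewer than ``min_count`` pairs are flagged invalid.
    """
    if ef <= 0:
        raise ValueError("ef must be > 0")
    nodes = fld.nodes[fld.valid]
    vecs = fld.vectors[fld.valid]
    if len(nodes) < 2:
        raise ValueError("need at least 2 valid nodes")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, len(nodes), n_pairs)
    j = rng.integers(0, len(nodes), n_pairs)
    keep = i != j
    i, j = i[keep], j[keep]
    to_um = pixel_nm / ef / 1000.0
    sep = np.linalg.norm(nodes[i] - nodes[j], axis=1) * to_um
    err = np.linalg.norm(vecs[i] - vecs[j], axis=1) * to_um
    if bin_edges_um is None:
        bin_edges_um = np.linspace(0.0, sep.max() * 1.0001, 11)
    bin_edges_um = np.asarray(bin_edges_um, dtype=float)
    idx = np.digitize(sep, bin_edges_um) - 1
    nb = len(bin_edges_um) - 1
    rms = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b] > 0:
            rms[b] = float(np.sqrt(np.mean(err[sel] ** 2)))
    centers = 0.5 * (bin_edges_um[:-1] + bin_edges_um[1:])
    return RMSCurve(centers, rms, counts, counts >= min_count, min_count)


def register_expansion_pair(img_pre: np.ndarray, img_post: np.ndarray,
                            ratio_threshold: float = 0.8,
                            inlier_tol: float = 2.0, min_inliers: int = 10,
                            seed: int = 0):
    """Convenience chain: keypoints -> RANSAC similarity -> aligned post.

    Returns ``(transform, aligned_post, matches, inlier_mask)`` with the
    post image resampled into the pre frame (cubic interpolation).
    """
    from scipy import ndimage as ndi

    m = detect_and_match_keypoints(img_pre, img_post, ratio_threshold)
    t, mask = ransac_similarity(m, inlier_tol=inlier_tol,
                                min_inliers=min_inliers, seed=seed)
    ny, nx = np.asarray(img_pre).shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    src = t.apply(pts)  # pre coords -> post coords
    aligned = ndi.map_coordinates(np.asarray(img_post, dtype=float),
                                  [src[:, 1], src[:, 0]], order=3,
                                  mode="constant", cval=0.0).reshape(ny, nx)
    return t, aligned, m, mask
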