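"""Axoneme defect scoring and contingency-table statistics.

A motile cilium's axoneme normally shows nine outer microtubule doublets
around a central pair ("9+2").  A cross-section is called *normal* exactly
when nine outer subunits and two central subunits are counted, otherwise
*defective*.  Defect proportions across conditions (or across imaging
methods) are compared with the Pearson chi-square test at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import chi2
from skimage.feature import peak_local_max

from .morphometry import radial_profile


@dataclass
class CiliumCall:
    n_outer: int
    n_central: int
    call: str = field(init=False)
    source: str = ""

    def __post_init__(self) -> None:
        if self.n_outer < 0 or self.n_central < 0:
            raise ValueError("counts must be >= 0")
        self.call = ("normal" if (self.n_outer == 9 and self.n_central == 2)
                     else "defective")


@dataclass
class DefectCounts:
    """Per-condition (normal, defective) counts; unscorable images tallied
    separately, never classified."""

    conditions: list[str]
    normal: np.ndarray
    defective: np.ndarray
    unscorable: np.ndarray | None = None

    def table(self) -> np.ndarray:
        return np.column_stack([self.normal, self.defective])


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected: bool
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def classify_cilium(n_outer: int, n_central: int,
                    source: str = "") -> CiliumCall:
    """Normal iff nine outer subunits and two central subunits."""
    return CiliumCall(n_outer, n_central, source=source)


def count_central(image: np.ndarray, center, radius: float,
                  min_distance: int = 2, rel_threshold: float = 0.3) -> int:
    """Count intensity maxima inside the central disk of an axoneme ring."""
    img = np.asarray(image, dtype=float)
    cx, cy = center
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    sub = np.where(mask, img, 0.0)
    if sub.max() <= 0:
        return 0
    pk = peak_local_max(sub, min_distance=min_distance,
                        threshold_abs=rel_threshold * sub.max(),
                        exclude_border=False)
    return len(pk)


def score_ring_image(image: np.ndarray, center_init=None,
                     central_radius: float | None = None,
                     peak_prominence: float = 0.2,
                     source: str = "") -> CiliumCall:
    """Count outer and central subunits of one axoneme cross-section.

    Outer count = angular peaks at the outer-ring radius (from the radial
    profile); central count = local maxima within the central disk (half the
    ring radius by default).
    """
    prof = radial_profile(image, center_init=center_init,
                          peak_prominence=peak_prominence)
    n_outer = len(prof.peak_angles_deg)
    r_cen = central_radius if central_radius is not None \
        else 0.5 * prof.peak_radius_px
    n_central = count_central(image, prof.center, r_cen)
    return classify_cilium(n_outer, n_central, source=source)


def assess_cilia(images_by_condition: dict, **score_kwargs) -> DefectCounts:
    """Score batches of ring images and aggregate calls per condition.

    ``images_by_condition`` maps condition label -> list of images.  Images
    the profiler cannot measure (flat, no ring) are excluded and counted in
    the ``unscorable`` tally rather than silently dropped or classified.
    """
    conds, nn, nd, nu = [], [], [], []
    for cond, images in images_by_condition.items():
        n_norm = n_def = n_uns = 0
        for i, img in enumerate(images):
            try:
                call = score_ring_image(img, source=f"{cond}[{i}]",
                                        **score_kwargs)
            except ValueError:
                n_uns += 1
                continue
            if call.call == "normal":
                n_norm += 1
            else:
                n_def += 1
        conds.append(cond)
        nn.append(n_norm)
        nd.append(n_def)
        nu.append(n_uns)
    return DefectCounts(conds, np.asarray(nn), np.asarray(nd), np.asarray(nu))


def chisq_proportions(table, alpha: float = 0.05,
                      yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity on an r x c count table.

    statistic = sum (O - E)^2 / E with E from the product of marginals;
    df = (r-1)(c-1); upper-tail p-value.  Expected counts below 5 set the
    ``low_expected`` flag.  No continuity correction by default (``yates``
    applies the Yates correction for 2x2 tables).
    """
    if isinstance(table, DefectCounts):
        obs = table.table().astype(float)
    else:
        obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: zero marginal")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(chi2.sf(stat, df))
    return ChiSquareResult(stat, df, p, expected,
                           low_expected=bool(np.any(expected < 5)),
                           alpha=alpha)
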