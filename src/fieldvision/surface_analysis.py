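"""Curvature analysis of recovered plant surfaces.

Once a surface ``z = f(x, y)`` has been recovered (from photometric
stereo or a depth camera) its local shape can be classified from the
mean curvature H and Gaussian curvature K, computed from the smoothed
Hessian of the depth map using the full Monge-patch formulas (leaf
slopes are not small, so the first-derivative terms are kept):

    K = (fxx*fyy - fxy^2) / (1 + fx^2 + fy^2)^2
    H = ((1+fx^2)*fyy - 2*fx*fy*fxy + (1+fy^2)*fxx)
        / (2*(1 + fx^2 + fy^2)^(3/2))

Principal curvatures are ``k1, k2 = H +- sqrt(H^2 - K)`` and the shape
index ``S = (2/pi) * arctan((k1 + k2)/(k2 - k1))`` is a scale-free
descriptor in [-1, 1] spanning cup -> trough -> saddle -> ridge -> cap.

The HK label map supports meristem localisation for directed weeding: a
rosette weed's growing point sits in a central depression, which under
the convention ``z`` toward the camera appears as a *pit* (H > 0,
K > 0).  An alternative detector scans localised histograms of the
one-axis gradient field produced by the moving-platform two-light rig,
scoring windows with a pluggable trained classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.transform import resize

from .ps_core import DepthMap, SurfaceFields

__all__ = [
    "HKClass",
    "CurvatureField",
    "HKLabelMap",
    "MeristemCandidate",
    "curvature_fields",
    "hk_segment",
    "detect_meristem_hk",
    "gradient_histogram_features",
    "train_linear_scorer",
    "scan_meristem_classifier",
    "leaf_area_3d",
]

DEFAULT_EPS_H = 2e-3  # px^-1
DEFAULT_EPS_K = 1e-5  # px^-2


class HKClass(Enum):
    """Surface-type taxonomy from the signs of H and K."""

    PEAK = 0
    PIT = 1
    RIDGE = 2
    VALLEY = 3
    SADDLE_RIDGE = 4
    SADDLE_VALLEY = 5
    FLAT = 6
    MINIMAL = 7


@dataclass
class CurvatureField:
    H: np.ndarray
    K: np.ndarray
    k1: np.ndarray  # larger principal curvature
    k2: np.ndarray  # smaller principal curvature
    S: np.ndarray  # shape index, NaN where k1 == k2 == 0
    valid_mask: np.ndarray


@dataclass
class HKLabelMap:
    labels: np.ndarray  # int raster of HKClass values
    eps_H: float
    eps_K: float
    valid_mask: np.ndarray

    def class_mask(self, cls: HKClass) -> np.ndarray:
        return (self.labels == cls.value) & self.valid_mask


@dataclass
class MeristemCandidate:
    location: tuple[float, float]  # (row, col)
    score: float
    method: str


def curvature_fields(
    depth: DepthMap, sigma: float = 2.0, mask: np.ndarray | None = None
) -> CurvatureField:
    """Mean/Gaussian/principal curvatures and shape index of a depth map.

    Derivatives are Gaussian-smoothed central differences at scale
    ``sigma`` (pixels); sigma=0 uses plain central differences.  Units:
    H in 1/px, K in 1/px^2 (multiply by pitch factors for metric
    curvatures).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    z = depth.z
    if min(z.shape) < 5:
        raise ValueError("depth raster smaller than the differentiation stencil")
    if mask is None:
        mask = depth.valid_mask
    # detrend: remove the best-fit plane before smoothing so boundary
    # padding does not bend a tilted surface; the removed slopes are
    # added back to the first derivatives (second derivatives unchanged)
    rr, cc = np.nonzero(mask)
    design = np.column_stack([cc, rr, np.ones(len(rr))])
    coef, *_ = np.linalg.lstsq(design, z[mask], rcond=None)
    yy, xx = np.mgrid[0 : z.shape[0], 0 : z.shape[1]].astype(float)
    trend = coef[0] * xx + coef[1] * yy + coef[2]
    zf = np.where(mask, z - trend, 0.0)
    if sigma > 0:
        zf = ndimage.gaussian_filter(zf, sigma, mode="nearest")
    fy, fx = np.gradient(zf)
    fx += coef[0]
    fy += coef[1]
    fyy, fyx = np.gradient(fy)
    fxy, fxx = np.gradient(fx)
    fxy = (fxy + fyx) / 2
    w = 1.0 + fx * fx + fy * fy
    K = (fxx * fyy - fxy * fxy) / (w * w)
    H = ((1 + fx * fx) * fyy - 2 * fx * fy * fxy + (1 + fy * fy) * fxx) / (
        2 * w**1.5
    )
    disc = np.sqrt(np.maximum(H * H - K, 0.0))
    k1 = H + disc
    k2 = H - disc
    S = np.full(z.shape, np.nan)
    diff = k2 - k1  # <= 0
    defined = np.abs(diff) > 1e-15
    S[defined] = (2.0 / np.pi) * np.arctan(
        (k2[defined] + k1[defined]) / diff[defined]
    )
    # erode the mask so border pixels touched by one-sided stencils or the
    # smoothing kernel's support are excluded
    border = 2 + int(np.ceil(2 * sigma))
    interior = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3), bool), iterations=border, border_value=0
    )
    return CurvatureField(H, K, k1, k2, S, interior)


def hk_segment(
    curv: CurvatureField,
    eps_H: float = DEFAULT_EPS_H,
    eps_K: float = DEFAULT_EPS_K,
) -> HKLabelMap:
    """Classify every valid pixel by the signs of H and K.

    Thresholds ``eps_H``/``eps_K`` define the dead band treated as zero
    curvature.  With z increasing toward the camera, a bump facing the
    camera has H < 0 (peak) and a depression H > 0 (pit).
    """
    if eps_H <= 0 or eps_K <= 0:
        raise ValueError("eps_H and eps_K must be positive")
    H, K = curv.H, curv.K
    h0 = np.abs(H) <= eps_H
    k0 = np.abs(K) <= eps_K
    hn, hp = H < -eps_H, H > eps_H
    kn, kp = K < -eps_K, K > eps_K
    labels = np.full(H.shape, HKClass.FLAT.value, dtype=np.int8)
    labels[h0 & kn] = HKClass.MINIMAL.value
    labels[hn & kp] = HKClass.PEAK.value
    labels[hp & kp] = HKClass.PIT.value
    labels[hn & k0] = HKClass.RIDGE.value
    labels[hp & k0] = HKClass.VALLEY.value
    labels[hn & kn] = HKClass.SADDLE_RIDGE.value
    labels[hp & kn] = HKClass.SADDLE_VALLEY.value
    return HKLabelMap(labels, eps_H, eps_K, curv.valid_mask.copy())


def detect_meristem_hk(
    labels: HKLabelMap,
    curv: CurvatureField,
    min_blob_px: int = 5,
    polarity: str = "pit",
) -> list[MeristemCandidate]:
    """Meristem candidates from connected pit (or peak) components.

    Each component of at least ``min_blob_px`` pixels yields one
    candidate at its |K|-weighted centroid with score = mean |K|;
    candidates are sorted by descending score.  Polarity defaults to
    "pit" (the central depression of a rosette); "peak" suits plants
    whose growing point protrudes.
    """
    if min_blob_px < 1:
        raise ValueError("min_blob_px must be >= 1")
    cls = HKClass.PIT if polarity == "pit" else HKClass.PEAK
    target = labels.class_mask(cls)
    comp = cc_label(target, connectivity=2)
    out: list[MeristemCandidate] = []
    absk = np.abs(curv.K)
    for lab in range(1, comp.max() + 1):
        sel = comp == lab
        n = int(sel.sum())
        if n < min_blob_px:
            continue
        wts = absk[sel]
        rr, cc = np.nonzero(sel)
        total = wts.sum()
        if total <= 0:
            loc = (rr.mean(), cc.mean())
        else:
            loc = (float((rr * wts).sum() / total), float((cc * wts).sum() / total))
        out.append(MeristemCandidate(loc, float(wts.mean()), "hk"))
    out.sort(key=lambda c: -c.score)
    return out


# ---------------------------------------------------------------------------
# Gradient-histogram meristem scoring (two-light moving-platform data)


def _window_grid(shape: tuple[int, int], window_px: int, stride: int):
    h, w = shape
    if window_px > min(h, w):
        raise ValueError("window larger than image")
    rows = list(range(0, h - window_px + 1, stride))
    cols = list(range(0, w - window_px + 1, stride))
    return rows, cols


def gradient_histogram_features(
    p: np.ndarray,
    window_px: int = 16,
    n_bins: int = 12,
    stride: int | None = None,
    p_range: float = 1.5,
) -> np.ndarray:
    """L1-normalised histograms of x-gradient values over sliding windows.

    Returns an (n_rows, n_cols, n_bins) array; bin edges are fixed and
    symmetric over [-p_range, p_range] with values clipped into range,
    so features are comparable across images.
    """
    if window_px < 4 or n_bins < 4:
        raise ValueError("need window_px >= 4 and n_bins >= 4")
    p = np.asarray(p, dtype=float)
    stride = stride or max(window_px // 2, 1)
    rows, cols = _window_grid(p.shape, window_px, stride)
    edges = np.linspace(-p_range, p_range, n_bins + 1)
    clipped = np.clip(p, -p_range, p_range - 1e-12)
    feats = np.empty((len(rows), len(cols), n_bins))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            win = clipped[r : r + window_px, c : c + window_px]
            hist, _ = np.histogram(win, bins=edges)
            feats[i, j] = hist / hist.sum()
    return feats


def train_linear_scorer(
    pos: Sequence[np.ndarray], neg: Sequence[np.ndarray]
) -> Callable[[np.ndarray], float]:
    """Minimal reference trainer: a linear margin scorer.

    Fits the direction between class means in feature space, whitened
    by the pooled per-feature variance (a Fisher-style linear
    discriminant without the full covariance).  Returns a callable
    mapping one feature vector to a scalar score, larger for
    meristem-like windows.  Any stronger binary classifier with the
    same signature can be plugged in instead.
    """
    xp = np.asarray(pos, dtype=float)
    xn = np.asarray(neg, dtype=float)
    mp, mn = xp.mean(axis=0), xn.mean(axis=0)
    var = (xp.var(axis=0) * len(xp) + xn.var(axis=0) * len(xn)) / (
        len(xp) + len(xn)
    )
    w = (mp - mn) / (var + 1e-9)
    b = -0.5 * (w @ mp + w @ mn)

    def scorer(f: np.ndarray) -> float:
        return float(w @ np.asarray(f, dtype=float) + b)

    return scorer


def scan_meristem_classifier(
    p: np.ndarray,
    scorer: Callable[[np.ndarray], float],
    window_px: int = 16,
    n_bins: int = 12,
    stride: int | None = None,
    p_range: float = 1.5,
) -> tuple[np.ndarray, MeristemCandidate]:
    """Slide the scorer over gradient-histogram windows.

    Returns a heat raster (window scores upsampled to the image size)
    and the best-scoring window centre as a candidate.  Ties break to
    the smallest (row, col) in scan order.
    """
    p = np.asarray(p, dtype=float)
    stride = stride or max(window_px // 2, 1)
    feats = gradient_histogram_features(p, window_px, n_bins, stride, p_range)
    nr, nc, _ = feats.shape
    scores = np.empty((nr, nc))
    for i in range(nr):
        for j in range(nc):
            scores[i, j] = scorer(feats[i, j])
    best_flat = int(np.argmax(scores))  # first max in scan order
    bi, bj = divmod(best_flat, nc)
    centre = (bi * stride + window_px / 2, bj * stride + window_px / 2)
    cand = MeristemCandidate(centre, float(scores[bi, bj]), "gradient_hist")
    heat = resize(scores, p.shape, order=1, mode="edge", anti_aliasing=False)
    return heat, cand


def leaf_area_3d(
    fields: SurfaceFields, mask: np.ndarray, pixel_pitch: float
) -> tuple[float, int]:
    """True (unforeshortened) leaf area over a pixel mask, in mm^2.

    Each pixel's projected area ``pitch^2`` is scaled by
    ``sqrt(1 + p^2 + q^2)``, the inverse cosine of the surface tilt, so
    parallax/foreshortening is removed.  Invalid pixels inside the mask
    are excluded; their count is returned alongside the area.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty leaf mask")
    usable = mask & fields.valid_mask
    excluded = int(mask.sum() - usable.sum())
    scale = np.sqrt(1.0 + fields.p[usable] ** 2 + fields.q[usable] ** 2)
    return float(pixel_pitch**2 * scale.sum()), excluded
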