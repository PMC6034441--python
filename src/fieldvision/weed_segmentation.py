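"""Texture-entropy segmentation of broad-leaved weeds in grass.

Grass canopy shows high-frequency, multi-directional texture, so the
grey-level distribution inside a local window is close to uniform and
its Shannon entropy is high.  Broad smooth leaves such as dock (Rumex
obtusifolius) concentrate the local histogram into a few levels and
score low.  The pipeline is: local entropy filtering (default 32 x 32
pixel window), thresholding the entropy map (low entropy = weed),
morphological opening/closing, and small-component removal.  A depth
band-pass ("range threshold") can additionally reject structures
outside the expected canopy height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import sobel, threshold_otsu
from skimage.filters.rank import entropy as _rank_entropy
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.morphology import opening as _opening

from .ps_core import DepthMap

__all__ = [
    "EntropyMap",
    "WeedRegion",
    "WeedMask",
    "edge_filter",
    "local_entropy",
    "segment_dock",
    "range_threshold_fuse",
    "excess_green",
]

#: Cap applied to the automatic (Otsu) entropy threshold, as a fraction
#: of the maximum achievable entropy log2(n_levels).  Otsu always finds
#: a split; on a weed-free scene that split sits inside the high-entropy
#: grass mode, so thresholds above this cap are rejected.
AUTO_THRESHOLD_CAP = 0.75


@dataclass
class EntropyMap:
    entropy: np.ndarray  # bits
    window_px: int
    n_levels: int


@dataclass
class WeedRegion:
    area_px: int
    centroid: tuple[float, float]  # (row, col)


@dataclass
class WeedMask:
    mask: np.ndarray
    regions: list[WeedRegion] = field(default_factory=list)

    @property
    def coverage_fraction(self) -> float:
        return float(self.mask.sum() / self.mask.size)

    @classmethod
    def from_binary(cls, mask: np.ndarray) -> "WeedMask":
        mask = np.asarray(mask, dtype=bool)
        comp = cc_label(mask, connectivity=2)
        regions = [
            WeedRegion(int(r.area), tuple(map(float, r.centroid)))
            for r in regionprops(comp)
        ]
        return cls(mask, regions)


def excess_green(rgb: np.ndarray) -> np.ndarray:
    """Green-excess channel 2G - R - B, rescaled to [0, 1].

    Highlights green vegetation against soil; for grass-on-grass scenes
    plain luminance is the better input.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) colour image")
    ex = 2 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    lo, hi = ex.min(), ex.max()
    return (ex - lo) / (hi - lo) if hi > lo else np.zeros(ex.shape)


def edge_filter(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, normalised to [0, 1]."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("edge_filter expects a single-channel image")
    mag = sobel(image)
    top = mag.max()
    if top <= 1e-12 * max(1.0, np.abs(image).max()):
        return np.zeros_like(mag)
    return mag / top


def local_entropy(
    image: np.ndarray, window_px: int = 32, n_levels: int = 256
) -> EntropyMap:
    """Shannon entropy (bits) of the local grey histogram per pixel.

    The image is quantised to ``n_levels`` grey levels; entropy is
    computed over a centred ``window_px`` square with reflect padding
    at the borders, so the output matches the input shape.
    """
    if window_px < 2 or n_levels < 2:
        raise ValueError("need window_px >= 2 and n_levels >= 2")
    if n_levels > 256:
        raise ValueError("n_levels above 256 is not supported")
    image = np.asarray(image, dtype=float)
    quant = np.clip((image * n_levels).astype(np.int64), 0, n_levels - 1).astype(
        np.uint8
    )
    pad = window_px // 2
    padded = np.pad(quant, pad, mode="reflect")
    footprint = np.ones((window_px, window_px), dtype=bool)
    ent = _rank_entropy(padded, footprint)
    # the rank filter centres an even window at floor(w/2): crop back
    h, w = image.shape
    ent = ent[pad : pad + h, pad : pad + w]
    return EntropyMap(ent, window_px, n_levels)


def segment_dock(
    entropy: EntropyMap,
    threshold_bits: float | None = None,
    open_px: int = 5,
    close_px: int = 9,
    min_area_px: int = 200,
) -> WeedMask:
    """Threshold low-entropy regions and clean them morphologically.

    ``threshold_bits=None`` selects the threshold automatically with
    Otsu's method on the entropy map, capped at
    ``AUTO_THRESHOLD_CAP * log2(n_levels)`` so that weed-free scenes
    (whose entropy histogram is unimodal and high) yield an empty mask.
    The mask is opened (disk ``open_px``), closed (disk ``close_px``)
    and components below ``min_area_px`` are dropped.
    """
    max_bits = np.log2(entropy.n_levels)
    if threshold_bits is None:
        threshold_bits = min(
            float(threshold_otsu(entropy.entropy)), AUTO_THRESHOLD_CAP * max_bits
        )
    if not (0 <= threshold_bits <= max_bits):
        raise ValueError("threshold outside [0, log2(n_levels)]")
    mask = entropy.entropy < threshold_bits
    if open_px > 0:
        mask = _opening(mask, disk(open_px))
    if close_px > 0:
        mask = _closing(mask, disk(close_px))
    if min_area_px > 0:
        comp = cc_label(mask, connectivity=2)
        for r in regionprops(comp):
            if r.area < min_area_px:
                mask[comp == r.label] = False
    return WeedMask.from_binary(mask)


def range_threshold_fuse(
    weed: WeedMask, depth: DepthMap, z_min: float, z_max: float
) -> WeedMask:
    """Keep mask pixels whose depth lies inside [z_min, z_max].

    Fusing the 2-D entropy decision with a 3-D height band rejects
    structures at implausible canopy heights; regions and coverage are
    recomputed on the fused mask.
    """
    if depth.z.shape != weed.mask.shape:
        raise ValueError("depth map and weed mask shapes differ")
    keep = (depth.z >= z_min) & (depth.z <= z_max) & depth.valid_mask
    return WeedMask.from_binary(weed.mask & keep)
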