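"""Synthetic scenes with exact ground truth for every pipeline.

Each generator is a pure function of its parameters and seed and
returns the analytic truth alongside the rendered data:

* ``make_surface`` — closed-form test surfaces (plane, sphere cap,
  cylinder, saddle, ellipsoid, lobed leaf, rosette) with exact
  gradient-space slopes and unit normals.
* ``render_lambertian`` — the forward Lambertian imaging model
  ``I = clip(rho * max(0, n.l) + noise, 0, 1)`` for a calibrated light
  set, with the attached-shadow truth mask recorded.
* ``make_conveyor_frame`` — a belt-plane depth frame populated with
  upper-half ellipsoid tubers (optionally touching), with true axes,
  sieve sizes and bands.
* ``make_grass_dock`` — high-entropy multi-orientation grass texture
  with smooth low-entropy dock blobs and their truth mask.
* ``make_gps_scene`` — a serpentine harvester track with Poisson-timed
  banded tuber records.

Noise is additive Gaussian on intensities or depth; Kinect-style depth
quantisation can be emulated with a 1 mm rounding flag.  Cast shadows
are not modelled (attached shadows only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import FieldVisionError
from .field_mapping import EARTH_M_PER_DEG_LAT, GpsTrack
from .potato_metrology import (
    DEFAULT_BAND_EDGES,
    DepthFrame,
    TuberRecord,
    band_labels,
    sieve_size_bruteforce,
    size_band,
)
from .ps_core import DepthMap, ImageStack, LightSet, SurfaceFields

__all__ = [
    "SceneSpec",
    "make_surface",
    "render_lambertian",
    "make_conveyor_frame",
    "make_grass_dock",
    "make_gps_scene",
]

SURFACE_KINDS = ("plane", "sphere", "cylinder", "saddle", "ellipsoid", "leaf", "rosette")


@dataclass
class SceneSpec:
    """Declarative description of a synthetic scene."""

    kind: str
    params: dict = dc_field(default_factory=dict)
    seed: int = 0
    noise_sigma: float = 0.0


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred pixel coordinates: x = col - centre, y = row - centre."""
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size].astype(float)
    return x - c, y - c


def _gaussian_bump(x, y, amp, sx, sy, x0=0.0, y0=0.0):
    """z, dz/dx, dz/dy of an anisotropic Gaussian bump."""
    u, v = x - x0, y - y0
    z = amp * np.exp(-(u * u) / (2 * sx * sx) - (v * v) / (2 * sy * sy))
    return z, -z * u / (sx * sx), -z * v / (sy * sy)


def make_surface(
    spec: SceneSpec,
) -> tuple[DepthMap, SurfaceFields, np.ndarray]:
    """Analytic surface with exact gradients on its mask.

    Returns ``(depth, fields, mask)``; the fields' ``p``/``q`` are the
    closed-form slopes (zero outside the mask), so solver output can be
    compared against exact truth.  The rosette records its meristem
    centre in ``spec.params['centre']`` (set on return).
    """
    kind = spec.kind
    if kind not in SURFACE_KINDS:
        raise ValueError(f"unknown surface kind {kind!r}")
    p_par = spec.params
    size = int(p_par.get("size", 128))
    x, y = _grid(size)
    mask = np.ones((size, size), dtype=bool)

    if kind == "plane":
        slope_p = float(p_par.get("p", 0.0))
        slope_q = float(p_par.get("q", 0.0))
        # p = -dz/dx  =>  z = -p*x - q*y (+ offset)
        z = -slope_p * x - slope_q * y + float(p_par.get("offset", 0.0))
        p = np.full_like(z, slope_p)
        q = np.full_like(z, slope_q)

    elif kind == "sphere":
        r_sph = float(p_par.get("radius", 50.0))
        r_cap = float(p_par.get("cap_radius", 0.7 * r_sph))
        if r_sph <= 0 or not (0 < r_cap < r_sph):
            raise ValueError("need radius > 0 and 0 < cap_radius < radius")
        r2 = x * x + y * y
        mask = r2 <= r_cap * r_cap
        s = np.sqrt(np.clip(r_sph * r_sph - r2, 1e-12, None))
        z = np.where(mask, s - math.sqrt(r_sph**2 - r_cap**2), 0.0)
        # dz/dx = -x/s  =>  p = x/s
        p = np.where(mask, x / s, 0.0)
        q = np.where(mask, y / s, 0.0)

    elif kind == "cylinder":
        r_cyl = float(p_par.get("radius", 60.0))
        half = float(p_par.get("half_width", 0.7 * r_cyl))
        if r_cyl <= 0 or not (0 < half < r_cyl):
            raise ValueError("need radius > 0 and 0 < half_width < radius")
        mask = np.abs(x) <= half
        s = np.sqrt(np.clip(r_cyl * r_cyl - x * x, 1e-12, None))
        z = np.where(mask, s - math.sqrt(r_cyl**2 - half**2), 0.0)
        p = np.where(mask, x / s, 0.0)
        q = np.zeros_like(z)

    elif kind == "saddle":
        r_sc = float(p_par.get("scale", 100.0))
        if r_sc <= 0:
            raise ValueError("scale must be positive")
        z = (x * x - y * y) / (2 * r_sc)
        p = -x / r_sc  # p = -dz/dx
        q = y / r_sc

    elif kind == "ellipsoid":
        a = float(p_par.get("a", 50.0))
        b = float(p_par.get("b", 35.0))
        c = float(p_par.get("c", 25.0))
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        w = 1 - (x / a) ** 2 - (y / b) ** 2
        mask = w > 0.05  # avoid the vertical rim where slopes diverge
        s = np.sqrt(np.clip(w, 1e-12, None))
        z = np.where(mask, c * s, 0.0)
        p = np.where(mask, (c * x) / (a * a * s), 0.0)
        q = np.where(mask, (c * y) / (b * b * s), 0.0)

    elif kind == "leaf":
        rng = np.random.default_rng(spec.seed)
        amp = float(p_par.get("amp", 8.0))
        vein_amp = float(p_par.get("vein_amp", 0.0))
        sx = float(p_par.get("sx", size * 0.22))
        sy = float(p_par.get("sy", size * 0.3))
        z = np.zeros((size, size))
        dzx = np.zeros_like(z)
        dzy = np.zeros_like(z)
        # blade plus two side lobes
        bumps = [(amp, sx, sy, 0.0, 0.0)]
        for side in (-1.0, 1.0):
            bumps.append(
                (
                    amp * rng.uniform(0.3, 0.5),
                    sx * 0.6,
                    sy * 0.5,
                    side * sx * 0.9,
                    rng.uniform(-0.2, 0.2) * sy,
                )
            )
        if vein_amp > 0:  # raised midrib ridge
            bumps.append((vein_amp, size * 0.03, sy, 0.0, 0.0))
        for b_amp, b_sx, b_sy, x0, y0 in bumps:
            bz, bx, by = _gaussian_bump(x, y, b_amp, b_sx, b_sy, x0, y0)
            z += bz
            dzx += bx
            dzy += by
        mask = z > 0.05 * amp
        p, q = -dzx, -dzy

    else:  # rosette
        rng = np.random.default_rng(spec.seed)
        n_leaves = int(p_par.get("n_leaves", rng.integers(5, 9)))
        leaf_amp = float(p_par.get("leaf_amp", rng.uniform(6.0, 10.0)))
        ripple = float(p_par.get("ripple", rng.uniform(0.2, 0.4)))
        dep_amp = float(p_par.get("dep_amp", rng.uniform(3.0, 6.0)))
        dep_sigma = float(p_par.get("dep_sigma", rng.uniform(4.0, 7.0)))
        rl = float(p_par.get("leaf_scale", size * 0.25))
        phase = rng.uniform(0, 2 * np.pi)
        cy = float(p_par.get("centre_row", (size - 1) / 2 + rng.uniform(-size / 8, size / 8)))
        cx = float(p_par.get("centre_col", (size - 1) / 2 + rng.uniform(-size / 8, size / 8)))
        spec.params["centre"] = (cy, cx)
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        u, v = xx - cx, yy - cy
        r = np.hypot(u, v)
        r_safe = np.maximum(r, 1e-9)
        phi = np.arctan2(v, u)
        # leaves slope up and ripple azimuthally; depression marks the meristem
        g = r * r / (r * r + rl * rl)
        dg = 2 * r * rl * rl / (r * r + rl * rl) ** 2
        ang = 1 + ripple * np.cos(n_leaves * phi + phase)
        dz_dr = leaf_amp * dg * ang
        dz_dphi = -leaf_amp * g * ripple * n_leaves * np.sin(n_leaves * phi + phase)
        dep = dep_amp * np.exp(-(r * r) / (2 * dep_sigma * dep_sigma))
        z = leaf_amp * g * ang - dep
        ddep_dr = -dep * r / (dep_sigma * dep_sigma)
        dz_dr = dz_dr - ddep_dr
        dzx = dz_dr * u / r_safe + dz_dphi * (-v / (r_safe * r_safe))
        dzy = dz_dr * v / r_safe + dz_dphi * (u / (r_safe * r_safe))
        p, q = -dzx, -dzy
        mask = np.ones((size, size), dtype=bool)

    fields = SurfaceFields.from_gradients(p, q, valid_mask=mask)
    depth = DepthMap(z, valid_mask=mask)
    return depth, fields, mask


def render_lambertian(
    fields: SurfaceFields,
    lights: LightSet,
    albedo: float | np.ndarray = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Forward Lambertian render of a gradient field under a light set.

    Returns the image stack and the lit-everywhere truth mask (pixels
    with ``n . l > 0`` under every light — where the no-shadow
    assumption of the inverse solve holds).
    """
    if len(lights) == 0:
        raise ValueError("need at least one light")
    rng = np.random.default_rng(seed)
    lhat = lights.unit_vectors()
    shading = np.einsum("hwk,nk->nhw", fields.normal, lhat)
    alb = np.broadcast_to(np.asarray(albedo, dtype=float), fields.p.shape)
    imgs = alb[None] * np.maximum(shading, 0.0)
    lit = np.all(shading > 0, axis=0)
    if noise_sigma > 0:
        imgs = imgs + rng.normal(0.0, noise_sigma, imgs.shape)
    imgs = np.clip(imgs, 0.0, 1.0)
    stack = ImageStack(list(imgs), pixel_pitch=fields.pixel_pitch)
    return stack, lit


# ---------------------------------------------------------------------------
# Conveyor depth frames


def _footprint_radius(a: float, b: float, yaw: float, direction: np.ndarray) -> float:
    """Support radius of the (a, b) footprint ellipse along a direction."""
    co, si = math.cos(yaw), math.sin(yaw)
    dx = co * direction[0] + si * direction[1]
    dy = -si * direction[0] + co * direction[1]
    return math.hypot(a * dx, b * dy)


def make_conveyor_frame(
    n_tubers: int = 6,
    axis_ranges_mm: tuple[tuple[float, float], ...] = ((25, 55), (18, 45), (14, 30)),
    touching_prob: float = 0.0,
    noise_sigma_mm: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int] = (360, 480),
    camera_mm: float = 800.0,
    pixel_pitch: float = 1.0,
    belt_tilt_deg: float = 0.0,
    quantize_mm: bool = False,
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
    timestamp: float = 0.0,
) -> tuple[DepthFrame, list[TuberRecord]]:
    """Depth frame of upper-half ellipsoid tubers on a belt plane.

    Tubers rest with their smallest axis vertical and a random in-plane
    yaw; with probability ``touching_prob`` a tuber is placed in
    contact with the previous one (their footprints touch), emulating
    tubers in contact on the conveyor.  Truth records carry the exact
    axes, the brute-force sieve size and the band.  ``quantize_mm``
    rounds depths to whole millimetres, emulating the depth resolution
    of structured-light RGB-D sensors.
    """
    if n_tubers < 0:
        raise ValueError("n_tubers must be >= 0")
    for lo, hi in axis_ranges_mm:
        if not (0 < lo <= hi):
            raise ValueError("axis ranges must be positive and ordered")
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    x_mm, y_mm = xx * pixel_pitch, yy * pixel_pitch
    tilt = math.tan(math.radians(belt_tilt_deg))
    belt_depth = camera_mm + tilt * y_mm  # deeper toward larger row if tilted
    heights = np.zeros((h, w))

    placed: list[tuple[float, float, float, float, float, float]] = []
    truth: list[TuberRecord] = []
    margin = 5.0
    for k in range(n_tubers):
        a = rng.uniform(*axis_ranges_mm[0])
        b = rng.uniform(*axis_ranges_mm[1])
        c = rng.uniform(*axis_ranges_mm[2])
        a, b, c = sorted((a, b, c), reverse=True)
        yaw = rng.uniform(0, np.pi)
        ok = False
        for _attempt in range(200):
            touch = placed and rng.uniform() < touching_prob
            if touch:
                ox, oy, oa, ob, oyaw, _ = placed[-1]
                ang = rng.uniform(0, 2 * np.pi)
                d = np.array([math.cos(ang), math.sin(ang)])
                dist = (
                    _footprint_radius(oa, ob, oyaw, d)
                    + _footprint_radius(a, b, yaw, d)
                    - 1.0  # 1 mm overlap guarantees a shared region
                )
                cx, cy = ox + dist * d[0], oy + dist * d[1]
            else:
                cx = rng.uniform(a + margin, w * pixel_pitch - a - margin)
                cy = rng.uniform(a + margin, h * pixel_pitch - a - margin)
            if not (
                a < cx < w * pixel_pitch - a and a < cy < h * pixel_pitch - a
            ):
                continue
            clear = True
            for j, (ox, oy, oa, ob, oyaw, _) in enumerate(placed):
                if touch and j == len(placed) - 1:
                    continue
                if math.hypot(cx - ox, cy - oy) < a + oa + margin:
                    clear = False
                    break
            if clear:
                ok = True
                break
        if not ok:
            raise FieldVisionError(
                f"could not place tuber {k} without excessive overlap"
            )
        placed.append((cx, cy, a, b, c, yaw))
        co, si = math.cos(yaw), math.sin(yaw)
        u = co * (x_mm - cx) + si * (y_mm - cy)
        v = -si * (x_mm - cx) + co * (y_mm - cy)
        wq = 1 - (u / a) ** 2 - (v / b) ** 2
        inside = wq > 0
        zt = np.zeros((h, w))
        zt[inside] = c * np.sqrt(wq[inside])
        heights = np.maximum(heights, zt)
        sieve = sieve_size_bruteforce(2 * b, 2 * c)
        truth.append(
            TuberRecord(
                2 * a,
                2 * b,
                2 * c,
                sieve,
                size_band(sieve, band_edges),
                (cy / pixel_pitch, cx / pixel_pitch),
                timestamp,
            )
        )
        # re-pack placed tuple with c for completeness
        placed[-1] = (cx, cy, a, b, c, yaw)

    depth = belt_depth - heights
    if noise_sigma_mm > 0:
        depth = depth + rng.normal(0.0, noise_sigma_mm, depth.shape)
    if quantize_mm:
        depth = np.round(depth)
    frame = DepthFrame(
        depth,
        roi=(0, 0, h, w),
        timestamp=timestamp,
        pixel_pitch=pixel_pitch,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# Grass / dock texture scenes


def make_grass_dock(
    image_size: int = 512,
    n_docks: int = 3,
    dock_area_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Procedural grass texture with smooth dock-leaf blobs.

    The background sums several randomly oriented high-frequency noise
    fields (multi-directional grass texture: near-uniform local grey
    histogram, high entropy).  Docks are elliptical blobs filled with a
    very smooth random field (few local grey levels, low entropy).  The
    achieved dock coverage lands within 10% of the request.  Returns
    ``(image in [0, 1], truth mask)``.
    """
    if not (0 <= dock_area_fraction <= 0.5):
        raise ValueError("dock_area_fraction must be in [0, 0.5]")
    from scipy.ndimage import gaussian_filter, rotate

    rng = np.random.default_rng(seed)
    n = image_size
    img = np.zeros((n, n))
    for _ in range(4):
        theta = rng.uniform(0, 180)
        streaks = gaussian_filter(rng.normal(size=(n, n)), (0.5, 3.0))
        img += rotate(streaks, theta, reshape=False, order=1, mode="reflect")
    img += 0.6 * rng.normal(size=(n, n))
    img = (img - img.min()) / np.ptp(img)

    truth = np.zeros((n, n), dtype=bool)
    if n_docks > 0 and dock_area_fraction > 0:
        area_per = dock_area_fraction * n * n / n_docks
        r0 = math.sqrt(area_per / math.pi)
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        for _k in range(n_docks):
            for _attempt in range(100):
                cy, cx = rng.uniform(0.15, 0.85, 2) * n
                ry = r0 * rng.uniform(0.8, 1.2)
                rx = area_per / math.pi / ry
                blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1
                if not (blob & truth).any() and blob.any():
                    truth |= blob
                    base = rng.uniform(0.35, 0.65)
                    fill = gaussian_filter(rng.normal(size=(n, n)), 20.0)
                    fill = 0.03 * fill / max(fill.std(), 1e-9)
                    img[blob] = base + fill[blob]
                    break
            else:
                raise FieldVisionError("could not place dock blobs without overlap")
    return np.clip(img, 0.0, 1.0), truth


# ---------------------------------------------------------------------------
# GPS harvest scenes


def make_gps_scene(
    field_size_m: tuple[float, float] = (200.0, 120.0),
    pass_spacing_m: float = 10.0,
    speed_mps: float = 1.5,
    tuber_rate_hz: float = 2.0,
    bands: tuple[float, ...] = DEFAULT_BAND_EDGES,
    band_weights: tuple[float, ...] | None = None,
    origin_latlon: tuple[float, float] = (52.5, -2.0),
    fix_interval_s: float = 1.0,
    seed: int = 0,
) -> tuple[GpsTrack, list[TuberRecord]]:
    """Serpentine harvester track with Poisson-timed tuber records.

    The harvester drives parallel passes ``pass_spacing_m`` apart at
    constant speed; records arrive as a Poisson process at
    ``tuber_rate_hz`` with bands drawn from ``band_weights``.  Record
    dimensions are synthesised to be consistent with the drawn band.
    """
    if min(field_size_m) <= 0 or pass_spacing_m <= 0 or speed_mps <= 0:
        raise ValueError("field size, pass spacing and speed must be positive")
    if tuber_rate_hz < 0:
        raise ValueError("tuber_rate_hz must be >= 0")
    rng = np.random.default_rng(seed)
    length, width_f = field_size_m
    n_passes = max(int(width_f // pass_spacing_m) + 1, 2)
    # waypoints of the serpentine, in metres (x east, y north)
    waypoints = []
    for i in range(n_passes):
        y = i * pass_spacing_m
        xs = (0.0, length) if i % 2 == 0 else (length, 0.0)
        waypoints.append((xs[0], y))
        waypoints.append((xs[1], y))
    # constant-speed time parameterisation
    pts = np.array(waypoints)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t_way = np.concatenate([[0.0], np.cumsum(seg) / speed_mps])
    duration = float(t_way[-1])

    lat0, lon0 = origin_latlon
    m_per_lon = EARTH_M_PER_DEG_LAT * math.cos(math.radians(lat0))

    def pos_at(t: float) -> tuple[float, float]:
        x = np.interp(t, t_way, pts[:, 0])
        y = np.interp(t, t_way, pts[:, 1])
        return lat0 + y / EARTH_M_PER_DEG_LAT, lon0 + x / m_per_lon

    times = np.arange(0.0, duration + fix_interval_s / 2, fix_interval_s)
    fixes = [(float(t), *pos_at(float(t))) for t in times]
    track = GpsTrack(fixes)

    labels = band_labels(bands)
    if band_weights is None:
        band_weights = tuple([1.0] * len(labels))
    wts = np.asarray(band_weights, dtype=float)
    wts = wts / wts.sum()
    # representative sieve sizes per band for synthesising dimensions
    edges = (0.0, *bands, bands[-1] + 20.0)
    records: list[TuberRecord] = []
    t = 0.0
    while tuber_rate_hz > 0:
        t += rng.exponential(1.0 / tuber_rate_hz)
        if t > duration:
            break
        bi = int(rng.choice(len(labels), p=wts))
        sieve_lo, sieve_hi = edges[bi], edges[bi + 1]
        sieve = rng.uniform(sieve_lo + 1, sieve_hi - 1) if sieve_hi - sieve_lo > 2 else sieve_lo + 1
        height = sieve / 1.1
        width = sieve * 1.15
        length_mm = width * rng.uniform(1.1, 1.6)
        records.append(
            TuberRecord(
                length_mm,
                width,
                height,
                sieve,
                labels[bi],
                (0.0, 0.0),
                timestamp=float(t),
            )
        )
    return track, records
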