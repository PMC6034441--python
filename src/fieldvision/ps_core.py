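"""Photometric-stereo surface recovery under the Lambertian model.

A single fixed camera observes a surface ``z = f(x, y)`` under several
directional light sources.  Surface orientation is parameterised in
gradient space, ``p = -df/dx`` and ``q = -df/dy``, so the (unnormalised)
surface normal is ``N = [-p, -q, 1]``.  Each light is parameterised the
same way: a light with gradient-space coordinates ``(ps, qs)`` shines
along ``L = [-ps, -qs, 1]``.  For a Lambertian surface with albedo
``rho`` the recorded radiance is

    R(p, q) = rho * (1 + p*ps + q*qs)
              / (sqrt(1 + p^2 + q^2) * sqrt(1 + ps^2 + qs^2))

which is exactly ``rho * (n_hat . l_hat)``.  With three (or more)
non-coplanar lights the per-pixel radiances determine the scaled normal
``rho * n_hat`` by solving a linear system; its length is the albedo and
its direction the unit normal.

Coordinates follow image convention: rasters are indexed (row, col),
x = col increasing rightward, y = row increasing downward, z toward the
camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.fft import dctn, idctn

from .errors import ConfigurationError

__all__ = [
    "ImageStack",
    "LightSet",
    "SurfaceFields",
    "DepthMap",
    "reflectance_map",
    "shadow_mask",
    "solve_ps_exact",
    "solve_ps_lsq",
    "two_source_gradient",
    "integrate_gradients",
]

#: Default intensity bounds outside which a pixel is treated as shadowed
#: or saturated.
DEFAULT_LOW = 0.02
DEFAULT_HIGH = 0.98


@dataclass
class ImageStack:
    """Co-registered intensity images, one per light source.

    Parameters
    ----------
    images
        Sequence of 2-D float rasters normalised to [0, 1], identical
        shapes.
    pixel_pitch
        Physical size of one pixel in mm, if known (used for metric
        areas; purely optional for orientation recovery).
    """

    images: list[np.ndarray]
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("an image stack needs at least 2 images")
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        shape = self.images[0].shape
        for i, im in enumerate(self.images):
            if im.ndim != 2:
                raise ValueError(f"image {i} is not a 2-D raster")
            if im.shape != shape:
                raise ValueError(
                    f"image {i} has shape {im.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(im)):
                raise ValueError(f"image {i} contains non-finite values")
            if im.min() < 0 or im.max() > 1:
                raise ValueError(f"image {i} intensities outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    def as_array(self) -> np.ndarray:
        """Stack as a (n_lights, H, W) array."""
        return np.stack(self.images, axis=0)


@dataclass
class LightSet:
    """Calibrated illumination directions in gradient-space form.

    Each entry ``(ps, qs)`` induces the direction vector
    ``L = [-ps, -qs, 1]``.
    """

    directions: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.directions = [(float(p), float(q)) for p, q in self.directions]
        for ps, qs in self.directions:
            if not (np.isfinite(ps) and np.isfinite(qs)):
                raise ConfigurationError("non-finite light direction")

    def __len__(self) -> int:
        return len(self.directions)

    def unit_vectors(self) -> np.ndarray:
        """(n, 3) array of unit L vectors."""
        ls = np.array([[-ps, -qs, 1.0] for ps, qs in self.directions])
        return ls / np.linalg.norm(ls, axis=1, keepdims=True)

    def require_rank3(self) -> np.ndarray:
        """Return the unit-vector matrix, failing if it is rank-deficient.

        Lights collinear in azimuth (all in one plane with the view
        axis) leave the normal underdetermined.
        """
        m = self.unit_vectors()
        if len(self.directions) < 3 or np.linalg.matrix_rank(m, tol=1e-10) < 3:
            names = ", ".join(f"({ps:g},{qs:g})" for ps, qs in self.directions)
            raise ConfigurationError(
                "light directions do not span 3-D (collinear in azimuth): "
                + names
            )
        return m


@dataclass
class SurfaceFields:
    """Per-pixel surface orientation and reflectance.

    ``p``/``q`` are the gradient-space slopes, ``normal`` an (H, W, 3)
    raster of unit normals, ``albedo`` the diffuse reflectance and
    ``valid_mask`` flags pixels where the Lambertian solve held (no
    shadow/saturation, sufficient light coverage).
    """

    p: np.ndarray
    q: np.ndarray
    normal: np.ndarray
    albedo: np.ndarray
    valid_mask: np.ndarray
    pixel_pitch: float | None = None

    @classmethod
    def from_gradients(
        cls,
        p: np.ndarray,
        q: np.ndarray,
        albedo: np.ndarray | float = 1.0,
        valid_mask: np.ndarray | None = None,
        pixel_pitch: float | None = None,
    ) -> "SurfaceFields":
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        n = np.stack([-p, -q, np.ones_like(p)], axis=-1)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        alb = np.broadcast_to(np.asarray(albedo, dtype=float), p.shape).copy()
        if valid_mask is None:
            valid_mask = np.ones(p.shape, dtype=bool)
        return cls(p, q, n, alb, np.asarray(valid_mask, dtype=bool), pixel_pitch)


@dataclass
class DepthMap:
    """Height raster ``z = f(x, y)``, defined up to an additive offset
    when produced by gradient integration."""

    z: np.ndarray
    pixel_pitch: float | None = None
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.z.shape, dtype=bool)


def reflectance_map(p, q, ps: float, qs: float, albedo):
    """Lambertian reflectance for gradients (p, q) under light (ps, qs).

    Accepts scalars or broadcastable arrays.  Radiance is clamped at
    zero where the surface faces away from the light (attached shadow).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    albedo = np.asarray(albedo, dtype=float)
    for name, v in (("p", p), ("q", q), ("ps", ps), ("qs", qs), ("albedo", albedo)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value in {name}")
    if np.any(albedo < 0):
        raise ValueError("albedo must be non-negative")
    num = albedo * (1.0 + p * ps + q * qs)
    den = np.sqrt(1.0 + p * p + q * q) * np.sqrt(1.0 + ps * ps + qs * qs)
    r = np.maximum(num, 0.0) / den
    if r.ndim == 0:
        return float(r)
    return r


def shadow_mask(
    stack: ImageStack, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> np.ndarray:
    """Pixels usable in every image: intensity strictly inside (low, high).

    Enforces the no-shadow assumption of the Lambertian solve and
    excludes saturated pixels.
    """
    if not (0 <= low < high <= 1):
        raise ValueError("need 0 <= low < high <= 1")
    arr = stack.as_array()
    return np.all((arr > low) & (arr < high), axis=0)


def _scaled_normal_fields(
    g: np.ndarray, valid: np.ndarray, pixel_pitch: float | None
) -> SurfaceFields:
    """Build SurfaceFields from a (H, W, 3) scaled-normal raster."""
    albedo = np.linalg.norm(g, axis=-1)
    ok = valid & (albedo > 1e-12) & (g[..., 2] > 0)
    normal = np.zeros_like(g)
    normal[..., 2] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nz = albedo > 1e-12
        normal[nz] = g[nz] / albedo[nz, None]
    p = np.zeros(albedo.shape)
    q = np.zeros(albedo.shape)
    safe = ok & (np.abs(normal[..., 2]) > 1e-12)
    p[safe] = -normal[..., 0][safe] / normal[..., 2][safe]
    q[safe] = -normal[..., 1][safe] / normal[..., 2][safe]
    albedo = np.where(ok, albedo, 0.0)
    return SurfaceFields(p, q, normal, albedo, ok, pixel_pitch)


def solve_ps_exact(
    stack: ImageStack,
    lights: LightSet,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> SurfaceFields:
    """Exact three-light photometric-stereo solve.

    Per pixel, solves ``I = M (rho n_hat)`` where the rows of ``M`` are
    the unit light vectors.  Three non-coplanar lights determine the
    scaled normal uniquely; its length is the albedo.  Pixels failing
    the shadow/saturation test are flagged invalid.
    """
    if len(stack.images) != 3 or len(lights) != 3:
        raise ConfigurationError("exact solve needs exactly 3 images and 3 lights")
    m = lights.require_rank3()
    minv = np.linalg.inv(m)
    arr = stack.as_array()  # (3, H, W)
    g = np.einsum("ij,jhw->hwi", minv, arr)
    valid = shadow_mask(stack, low, high)
    return _scaled_normal_fields(g, valid, stack.pixel_pitch)


def solve_ps_lsq(
    stack: ImageStack,
    lights: LightSet,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> SurfaceFields:
    """Least-squares photometric stereo with >= 3 lights.

    Per pixel, the scaled normal is fitted by linear least squares over
    the subset of images whose intensity passes the shadow/saturation
    test; pixels with fewer than 3 usable intensities are marked
    invalid rather than raising.  With exactly 3 usable images this
    reduces to the exact solve.
    """
    n = len(stack.images)
    if len(lights) != n:
        raise ConfigurationError("light count must match image count")
    m = lights.require_rank3()
    arr = stack.as_array()  # (n, H, W)
    h, w = stack.shape
    usable = (arr > low) & (arr < high)  # (n, H, W)
    # encode per-pixel usable-light pattern as a bitmask and solve each
    # pattern with one pseudo-inverse (n is small, so few patterns)
    codes = np.zeros((h, w), dtype=np.int64)
    for i in range(n):
        codes |= usable[i].astype(np.int64) << i
    g = np.zeros((h, w, 3))
    valid = np.zeros((h, w), dtype=bool)
    flat = arr.reshape(n, -1)
    for code in np.unique(codes):
        rows = [i for i in range(n) if (code >> i) & 1]
        if len(rows) < 3:
            continue
        sub = m[rows]
        if np.linalg.matrix_rank(sub, tol=1e-10) < 3:
            continue
        pix = (codes == code).ravel()
        pinv = np.linalg.pinv(sub)
        g.reshape(-1, 3)[pix] = (pinv @ flat[np.ix_(rows, np.flatnonzero(pix))]).T
        valid.ravel()[pix] = True
    return _scaled_normal_fields(g, valid, stack.pixel_pitch)


def two_source_gradient(
    i1: np.ndarray,
    i2: np.ndarray,
    lights: LightSet,
    sum_floor: float = 2 * DEFAULT_LOW,
) -> tuple[np.ndarray, np.ndarray]:
    """One-axis gradient recovery from two opposed x-axis lights.

    For a moving platform only two exposures are practical.  With both
    lights in the camera's x-z plane at symmetric slopes ``(+-ps, 0)``
    the Lambertian ratio

        (I1 - I2) / (I1 + I2) = p * ps

    cancels the albedo and the y-slope ``q``, giving the x-gradient
    directly: ``p = ratio / ps``.

    Returns ``(p, valid_mask)``; pixels where ``i1 + i2`` falls below
    ``sum_floor`` are invalid.
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if i1.shape != i2.shape:
        raise ValueError("the two images must share a shape")
    if len(lights) != 2:
        raise ConfigurationError("two-source recovery needs exactly 2 lights")
    (ps1, qs1), (ps2, qs2) = lights.directions
    if abs(qs1) > 1e-9 or abs(qs2) > 1e-9:
        raise ConfigurationError(
            "two-source lights must lie in the camera x-axis plane (qs = 0)"
        )
    if abs(ps1 + ps2) > 1e-9 or abs(ps1) < 1e-9:
        raise ConfigurationError(
            "two-source lights must have opposite, non-zero ps"
        )
    total = i1 + i2
    valid = total > sum_floor
    p = np.zeros(i1.shape)
    p[valid] = (i1[valid] - i2[valid]) / total[valid] / ps1
    return p, valid


# ---------------------------------------------------------------------------
# Gradient-field integration


def _integrate_dct(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Global least-squares integration via a DCT Poisson solve.

    Solves ``laplace(z) = div(grad z)`` with natural (Neumann)
    boundaries; this is the spectral least-squares fit of an integrable
    surface to a possibly non-integrable gradient field.
    """
    gx, gy = -p, -q  # convention p = -dz/dx
    h, w = p.shape
    # exact normal-equation RHS for the forward-difference least squares:
    # per-edge targets are midpoint gradients; boundary terms carry the
    # Neumann flux, so constant-gradient fields integrate to planes
    gmx = (gx[:, 1:] + gx[:, :-1]) / 2  # (h, w-1) edge targets
    gmy = (gy[1:, :] + gy[:-1, :]) / 2
    fx = np.zeros_like(gx)
    fx[:, :-1] += gmx
    fx[:, 1:] -= gmx
    fy = np.zeros_like(gy)
    fy[:-1, :] += gmy
    fy[1:, :] -= gmy
    f = fx + fy
    coef = dctn(f, norm="ortho")
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    denom = (2 * np.cos(np.pi * xx / w) - 2) + (2 * np.cos(np.pi * yy / h) - 2)
    denom[0, 0] = 1.0
    zc = coef / denom
    zc[0, 0] = 0.0
    return idctn(zc, norm="ortho")


def _integrate_masked(p: np.ndarray, q: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Sparse least-squares integration restricted to a pixel mask.

    Each pair of mask-adjacent pixels contributes one finite-difference
    equation; the solution is the depth field (up to offset) minimising
    the squared mismatch to the given gradients.
    """
    h, w = p.shape
    idx = -np.ones((h, w), dtype=np.int64)
    ids = np.flatnonzero(mask.ravel())
    idx.ravel()[ids] = np.arange(len(ids))
    gx, gy = -p, -q
    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    for di, dj, g in ((0, 1, gx), (1, 0, gy)):
        both = mask[: h - di, : w - dj] & mask[di:, dj:]
        ii, jj = np.nonzero(both)
        n = len(ii)
        rows.extend([np.arange(eq, eq + n)] * 2)
        cols.extend([idx[ii + di, jj + dj], idx[ii, jj]])
        vals.extend([np.ones(n), -np.ones(n)])
        rhs.append((g[ii, jj] + g[ii + di, jj + dj]) / 2)
        eq += n
    a = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(eq, len(ids)),
    )
    b = np.concatenate(rhs)
    # normal equations with a tiny Tikhonov term to pin the free offset
    ata = (a.T @ a + 1e-9 * sp.identity(len(ids))).tocsc()
    z_vals = sp.linalg.spsolve(ata, a.T @ b)
    z = np.zeros((h, w))
    z.ravel()[ids] = z_vals
    return z


def integrate_gradients(fields: SurfaceFields) -> DepthMap:
    """Recover a depth map from a gradient field by least squares.

    Uses a spectral (DCT) Poisson solve when every pixel is valid and a
    masked sparse least-squares solve otherwise.  The additive offset is
    fixed by mean-centring over the valid mask.  Gradient noise makes
    the field slightly non-integrable; the least-squares formulation
    absorbs that rather than accumulating it along integration paths.
    """
    mask = fields.valid_mask
    if not mask.any():
        raise ValueError("cannot integrate an all-invalid gradient field")
    p = np.where(mask, fields.p, 0.0)
    q = np.where(mask, fields.q, 0.0)
    if not np.all(np.isfinite(p[mask])) or not np.all(np.isfinite(q[mask])):
        raise ValueError("non-finite gradients on the valid mask")
    if mask.all():
        z = _integrate_dct(p, q)
        z -= z.mean()
    else:
        z = _integrate_masked(p, q, mask)
        z[~mask] = np.nan
        z[mask] -= z[mask].mean()
    return DepthMap(z, fields.pixel_pitch, mask.copy())


def color_albedo(
    stacks_rgb: Sequence[ImageStack], lights: LightSet
) -> tuple[SurfaceFields, np.ndarray]:
    """Per-channel albedo for a colour capture.

    Orientation is solved once on the luminance stack; each colour
    channel's albedo is then the mean ratio of its intensities to the
    predicted Lambert shading.  Returns the luminance-solved fields and
    an (H, W, 3) albedo raster.
    """
    if len(stacks_rgb) != 3:
        raise ValueError("expected one ImageStack per colour channel (R, G, B)")
    lum = ImageStack(
        [
            0.2126 * r + 0.7152 * g + 0.0722 * b
            for r, g, b in zip(
                stacks_rgb[0].images, stacks_rgb[1].images, stacks_rgb[2].images
            )
        ],
        pixel_pitch=stacks_rgb[0].pixel_pitch,
    )
    fields = solve_ps_lsq(lum, lights)
    lhat = lights.unit_vectors()
    shading = np.einsum("hwk,nk->nhw", fields.normal, lhat)
    shading = np.maximum(shading, 1e-6)
    albedo = np.zeros(fields.albedo.shape + (3,))
    for c, stack in enumerate(stacks_rgb):
        ratios = stack.as_array() / shading
        albedo[..., c] = np.where(fields.valid_mask, ratios.mean(axis=0), 0.0)
    return fields, albedo
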