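"""Shared I/O, run configuration and manifests.

Rasters travel as PNG (8/16-bit integer, normalised to [0, 1] on read)
or TIFF (including float32, read verbatim).  Run configuration is one
declarative YAML file per run, schema-checked with all violations
reported at once; every CLI run writes a manifest (inputs, config
hash, package version, seed) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .errors import ConfigurationError, ImageFormatError
from .ps_core import ImageStack, LightSet

__all__ = [
    "read_image",
    "write_image",
    "read_depth",
    "write_depth",
    "RunConfig",
    "validate_config",
    "load_ps_config",
    "write_manifest",
]

log = logging.getLogger("fieldvision")


def read_image(path: str | Path) -> np.ndarray:
    """Read a raster, normalising integer images to [0, 1] floats.

    Float TIFFs are returned verbatim (depth maps carry physical
    units).  Unsupported files raise :class:`ImageFormatError` naming
    the offender.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float32 if arr.dtype.itemsize <= 4 else float)
    raise ImageFormatError(f"{path}: unsupported bit depth {arr.dtype}")


def write_image(path: str | Path, raster: np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0, 1] raster as PNG (8/16-bit) or a float raster as TIFF."""
    path = Path(path)
    raster = np.asarray(raster)
    if path.suffix.lower() in (".tif", ".tiff"):
        photometric = "rgb" if raster.ndim == 3 and raster.shape[-1] == 3 else "minisblack"
        tifffile.imwrite(path, raster.astype(np.float32), photometric=photometric)
        return
    if bit_depth == 8:
        data = np.clip(np.round(raster * 255), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.clip(np.round(raster * 65535), 0, 65535).astype(np.uint16)
    else:
        raise ImageFormatError(f"unsupported PNG bit depth {bit_depth}")
    Image.fromarray(data).save(path)


def read_depth(path: str | Path) -> np.ndarray:
    """Read a depth raster in mm (float TIFF or .npy).

    Integer input (1 mm-quantised sensors) is promoted to float with a
    logged warning.
    """
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise ImageFormatError(f"cannot read depth {path}: {exc}") from exc
    if np.issubdtype(arr.dtype, np.integer):
        log.warning("%s: integer depth promoted to float (assumed mm)", path)
        arr = arr.astype(float)
    return np.asarray(arr, dtype=float)


def write_depth(path: str | Path, depth_mm: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(depth_mm, dtype=np.float32))
    else:
        tifffile.imwrite(path, np.asarray(depth_mm, dtype=np.float32))


# ---------------------------------------------------------------------------
# Run configuration


_PS_KEYS = {"images", "lights", "pixel_pitch", "method", "low", "high"}


@dataclass
class RunConfig:
    """Validated run configuration with resolved defaults."""

    pipeline: str
    raw: dict
    defaulted: list[str] = field(default_factory=list)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(path: str | Path, pipeline: str = "ps") -> RunConfig:
    """Load and schema-check a YAML run configuration.

    All violations are collected and reported in one error.  Currently
    the photometric-stereo section is fully validated; other pipelines
    accept free-form parameter overrides under their own section.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    defaulted: list[str] = []
    if pipeline == "ps":
        unknown = set(raw) - _PS_KEYS
        if unknown:
            problems.append(f"unknown keys: {sorted(unknown)}")
        images = raw.get("images")
        lights = raw.get("lights")
        if not images or not isinstance(images, list):
            problems.append("missing or empty 'images' list")
        if not lights or not isinstance(lights, list):
            problems.append("missing or empty 'lights' list")
        if images and lights:
            if len(images) != len(lights):
                problems.append(
                    f"{len(images)} images but {len(lights)} lights"
                )
            for i, img in enumerate(images):
                if not (path.parent / img).exists():
                    problems.append(f"image file not found: {img}")
            try:
                ls = LightSet([tuple(l) for l in lights])
                method = raw.get("method", "lsq")
                if method in ("exact", "lsq"):
                    ls.require_rank3()
            except (ConfigurationError, TypeError) as exc:
                problems.append(str(exc))
        for key, default in (("method", "lsq"), ("low", 0.02), ("high", 0.98)):
            if key not in raw:
                raw[key] = default
                defaulted.append(key)
        if raw.get("method") not in ("exact", "lsq", "two-source"):
            problems.append(f"unknown method {raw.get('method')!r}")
    if problems:
        raise ConfigurationError(
            f"{path}: " + "; ".join(problems)
        )
    for key in defaulted:
        log.info("config %s: defaulted %s=%r", path, key, raw[key])
    return RunConfig(pipeline, raw, defaulted)


def load_ps_config(path: str | Path) -> tuple[ImageStack, LightSet, RunConfig]:
    """Read a PS stack manifest: image paths plus (ps, qs) per light."""
    cfg = validate_config(path, "ps")
    base = Path(path).parent
    images = [read_image(base / p) for p in cfg.raw["images"]]
    images = [
        im if im.ndim == 2 else im[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
        for im in images
    ]
    stack = ImageStack(images, pixel_pitch=cfg.raw.get("pixel_pitch"))
    lights = LightSet([tuple(l) for l in cfg.raw["lights"]])
    return stack, lights, cfg


def write_manifest(
    out_dir: str | Path,
    pipeline: str,
    inputs: list[str],
    config: RunConfig | None = None,
    seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a reproducibility manifest next to the run outputs."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("fieldvision")
    except PackageNotFoundError:
        ver = "unknown"
    manifest = {
        "pipeline": pipeline,
        "inputs": sorted(str(i) for i in inputs),
        "config_hash": config.hash() if config else None,
        "defaulted_keys": config.defaulted if config else [],
        "fieldvision_version": ver,
        "numpy_version": np.__version__,
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
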