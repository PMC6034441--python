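"""Geo-tagging tuber records and rendering per-band yield heat maps.

Each measured tuber carries a timestamp; a GPS track recorded on the
harvester gives its position by linear interpolation between the
bracketing fixes.  Tagged records are binned on a local metre grid
(equirectangular projection about the track centroid — fields are well
under a kilometre, so the distortion is negligible) into per-size-band
counts, rendered as blue -> green -> red heat maps plus a GeoJSON grid.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FieldVisionError
from .potato_metrology import DEFAULT_BAND_EDGES, TuberRecord, band_labels

__all__ = [
    "GpsTrack",
    "TaggedRecord",
    "GeoGrid",
    "parse_gps_log",
    "tag_records",
    "grid_bin",
    "render_heatmaps",
    "EARTH_M_PER_DEG_LAT",
]

#: Metres per degree of latitude (spherical approximation).
EARTH_M_PER_DEG_LAT = 111_320.0

#: Records more than this far outside the track's time span are dropped.
TIME_TOLERANCE_S = 5.0


@dataclass
class GpsTrack:
    """Time-ordered GPS fixes: (timestamp s, latitude deg, longitude deg)."""

    fixes: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if len(self.fixes) < 2:
            raise FieldVisionError("a GPS track needs at least 2 fixes")
        ts = [f[0] for f in self.fixes]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise FieldVisionError("GPS timestamps must be strictly increasing")
        for t, lat, lon in self.fixes:
            if not (abs(lat) <= 90 and abs(lon) <= 180):
                raise FieldVisionError(f"fix at t={t} outside lat/lon bounds")

    @property
    def t_start(self) -> float:
        return self.fixes[0][0]

    @property
    def t_end(self) -> float:
        return self.fixes[-1][0]

    def interpolate(self, t: float) -> tuple[float, float]:
        """(lat, lon) at time t, clamped to the track's endpoints."""
        ts = np.array([f[0] for f in self.fixes])
        lats = np.array([f[1] for f in self.fixes])
        lons = np.array([f[2] for f in self.fixes])
        return float(np.interp(t, ts, lats)), float(np.interp(t, ts, lons))


@dataclass
class TaggedRecord:
    record: TuberRecord
    lat: float
    lon: float


@dataclass
class GeoGrid:
    """Per-band tuber counts on a local metre grid."""

    origin: tuple[float, float]  # (lat, lon) of the projection centre
    cell_size_m: float
    counts: np.ndarray  # (n_bands, n_rows, n_cols), ints
    bands: list[str]
    west_m: float  # grid west edge, metres east of origin
    south_m: float  # grid south edge, metres north of origin

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell_polygon(self, row: int, col: int) -> list[tuple[float, float]]:
        """Corner (lon, lat) ring of a cell, closed."""
        lat0, lon0 = self.origin
        m_per_lon = EARTH_M_PER_DEG_LAT * math.cos(math.radians(lat0))
        xs = self.west_m + np.array([0, 1, 1, 0, 0]) * self.cell_size_m + col * self.cell_size_m
        ys = self.south_m + np.array([0, 0, 1, 1, 0]) * self.cell_size_m + row * self.cell_size_m
        return [
            (lon0 + x / m_per_lon, lat0 + y / EARTH_M_PER_DEG_LAT)
            for x, y in zip(xs, ys)
        ]


def parse_gps_log(path: str | Path) -> GpsTrack:
    """Read a timestamp,lat,lon CSV into a validated track.

    Rows are sorted by time; duplicate timestamps collapse to the last
    fix.  A malformed or out-of-bounds row raises with its line number.
    """
    fixes: dict[float, tuple[float, float, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"timestamp", "lat", "lon"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FieldVisionError(
                f"{path}: header must contain columns timestamp,lat,lon"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                t = float(row["timestamp"])
                lat = float(row["lat"])
                lon = float(row["lon"])
            except (TypeError, ValueError) as exc:
                raise FieldVisionError(f"{path}:{lineno}: unparseable row") from exc
            if not (abs(lat) <= 90 and abs(lon) <= 180):
                raise FieldVisionError(
                    f"{path}:{lineno}: lat/lon out of bounds ({lat}, {lon})"
                )
            fixes[t] = (t, lat, lon)
    if len(fixes) < 2:
        raise FieldVisionError(f"{path}: fewer than 2 usable fixes")
    return GpsTrack([fixes[t] for t in sorted(fixes)])


def tag_records(
    records: list[TuberRecord], track: GpsTrack
) -> tuple[list[TaggedRecord], int]:
    """Attach interpolated (lat, lon) to each record.

    Records timestamped outside ``[t_start - 5 s, t_end + 5 s]`` are
    dropped; the second return value counts them.
    """
    if not track.fixes:
        raise FieldVisionError("empty GPS track")
    tagged: list[TaggedRecord] = []
    dropped = 0
    for rec in records:
        if (
            rec.timestamp < track.t_start - TIME_TOLERANCE_S
            or rec.timestamp > track.t_end + TIME_TOLERANCE_S
        ):
            dropped += 1
            continue
        lat, lon = track.interpolate(rec.timestamp)
        tagged.append(TaggedRecord(rec, lat, lon))
    return tagged, dropped


def grid_bin(
    tagged: list[TaggedRecord],
    bands: tuple[float, ...] = DEFAULT_BAND_EDGES,
    cell_size_m: float = 5.0,
) -> GeoGrid:
    """Bin tagged records into per-band counts on a metre grid.

    The grid covers the bounding box of the tagged records padded by
    one cell; the projection origin is the records' centroid.
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    if not tagged:
        raise FieldVisionError("no tagged records to bin")
    labels = band_labels(bands)
    lat0 = float(np.mean([t.lat for t in tagged]))
    lon0 = float(np.mean([t.lon for t in tagged]))
    m_per_lon = EARTH_M_PER_DEG_LAT * math.cos(math.radians(lat0))
    xs = np.array([(t.lon - lon0) * m_per_lon for t in tagged])
    ys = np.array([(t.lat - lat0) * EARTH_M_PER_DEG_LAT for t in tagged])
    west = math.floor(xs.min() / cell_size_m - 1) * cell_size_m
    south = math.floor(ys.min() / cell_size_m - 1) * cell_size_m
    n_cols = int(math.floor((xs.max() - west) / cell_size_m)) + 2
    n_rows = int(math.floor((ys.max() - south) / cell_size_m)) + 2
    counts = np.zeros((len(labels), n_rows, n_cols), dtype=np.int64)
    band_index = {lab: i for i, lab in enumerate(labels)}
    for t, x, y in zip(tagged, xs, ys):
        bi = band_index.get(t.record.band)
        if bi is None:
            raise FieldVisionError(
                f"record band {t.record.band!r} not in configured bands"
            )
        col = int((x - west) // cell_size_m)
        row = int((y - south) // cell_size_m)
        counts[bi, row, col] += 1
    return GeoGrid((lat0, lon0), cell_size_m, counts, labels, west, south)


def _ramp_rgba(frac: np.ndarray) -> np.ndarray:
    """Blue -> green -> red colour ramp over [0, 1], returned as RGBA."""
    frac = np.clip(frac, 0.0, 1.0)
    r = np.clip(2 * frac - 1, 0, 1)
    b = np.clip(1 - 2 * frac, 0, 1)
    g = 1 - r - b
    a = np.ones_like(frac)
    return np.stack([r, g, b, a], axis=-1)


def render_heatmaps(
    grid: GeoGrid, out_dir: str | Path, scale_per_band: bool = True
) -> dict[str, Path]:
    """Write one PNG heat map per band plus a GeoJSON cell grid.

    Cell colour runs blue (low count) through green to red (high
    count); zero-count cells are transparent.  Each band is scaled to
    its own maximum by default (``scale_per_band=False`` shares one
    scale).  Returns the written paths keyed by band label (plus
    "geojson").
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    global_max = max(int(grid.counts.max()), 1)
    for bi, band in enumerate(grid.bands):
        layer = grid.counts[bi]
        top = max(int(layer.max()), 1) if scale_per_band else global_max
        rgba = _ramp_rgba(layer / top)
        rgba[layer == 0] = 0.0  # transparent empty cells
        img = (rgba[::-1] * 255).astype(np.uint8)  # north up
        safe = band.replace("<", "lt").replace("+", "plus").replace("-", "_")
        path = out_dir / f"heatmap_{safe}.png"
        iio.imwrite(path, img)
        written[band] = path
    features = []
    n_rows, n_cols = grid.counts.shape[1:]
    for row in range(n_rows):
        for col in range(n_cols):
            cell_counts = {
                band: int(grid.counts[bi, row, col])
                for bi, band in enumerate(grid.bands)
            }
            if sum(cell_counts.values()) == 0:
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [grid.cell_polygon(row, col)],
                    },
                    "properties": {"row": row, "col": col, **cell_counts},
                }
            )
    geojson = {"type": "FeatureCollection", "features": features}
    gj_path = out_dir / "grid.geojson"
    gj_path.write_text(json.dumps(geojson, indent=1))
    written["geojson"] = gj_path
    return written
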