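"""Gridded-layer and vector I/O, richness rasterization, and RGB rendering.

All rasters in this package live on a single geographic (lat/lon) grid
described by a :class:`GridSpec`: north-up, square cells, no projected CRS.
Rasters are exchanged as ESRI ASCII grids (plain text, widely readable by
GIS software); species ranges as GeoJSON FeatureCollections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

log = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "RangeSet",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_ranges",
    "write_ranges",
    "rasterize_richness",
    "render_rgb",
]


@dataclass(frozen=True)
class GridSpec:
    """Geographic analysis grid: north-up, square cells in degrees.

    ``origin`` is the (lon, lat) of the *lower-left corner* of the grid
    (ESRI ASCII convention); row 0 of any array on this grid is the
    *northernmost* row.
    """

    rows: int
    cols: int
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 0.05
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid must have positive rows and cols")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def row_latitudes(self) -> np.ndarray:
        """Latitude of each row centre, row 0 northernmost."""
        lat0 = self.origin[1]
        top = lat0 + self.rows * self.cell_size
        return top - (np.arange(self.rows) + 0.5) * self.cell_size

    def latitude_raster(self) -> np.ndarray:
        return np.repeat(self.row_latitudes()[:, None], self.cols, axis=1)

    def cell_areas(self, spherical: bool = True) -> np.ndarray:
        """Per-pixel area weights (relative units).

        With ``spherical`` the equal-angle cells are cos-latitude weighted,
        which is how areas shrink poleward on a geographic grid; otherwise
        every cell weighs 1.
        """
        if not spherical:
            return np.ones(self.shape)
        w = np.cos(np.deg2rad(self.row_latitudes()))
        return np.repeat(w[:, None], self.cols, axis=1)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of one cell rectangle in degrees."""
        lon0, lat0 = self.origin
        top = lat0 + self.rows * self.cell_size
        minx = lon0 + col * self.cell_size
        maxy = top - row * self.cell_size
        return (minx, maxy - self.cell_size, minx + self.cell_size, maxy)

    def validate(self, array: np.ndarray, name: str = "raster") -> None:
        if array.shape[-2:] != self.shape:
            raise ValueError(
                f"{name} shape {array.shape} does not match grid {self.shape}"
            )


@dataclass
class RangeSet:
    """Species range polygons with species/taxon identity.

    Polygon coordinates are in the same lon/lat degrees as the GridSpec.
    """

    polygons: list  # shapely geometries
    species_ids: list[str]
    taxa: list[str]

    def __post_init__(self) -> None:
        n = len(self.polygons)
        if len(self.species_ids) != n or len(self.taxa) != n:
            raise ValueError("polygons, species_ids and taxa must align")
        seen = set()
        for sid, taxon in zip(self.species_ids, self.taxa):
            key = (taxon, sid)
            if key in seen:
                raise ValueError(f"duplicate species id {sid!r} for taxon {taxon!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.polygons)


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)

def write_ascii_grid(path: str | Path, array: np.ndarray, grid: GridSpec) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes the nodata value."""
    grid.validate(array)
    data = np.asarray(array, dtype=float).copy()
    data[~np.isfinite(data)] = grid.nodata
    header = (
        f"ncols {grid.cols}\n"
        f"nrows {grid.rows}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in data)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    lines = Path(path).read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    }:
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    grid = GridSpec(
        rows=int(hdr["nrows"]),
        cols=int(hdr["ncols"]),
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        cell_size=hdr["cellsize"],
        nodata=hdr.get("nodata_value", -9999.0),
    )
    data = np.loadtxt(lines[i:], dtype=float).reshape(grid.shape)
    data[data == grid.nodata] = np.nan
    return data, grid


# ---------------------------------------------------------------------------
# vector I/O (GeoJSON)

def write_ranges(path: str | Path, ranges: RangeSet) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"species_id": sid, "taxon": taxon},
            "geometry": mapping(poly),
        }
        for poly, sid, taxon in zip(ranges.polygons, ranges.species_ids, ranges.taxa)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_ranges(path: str | Path) -> RangeSet:
    fc = json.loads(Path(path).read_text())
    polys, sids, taxa = [], [], []
    for feat in fc["features"]:
        polys.append(shape(feat["geometry"]))
        sids.append(feat["properties"]["species_id"])
        taxa.append(feat["properties"].get("taxon", "all"))
    return RangeSet(polys, sids, taxa)


# ---------------------------------------------------------------------------
# richness rasterization

def rasterize_richness(
    ranges: RangeSet, grid: GridSpec
) -> dict[str, np.ndarray]:
    """Count, per cell and per taxon, the species whose range touches the cell.

    A species is present in a cell iff its polygon intersects the cell
    rectangle at all (the any-part rule — a polygon clipping one corner of a
    cell still counts), tested with exact geometric predicates rather than a
    centre-point or all-touched approximation. Invalid polygons are repaired
    with ``make_valid``; a polygon that cannot be repaired is skipped and
    logged. Returns ``{taxon: raster, ..., "overall": raster}``; an empty
    RangeSet yields a single all-zero "overall" raster.
    """
    lon0, lat0 = grid.origin
    top = lat0 + grid.rows * grid.cell_size
    cs = grid.cell_size
    taxa = sorted(set(ranges.taxa)) or []
    out = {t: np.zeros(grid.shape, dtype=np.int32) for t in taxa}
    for poly, sid, taxon in zip(ranges.polygons, ranges.species_ids, ranges.taxa):
        if not poly.is_valid:
            poly = make_valid(poly)
            if poly.is_empty or not poly.is_valid:
                log.warning("range polygon %s could not be repaired; skipped", sid)
                continue
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor((minx - lon0) / cs)))
        c1 = min(grid.cols - 1, int(np.floor((maxx - lon0) / cs)))
        r0 = max(0, int(np.floor((top - maxy) / cs)))
        r1 = min(grid.rows - 1, int(np.floor((top - miny) / cs)))
        if c1 < c0 or r1 < r0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                             indexing="ij")
        xmin = lon0 + cc * cs
        ymax = top - rr * cs
        boxes = shapely.box(xmin, ymax - cs, xmin + cs, ymax)
        hit = shapely.intersects(boxes, poly)
        out[taxon][r0:r1 + 1, c0:c1 + 1] += hit.astype(np.int32)
    overall = (
        np.sum([v for v in out.values()], axis=0).astype(np.int32)
        if out else np.zeros(grid.shape, dtype=np.int32)
    )
    out["overall"] = overall
    return out


# ---------------------------------------------------------------------------
# rendering

def render_rgb(dhi, low: float = 2.0, high: float = 98.0) -> np.ndarray:
    """Render DHI layers as an RGB byte image.

    Channel assignment follows the standard DHI colour composite: red is
    variation, green is minimum, blue is cumulative. Each band is stretched
    linearly between its ``low`` and ``high`` percentiles (computed over
    valid pixels) to 0–255; masked pixels are black. A constant band (a
    degenerate stretch) maps to mid-grey 128.
    """
    mask = dhi.valid_mask
    img = np.zeros((*mask.shape, 3), dtype=np.uint8)
    if not mask.any():
        return img
    order = [dhi.variation, dhi.minimum, dhi.cumulative]  # R, G, B
    for ch, band in enumerate(order):
        vals = band[mask]
        lo, hi = np.percentile(vals, [low, high])
        if hi <= lo:
            img[..., ch][mask] = 128
            continue
        stretched = np.clip((band[mask] - lo) / (hi - lo), 0.0, 1.0)
        img[..., ch][mask] = np.round(stretched * 255).astype(np.uint8)
    return img
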