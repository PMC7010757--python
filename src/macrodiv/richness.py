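"""Species richness per grid cell from occurrence points.

Each species' range is the convex hull of its occurrences, built separately
in up to four world quadrants (hemisphere x ocean-basin half) so that, e.g.,
antitropical species do not get a spurious cross-equator bridge.  Ranges are
rasterized onto the equal-area grid by polygon-cell intersection in the
projected plane; a cell counts a species at most once.  Marine ranges can be
clipped by depth: cells whose maximum depth falls outside the species' known
depth range are removed.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, box
from shapely.prepared import prep

from . import grid as gridmod
from .grid import GridSpec

#: Default longitudinal split meridians: 20E / 160W approximates an
#: Atlantic vs Indo-Pacific divide.
DEFAULT_SPLIT_MERIDIANS = (20.0, -160.0)

OCCURRENCE_COLUMNS = ["species", "lat", "lon", "depth_min", "depth_max", "habitat"]


@dataclasses.dataclass
class SpeciesRange:
    """Up to four convex polygons (projected plane) plus depth limits."""

    species: str
    polygons: list  # shapely geometries in projected metres (may be Point/LineString)
    depth_min: float | None = None
    depth_max: float | None = None


def _basin_half(lon: np.ndarray, meridians: tuple[float, float]) -> np.ndarray:
    """True for the half east of meridians[0] and west of meridians[1]."""
    m_east, m_west = meridians
    lon = np.mod(np.asarray(lon, dtype=float) + 180.0, 360.0) - 180.0
    if m_east <= m_west:
        return (lon >= m_east) & (lon < m_west)
    return (lon >= m_east) | (lon < m_west)


def build_range(
    occurrences: pd.DataFrame,
    split_meridians: tuple[float, float] = DEFAULT_SPLIT_MERIDIANS,
) -> SpeciesRange:
    """Convex-hull range of one species, split into four world quadrants.

    ``occurrences`` holds one species' points (columns ``species, lat, lon``
    and optionally ``depth_min, depth_max``).  Quadrants are the cross of
    hemisphere (lat >= 0) and basin half; each non-empty quadrant yields the
    convex hull of its points (degenerate 1-2 point quadrants yield
    point/segment geometries).
    """
    if occurrences.empty:
        raise ValueError("no occurrences")
    species = str(occurrences["species"].iloc[0])
    lon = occurrences["lon"].to_numpy(dtype=float)
    lat = occurrences["lat"].to_numpy(dtype=float)
    north = lat >= 0.0
    half = _basin_half(lon, split_meridians)
    polys = []
    for hemi in (True, False):
        for basin in (True, False):
            mask = (north == hemi) & (half == basin)
            if not mask.any():
                continue
            x, y = gridmod.project(lon[mask], lat[mask])
            pts = MultiPoint(list(zip(np.atleast_1d(x), np.atleast_1d(y))))
            polys.append(pts.convex_hull)
    dmin = dmax = None
    if "depth_min" in occurrences.columns:
        vals = occurrences["depth_min"].dropna()
        dmin = float(vals.min()) if len(vals) else None
    if "depth_max" in occurrences.columns:
        vals = occurrences["depth_max"].dropna()
        dmax = float(vals.max()) if len(vals) else None
    return SpeciesRange(species=species, polygons=polys, depth_min=dmin, depth_max=dmax)


def range_cells(sp_range: SpeciesRange, spec: GridSpec = GridSpec()) -> set[tuple[int, int]]:
    """Grid cells intersecting any of a species' range polygons."""
    cells: set[tuple[int, int]] = set()
    cell_m = spec.cell_m
    for geom in sp_range.polygons:
        minx, miny, maxx, maxy = geom.bounds
        ix0 = int(np.floor((minx - spec.x_origin_m) / cell_m))
        ix1 = int(np.floor((maxx - spec.x_origin_m) / cell_m))
        iy0 = int(np.floor((miny - spec.y_origin_m) / cell_m))
        iy1 = int(np.floor((maxy - spec.y_origin_m) / cell_m))
        prepared = prep(geom)
        for ix in range(ix0, ix1 + 1):
            for iy in range(iy0, iy1 + 1):
                cell = box(
                    spec.x_origin_m + ix * cell_m,
                    spec.y_origin_m + iy * cell_m,
                    spec.x_origin_m + (ix + 1) * cell_m,
                    spec.y_origin_m + (iy + 1) * cell_m,
                )
                if prepared.intersects(cell):
                    cells.add((ix, iy))
    return cells


def clip_by_depth(
    cells: set[tuple[int, int]],
    bathymetry: Mapping[tuple[int, int], float] | None,
    depth_min: float | None,
    depth_max: float | None,
    strict_depth: bool = True,
) -> set[tuple[int, int]]:
    """Remove cells whose maximum depth lies outside the species' range.

    ``bathymetry`` maps cells to their maximum depth (positive metres).
    With ``strict_depth`` (default) a cell is removed when its maximum
    depth < depth_min or > depth_max; with it off only the shallow bound is
    enforced (cells deeper than the species' maximum are kept, the
    reading under which shallow species retain deep cells).  Missing
    bathymetry or absent depth metadata skips clipping.
    """
    if bathymetry is None or (depth_min is None and depth_max is None):
        if depth_min is not None or depth_max is not None:
            warnings.warn("bathymetry missing; depth clipping skipped")
        return set(cells)
    out = set()
    for c in cells:
        if c not in bathymetry:
            out.add(c)
            continue
        depth = bathymetry[c]
        if depth_min is not None and depth < depth_min:
            continue
        if strict_depth and depth_max is not None and depth > depth_max:
            continue
        out.add(c)
    return out


def rasterize_richness(
    ranges: Sequence[SpeciesRange],
    spec: GridSpec = GridSpec(),
    bathymetry: Mapping[tuple[int, int], float] | None = None,
    strict_depth: bool = True,
) -> pd.DataFrame:
    """Per-cell species count from range polygons.

    Returns a table ``cell_id, ix, iy, n_species_total``; each species
    contributes at most one to each cell it intersects (after optional
    depth clipping).
    """
    counts: dict[tuple[int, int], int] = {}
    for rng in ranges:
        cells = range_cells(rng, spec)
        cells = clip_by_depth(cells, bathymetry, rng.depth_min, rng.depth_max, strict_depth)
        for c in cells:
            counts[c] = counts.get(c, 0) + 1
    rows = [
        {"cell_id": gridmod.cell_id(ix, iy), "ix": ix, "iy": iy, "n_species_total": n}
        for (ix, iy), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["cell_id", "ix", "iy", "n_species_total"])


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("species", "lat", "lon") if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    return df


def richness_from_occurrences(
    occurrences: pd.DataFrame,
    spec: GridSpec = GridSpec(),
    split_meridians: tuple[float, float] = DEFAULT_SPLIT_MERIDIANS,
    bathymetry: Mapping[tuple[int, int], float] | None = None,
) -> pd.DataFrame:
    """Convenience: build all species ranges and rasterize in one call."""
    ranges = [
        build_range(grp, split_meridians) for _, grp in occurrences.groupby("species")
    ]
    return rasterize_richness(ranges, spec, bathymetry)
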