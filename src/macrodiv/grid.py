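"""Equal-area Behrmann world grid.

All per-cell aggregation in the pipeline happens on a cylindrical equal-area
grid with standard parallel 30 deg N/S (the Behrmann projection) and square
cells of 200 km edge by default.  Because the projection is equal-area by
construction, every cell covers the same surface area regardless of latitude,
which is what makes per-cell diversity values comparable across the globe.

Forward mapping (R the authalic Earth radius, lambda/phi in radians)::

    x = R * lambda * cos(30 deg)
    y = R * sin(phi) / cos(30 deg)

Cells are half-open boxes ``[edge, edge + cell)`` in the projected plane with
a cell *corner* anchored at projected (0, 0); point-to-cell assignment is a
floor division and is therefore total and deterministic.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

#: Authalic Earth radius in metres (sphere of equal surface area).
EARTH_RADIUS_M = 6_371_007.181

#: Cosine of the standard parallel (30 degrees).
_COS_SP = math.cos(math.radians(30.0))


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Parameters of the equal-area world grid.

    Attributes
    ----------
    cell_km:
        Cell edge length in kilometres (200 by default).
    x_origin_m, y_origin_m:
        Projected coordinates of the grid anchor; a cell *corner* sits here.
    """

    cell_km: float = 200.0
    x_origin_m: float = 0.0
    y_origin_m: float = 0.0

    def __post_init__(self) -> None:
        if not self.cell_km > 0:
            raise ValueError(f"cell_km must be positive, got {self.cell_km}")

    @property
    def cell_m(self) -> float:
        return self.cell_km * 1000.0


@dataclasses.dataclass(frozen=True)
class LatBand:
    """Half-open 10-degree latitude band ``[lower, upper)``.

    The top band ``[80, 90]`` is closed so that the bands partition the full
    latitude range.
    """

    lower: float
    upper: float

    def __contains__(self, lat: float) -> bool:
        if self.upper >= 90.0:
            return self.lower <= lat <= 90.0
        return self.lower <= lat < self.upper


def project(lon, lat):
    """Forward Behrmann projection, degrees -> metres.

    Accepts scalars or arrays; raises ``ValueError`` when any latitude lies
    outside [-90, 90].
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    x = EARTH_RADIUS_M * np.radians(lon) * _COS_SP
    y = EARTH_RADIUS_M * np.sin(np.radians(lat)) / _COS_SP
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def unproject(x, y):
    """Inverse Behrmann projection, metres -> degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sin_phi = y * _COS_SP / EARTH_RADIUS_M
    if np.any(np.abs(sin_phi) > 1.0 + 1e-12):
        raise ValueError("y outside projected range")
    sin_phi = np.clip(sin_phi, -1.0, 1.0)
    lon = np.degrees(x / (EARTH_RADIUS_M * _COS_SP))
    lat = np.degrees(np.arcsin(sin_phi))
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat


def cell_of(lon, lat, spec: GridSpec = GridSpec()):
    """Assign point(s) to grid cell indices ``(ix, iy)``.

    A point exactly on a cell edge belongs to the cell on the increasing
    side (half-open convention).
    """
    x, y = project(lon, lat)
    ix = np.floor((np.asarray(x) - spec.x_origin_m) / spec.cell_m).astype(int)
    iy = np.floor((np.asarray(y) - spec.y_origin_m) / spec.cell_m).astype(int)
    if ix.ndim == 0:
        return int(ix), int(iy)
    return ix, iy


def cell_centroid(ix, iy, spec: GridSpec = GridSpec()):
    """Projected centroid (metres) of cell ``(ix, iy)``."""
    x = spec.x_origin_m + (np.asarray(ix, dtype=float) + 0.5) * spec.cell_m
    y = spec.y_origin_m + (np.asarray(iy, dtype=float) + 0.5) * spec.cell_m
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def cell_centroid_lonlat(ix, iy, spec: GridSpec = GridSpec()):
    """Centroid of cell ``(ix, iy)`` in degrees."""
    return unproject(*cell_centroid(ix, iy, spec))


def cell_id(ix, iy) -> str:
    """Stable string id for a cell, used as key in all output tables."""
    return f"c{int(ix)}_{int(iy)}"


def parse_cell_id(cid: str) -> tuple[int, int]:
    if not cid.startswith("c"):
        raise ValueError(f"malformed cell id: {cid!r}")
    ix, _, iy = cid[1:].partition("_")
    return int(ix), int(iy)


def band_of(lat: float) -> LatBand:
    """10-degree latitude band containing ``lat``.

    Bands are half-open on the poleward side except the closed top band
    [80, 90].
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    lower = math.floor(lat / 10.0) * 10.0
    if lower >= 80.0:
        lower = 80.0
    if lower < -90.0:
        lower = -90.0
    return LatBand(lower, lower + 10.0)


def grid_table(cells, spec: GridSpec = GridSpec()) -> pd.DataFrame:
    """Tabulate cells as ``cell_id, ix, iy, centroid_lon, centroid_lat, x_m, y_m``.

    ``cells`` is an iterable of (ix, iy) pairs.
    """
    rows = []
    for ix, iy in cells:
        x, y = cell_centroid(ix, iy, spec)
        lon, lat = unproject(x, y)
        rows.append(
            {
                "cell_id": cell_id(ix, iy),
                "ix": int(ix),
                "iy": int(iy),
                "centroid_lon": lon,
                "centroid_lat": lat,
                "x_m": x,
                "y_m": y,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "ix", "iy", "centroid_lon", "centroid_lat", "x_m", "y_m"],
    )
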