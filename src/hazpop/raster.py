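"""Raster data model, ESRI ASCII grid I/O, cell geometry and zonal primitives.

All grids are unprojected WGS84 geographic degrees with square cells,
row 0 northernmost, cells indexed (row, col) 0-based.  Values are held in
a float64 array with an explicit nodata sentinel; integer layers (zone
ids, deciles, counts) round-trip exactly through the ASCII format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

#: Authalic Earth radius in km, used for all cell-area and distance math.
EARTH_RADIUS_KM = 6371.0

DEFAULT_NODATA = -9999.0


class RasterFormatError(ValueError):
    """Raised for unreadable files, unsupported geometry or bad headers."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid.

    ``origin_lon``/``origin_lat`` locate the *top-left corner* of cell
    (0, 0); ``cell_size`` is in decimal degrees and cells are square.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float
    origin_lat: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.origin_lat - self.n_rows * self.cell_size < -90.0 - 1e-9:
            raise ValueError("grid extends below the south pole")
        if self.origin_lat > 90.0 + 1e-9:
            raise ValueError("grid origin above the north pole")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_max(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def lat_min(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    def row_center_lats(self) -> np.ndarray:
        """Latitude of cell centers for every row (north to south)."""
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def col_center_lons(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; may be out of range."""
        col = math.floor((lon - self.origin_lon) / self.cell_size)
        row = math.floor((self.origin_lat - lat) / self.cell_size)
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        row, col = self.index_of(lon, lat)
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def same_geometry(self, other: "GridSpec") -> bool:
        """Equality of geometry, ignoring the nodata sentinel."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin_lon, other.origin_lon)
            and math.isclose(self.origin_lat, other.origin_lat)
        )


@dataclass
class Raster:
    """A grid of real values with georeference and nodata sentinel."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match "
                f"grid shape {self.spec.shape}"
            )
        live = self.values[~self.nodata_mask()]
        if live.size and not np.all(np.isfinite(live)):
            raise ValueError("non-nodata raster values must be finite")

    def nodata_mask(self) -> np.ndarray:
        return self.values == self.spec.nodata

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata replaced by ``fill``."""
        return np.where(self.nodata_mask(), fill, self.values)

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy())


@dataclass
class ZoneMap:
    """Integer country-id grid sharing a spec with the population raster.

    ``0`` marks ocean/unassigned cells; country ids are positive integers
    declared in ``legend`` (zone_id -> human-readable name or ISO3 code).
    """

    spec: GridSpec
    zone_ids: np.ndarray
    legend: Mapping[int, str] = field(default_factory=dict)

    NO_ZONE = 0

    def __post_init__(self) -> None:
        self.zone_ids = np.asarray(self.zone_ids, dtype=np.int64)
        if self.zone_ids.shape != self.spec.shape:
            raise ValueError("zone array shape does not match grid shape")
        if (self.zone_ids < 0).any():
            raise ValueError("zone ids must be >= 0 (0 = unassigned)")
        present = set(np.unique(self.zone_ids)) - {self.NO_ZONE}
        if self.legend and not present <= set(self.legend):
            missing = sorted(present - set(self.legend))
            raise ValueError(f"zone ids missing from legend: {missing}")

    def countries(self) -> list[int]:
        ids = np.unique(self.zone_ids)
        return [int(z) for z in ids if z != self.NO_ZONE]


@dataclass
class CellAreaGrid:
    """Per-cell surface area in km², constant along rows."""

    spec: GridSpec
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != self.spec.shape:
            raise ValueError("area array shape does not match grid shape")
        if not (self.areas > 0).all():
            raise ValueError("cell areas must be positive")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
                "yllcenter", "cellsize", "dx", "dy", "nodata_value"}


def read_raster(path: str | Path) -> Raster:
    """Read a single-band ESRI ASCII grid (.asc).

    Raises :class:`RasterFormatError` on missing files, malformed headers
    or non-square cells (``dx != dy`` variants).
    """
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows"):
        if key not in header:
            raise RasterFormatError(f"missing {key} in header of {path}")
    if "dx" in header or "dy" in header:
        if header.get("dx") != header.get("dy"):
            raise RasterFormatError("non-square cells are not supported")
        header["cellsize"] = header["dx"]
    if "cellsize" not in header:
        raise RasterFormatError(f"missing cellsize in header of {path}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cell / 2.0
    else:
        raise RasterFormatError(f"missing x georeference in {path}")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cell / 2.0
    else:
        raise RasterFormatError(f"missing y georeference in {path}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        values = np.loadtxt(lines[data_start:], ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"unparseable data block in {path}: {exc}") from exc
    if values.shape != (n_rows, n_cols):
        raise RasterFormatError(
            f"data block shape {values.shape} does not match header "
            f"({n_rows}, {n_cols}) in {path}"
        )
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_lon=xll,
        origin_lat=yll + n_rows * cell,
        nodata=nodata,
    )
    return Raster(spec, values)


def write_raster(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid; integer-valued layers round-trip exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    s = raster.spec
    vals = raster.values
    integral = np.all(vals == np.round(vals))
    fmt = "%d" if integral else "%.17g"
    with open(path, "w") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {s.origin_lon:.12g}\n")
        fh.write(f"yllcorner {s.lat_min:.12g}\n")
        fh.write(f"cellsize {s.cell_size:.12g}\n")
        fh.write(f"NODATA_value {s.nodata:.12g}\n")
        np.savetxt(fh, vals if not integral else vals.astype(np.int64), fmt=fmt)


# ---------------------------------------------------------------------------
# Geometry and resampling
# ---------------------------------------------------------------------------

def resample_nearest(src: Raster, target: GridSpec) -> Raster:
    """Nearest-neighbour resampling by cell-center containment.

    Each target cell takes the value of the source cell containing the
    target cell's center; centers outside the source extent get nodata.
    Categorical layers (deciles, masks) are therefore never interpolated.
    """
    if src.spec.same_geometry(target):
        out = src.values.copy()
        out[src.nodata_mask()] = target.nodata
        return Raster(target, out)

    s = src.spec
    if (
        target.origin_lon >= s.lon_max
        or target.lon_max <= s.origin_lon
        or target.origin_lat <= s.lat_min
        or target.lat_min >= s.origin_lat
    ):
        raise ValueError("source and target extents are disjoint")

    lons = target.col_center_lons()
    lats = target.row_center_lats()
    cols = np.floor((lons - s.origin_lon) / s.cell_size).astype(int)
    rows = np.floor((s.origin_lat - lats) / s.cell_size).astype(int)
    ok_col = (cols >= 0) & (cols < s.n_cols)
    ok_row = (rows >= 0) & (rows < s.n_rows)
    out = np.full(target.shape, target.nodata, dtype=float)
    rr = rows[ok_row][:, None]
    cc = cols[ok_col][None, :]
    picked = src.values[rr, cc]
    picked[picked == s.nodata] = target.nodata
    idx = np.ix_(ok_row, ok_col)
    out[idx] = picked
    return Raster(target, out)


def cell_areas(spec: GridSpec) -> CellAreaGrid:
    """Spherical cell areas: (R·Δ)·(R·Δ·cos φ) with φ the row-center latitude."""
    delta = math.radians(spec.cell_size)
    lat = np.radians(spec.row_center_lats())
    row_area = (EARTH_RADIUS_KM * delta) ** 2 * np.cos(lat)
    areas = np.repeat(row_area[:, None], spec.n_cols, axis=1)
    return CellAreaGrid(spec, areas)


def zonal_sum(values: Raster, zones: ZoneMap) -> dict[int, float]:
    """Sum of values per country id; nodata cells contribute zero."""
    if not values.spec.same_geometry(zones.spec):
        raise ValueError("value raster and zone map have different grids")
    vals = values.filled(0.0).ravel()
    ids = zones.zone_ids.ravel()
    sums = np.bincount(ids, weights=vals)
    return {
        int(z): float(sums[z])
        for z in np.unique(ids)
        if z != ZoneMap.NO_ZONE
    }
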