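"""Hazard event records -> frequency grids -> relative-frequency deciles.

Cyclone tracks are buffered by a per-category great-circle radius; flood
footprints are degree-snapped bounding boxes tallied by cell-center
containment; drought events are maximal runs of three or more consecutive
months at or below half the long-term median for that calendar month.
Counts are one tally per event per cell, never per day or per track point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .raster import CellAreaGrid, EARTH_RADIUS_KM, GridSpec, Raster

#: Default great-circle buffer radius (km) per intensity category 1-6.
DEFAULT_CATEGORY_RADII_KM: dict[int, float] = {
    1: 50.0, 2: 100.0, 3: 150.0, 4: 200.0, 5: 250.0, 6: 300.0,
}

#: Minimum population density (persons/km²) for a cell to stay in the
#: hazard-decile population unless it has significant agriculture.
MIN_DENSITY_PER_KM2 = 5.0

#: Monthly medians below this (mm) never qualify as drought; guards the
#: degenerate 0 <= 0.5·0 case in hyper-arid cells.
DEFAULT_MIN_MEDIAN_MM = 1.0


@dataclass(frozen=True)
class CycloneTrack:
    event_id: str
    points: tuple[tuple[float, float], ...]  # (lon, lat) pairs
    category: int

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("a track needs at least one point")
        if not 1 <= self.category <= 6:
            raise ValueError(f"category must be 1..6, got {self.category}")


@dataclass(frozen=True)
class FloodEvent:
    """Flood footprint as a bounding box with whole-degree corners."""

    event_id: str
    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float

    def __post_init__(self) -> None:
        for v in (self.lon_min, self.lat_min, self.lon_max, self.lat_max):
            if v != round(v):
                raise ValueError("flood footprint corners must be whole degrees")
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("flood footprint box is degenerate")


@dataclass
class PrecipCube:
    """Monthly precipitation stack (mm): shape (n_months, n_rows, n_cols)."""

    spec: GridSpec
    values: np.ndarray
    start_month: int = 1  # calendar month (1-12) of band 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.spec.shape:
            raise ValueError("precip cube must be (months, rows, cols) on spec")
        if self.values.shape[0] < 36:
            raise ValueError("need at least 36 monthly bands")
        if (self.values < 0).any():
            raise ValueError("precipitation must be non-negative")
        if not 1 <= self.start_month <= 12:
            raise ValueError("start_month must be 1..12")

    @property
    def n_months(self) -> int:
        return self.values.shape[0]


@dataclass
class FrequencyGrid:
    """Per-cell non-negative integer event count on a spec."""

    spec: GridSpec
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != self.spec.shape:
            raise ValueError("count array shape does not match grid shape")
        if (self.counts < 0).any():
            raise ValueError("event counts must be non-negative")


@dataclass
class DecileGrid:
    """Per-cell decile in {0..10}; 0 = no event or excluded cell."""

    spec: GridSpec
    deciles: np.ndarray

    def __post_init__(self) -> None:
        self.deciles = np.asarray(self.deciles, dtype=np.int64)
        if self.deciles.shape != self.spec.shape:
            raise ValueError("decile array shape does not match grid shape")
        if ((self.deciles < 0) | (self.deciles > 10)).any():
            raise ValueError("deciles must lie in 0..10")


@dataclass
class HazardWeightGrid:
    """Hazard likelihood weight H = decile/10, in {0.0, 0.1, ..., 1.0}."""

    spec: GridSpec
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.spec.shape:
            raise ValueError("weight array shape does not match grid shape")


# ---------------------------------------------------------------------------
# Event tallying
# ---------------------------------------------------------------------------

def _haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km; accepts arrays."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def cyclone_frequency(
    tracks: Iterable[CycloneTrack],
    spec: GridSpec,
    radii_km: Mapping[int, float] = DEFAULT_CATEGORY_RADII_KM,
) -> FrequencyGrid:
    """Tally, per cell, the number of cyclone events whose buffered track
    covers the cell center.  A cell is tallied at most once per event,
    regardless of how many track points pass within the buffer.
    """
    cats = sorted(radii_km)
    if any(radii_km[a] > radii_km[b] for a, b in zip(cats, cats[1:])):
        raise ValueError("buffer radii must be non-decreasing in category")
    lats = spec.row_center_lats()
    lons = spec.col_center_lons()
    counts = np.zeros(spec.shape, dtype=np.int64)
    deg_per_km_lat = 1.0 / (EARTH_RADIUS_KM * math.pi / 180.0)
    for track in tracks:
        if track.category not in radii_km:
            raise ValueError(f"no buffer radius for category {track.category}")
        radius = radii_km[track.category]
        covered = np.zeros(spec.shape, dtype=bool)
        pad_lat = radius * deg_per_km_lat * 1.05
        for lon, lat in track.points:
            # window the distance computation to a small lat/lon box
            coslat = max(math.cos(math.radians(lat)), 1e-6)
            pad_lon = pad_lat / coslat
            ri = np.nonzero(np.abs(lats - lat) <= pad_lat + spec.cell_size)[0]
            ci = np.nonzero(np.abs(lons - lon) <= pad_lon + spec.cell_size)[0]
            if ri.size == 0 or ci.size == 0:
                continue
            d = _haversine_km(
                lons[ci][None, :], lats[ri][:, None], lon, lat
            )
            hit = d <= radius
            covered[np.ix_(ri, ci)] |= hit
        counts += covered
    return FrequencyGrid(spec, counts)


def flood_frequency(events: Iterable[FloodEvent], spec: GridSpec) -> FrequencyGrid:
    """Count, per cell, the inundation events whose footprint contains the
    cell center (events, not inundated days)."""
    lats = spec.row_center_lats()
    lons = spec.col_center_lons()
    counts = np.zeros(spec.shape, dtype=np.int64)
    for ev in events:
        in_lat = (lats >= ev.lat_min) & (lats <= ev.lat_max)
        in_lon = (lons >= ev.lon_min) & (lons <= ev.lon_max)
        counts[np.ix_(in_lat, in_lon)] += 1
    return FrequencyGrid(spec, counts)


def monthly_medians(series: np.ndarray, start_month: int = 1) -> np.ndarray:
    """Long-term median per calendar month (index 0 = January)."""
    series = np.asarray(series, dtype=float)
    meds = np.empty(12)
    months = (np.arange(series.size) + start_month - 1) % 12
    for m in range(12):
        sel = series[months == m]
        meds[m] = np.median(sel) if sel.size else np.nan
    return meds


def detect_drought_events(
    series: Sequence[float],
    medians: np.ndarray | None = None,
    min_median_mm: float = DEFAULT_MIN_MEDIAN_MM,
    start_month: int = 1,
) -> int:
    """Number of drought events in one cell's monthly series.

    A month qualifies when its calendar month's long-term median is at
    least ``min_median_mm`` and precipitation is at or below half that
    median; an event is a maximal run of three or more consecutive
    qualifying months.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("series must span at least 3 months")
    if medians is None:
        medians = monthly_medians(series, start_month)
    medians = np.asarray(medians, dtype=float)
    months = (np.arange(series.size) + start_month - 1) % 12
    med = medians[months]
    qualifies = (med >= min_median_mm) & (series <= 0.5 * med)
    # count maximal runs of >= 3 consecutive qualifying months
    events = 0
    run = 0
    for q in qualifies:
        if q:
            run += 1
        else:
            if run >= 3:
                events += 1
            run = 0
    if run >= 3:
        events += 1
    return events


def drought_frequency(
    cube: PrecipCube, min_median_mm: float = DEFAULT_MIN_MEDIAN_MM
) -> FrequencyGrid:
    """Apply drought run-detection to every cell of a precipitation cube."""
    counts = np.zeros(cube.spec.shape, dtype=np.int64)
    for r in range(cube.spec.n_rows):
        for c in range(cube.spec.n_cols):
            counts[r, c] = detect_drought_events(
                cube.values[:, r, c],
                min_median_mm=min_median_mm,
                start_month=cube.start_month,
            )
    return FrequencyGrid(cube.spec, counts)


# ---------------------------------------------------------------------------
# Exclusion mask, decile binning, weights
# ---------------------------------------------------------------------------

def valid_cell_mask(
    pop: Raster, areas: CellAreaGrid, agriculture: Raster
) -> np.ndarray:
    """Cells kept in the decile population: density >= 5 persons/km² OR
    significant agriculture.  Returns a boolean array on pop's grid."""
    if not (pop.spec.same_geometry(areas.spec)
            and pop.spec.same_geometry(agriculture.spec)):
        raise ValueError("population, area and agriculture grids differ")
    density = pop.filled(0.0) / areas.areas
    agri = agriculture.filled(0.0) > 0
    return (density >= MIN_DENSITY_PER_KM2) | agri


def _nearest_rank_percentile(sorted_vals: np.ndarray, pct: float) -> float:
    n = sorted_vals.size
    idx = max(int(math.ceil(pct / 100.0 * n)), 1) - 1
    return float(sorted_vals[idx])


def to_deciles(freq: FrequencyGrid, mask: np.ndarray) -> DecileGrid:
    """Bin positive counts of valid cells into global relative-frequency
    deciles 1-10; invalid or zero-count cells get 0.

    Boundaries are the nearest-rank 10th..90th percentiles of the counts;
    a cell's decile is 1 + the number of boundaries strictly below its
    count, so tied counts always share a decile.  If every positive count
    is identical, all those cells sit in the top decile.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != freq.spec.shape:
        raise ValueError("mask shape does not match grid shape")
    positive = mask & (freq.counts >= 1)
    deciles = np.zeros(freq.spec.shape, dtype=np.int64)
    vals = freq.counts[positive]
    if vals.size == 0:
        return DecileGrid(freq.spec, deciles)
    if vals.min() == vals.max():
        deciles[positive] = 10
        return DecileGrid(freq.spec, deciles)
    svals = np.sort(vals)
    bounds = np.array(
        [_nearest_rank_percentile(svals, p) for p in range(10, 100, 10)]
    )
    counts = freq.counts[positive][:, None]
    deciles[positive] = 1 + (bounds[None, :] < counts).sum(axis=1)
    return DecileGrid(freq.spec, deciles)


def decile_weights(d: DecileGrid) -> HazardWeightGrid:
    """Map deciles to likelihood weights H = decile / 10."""
    return HazardWeightGrid(d.spec, d.deciles / 10.0)
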