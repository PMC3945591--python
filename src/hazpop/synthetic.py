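"""Synthetic input worlds: rectangular countries, clustered populations,
seeded hazard events and precipitation with injected deficit runs.

Everything is generated from a single seed and integer-valued where
aggregation identities must hold bit-exactly.  ``generate_world`` builds a
random but statistically controlled world; ``make_extreme_country_fixture``
builds a world in which country 1 monopolises the top decile of every
hazard, pinning the theoretical score maxima (1.0 per hazard, 3.0 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .hazards import CycloneTrack, FloodEvent, PrecipCube
from .raster import GridSpec, Raster, ZoneMap

HDI_CYCLE = ("Very High", "High", "Medium", "Low")


@dataclass(frozen=True)
class WorldConfig:
    """Knobs for the synthetic world generator; same seed -> same world."""

    seed: int = 0
    n_rows: int = 16
    n_cols: int = 32
    cell_size: float = 1.0
    origin_lon: float = 0.0
    origin_lat: float = 8.0
    n_countries: int = 8
    # population model
    pop_fill_prob: float = 0.7
    rural_log_mean: float = 3.0
    rural_log_sigma: float = 1.0
    cores_per_country: int = 2
    core_peak: float = 20000.0
    agriculture_prob: float = 0.3
    # cyclone model
    n_cyclone_tracks: int = 40
    track_points: int = 8
    track_step_deg: float = 1.0
    cyclone_west_bias: float = 2.0
    # flood model
    flood_rate: float = 25.0
    max_flood_extent_deg: int = 3
    # drought model
    drought_coarsen: int = 2
    n_months: int = 120
    start_month: int = 1
    precip_base_mm: float = 100.0
    precip_seasonal_amp: float = 0.4
    drought_run_prob: float = 0.4
    max_drought_runs: int = 2
    arid_country: int | None = None
    # tables
    urban_fraction_range: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if self.n_countries > self.n_cols:
            raise ValueError("more countries than grid columns")
        if not 0 <= self.pop_fill_prob <= 1:
            raise ValueError("pop_fill_prob must lie in [0,1]")
        lo, hi = self.urban_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("urban_fraction_range must lie in [0,1]")


@dataclass
class World:
    """A complete set of model inputs plus a ground-truth sidecar."""

    spec: GridSpec
    population: Raster
    zones: ZoneMap
    agriculture: Raster
    tracks: list[CycloneTrack]
    floods: list[FloodEvent]
    precip: PrecipCube
    urban_fractions: dict[int, float]
    hdi: dict[int, str]
    ground_truth: dict[str, Any] = field(default_factory=dict)


def _strip_zones(spec: GridSpec, n_countries: int,
                 widths: list[int] | None = None) -> ZoneMap:
    """Partition the grid into vertical country strips (ids 1..n)."""
    if widths is None:
        base, extra = divmod(spec.n_cols, n_countries)
        widths = [base + (1 if i < extra else 0) for i in range(n_countries)]
    ids = np.zeros(spec.shape, dtype=np.int64)
    col = 0
    legend = {}
    for i, w in enumerate(widths, start=1):
        ids[:, col:col + w] = i
        legend[i] = f"C{i:03d}"
        col += w
    return ZoneMap(spec, ids, legend)


def _inject_runs(
    series: np.ndarray,
    base_by_month: np.ndarray,
    n_runs: int,
    rng: np.random.Generator,
    start_month: int,
) -> int:
    """Overwrite ``n_runs`` disjoint 3-5 month spans with 40% of the
    climatological base, leaving at least one normal month between spans.

    No calendar month is lowered by more than one run, so each month's
    long-term median stays at the unperturbed level and every injected
    run is detectable exactly, even in short series.  Returns the number
    of runs actually placed."""
    m = series.size
    block = m // n_runs
    placed = 0
    used_cal_months: set[int] = set()
    for j in range(n_runs):
        run_len = int(rng.integers(3, 6))
        lo = j * block
        hi = min((j + 1) * block, m) - run_len - 1  # trailing gap inside block
        if hi < lo:
            continue
        for _ in range(8):  # retry placement a few times, else skip the run
            start = int(rng.integers(lo, hi + 1))
            months = (np.arange(start, start + run_len) + start_month - 1) % 12
            if used_cal_months.isdisjoint(months):
                series[start:start + run_len] = 0.4 * base_by_month[months]
                used_cal_months.update(months.tolist())
                placed += 1
                break
    return placed


def generate_world(cfg: WorldConfig) -> World:
    rng = np.random.default_rng(cfg.seed)
    spec = GridSpec(
        n_rows=cfg.n_rows, n_cols=cfg.n_cols, cell_size=cfg.cell_size,
        origin_lon=cfg.origin_lon, origin_lat=cfg.origin_lat,
    )
    zones = _strip_zones(spec, cfg.n_countries)

    # population: sparse rounded log-normal background + urban cores
    populated = rng.random(spec.shape) < cfg.pop_fill_prob
    background = np.round(
        rng.lognormal(cfg.rural_log_mean, cfg.rural_log_sigma, spec.shape)
    )
    pop = np.where(populated, background, 0.0)
    for country in zones.countries():
        rows, cols = np.nonzero(zones.zone_ids == country)
        picks = rng.choice(rows.size, size=min(cfg.cores_per_country, rows.size),
                           replace=False)
        for p in picks:
            pop[rows[p], cols[p]] += np.round(
                cfg.core_peak * (0.5 + rng.random())
            )
        if pop[rows, cols].sum() == 0:  # every country must be inhabited
            p = int(rng.integers(rows.size))
            pop[rows[p], cols[p]] = 100.0
    population = Raster(spec, pop)

    agriculture = Raster(
        spec, (rng.random(spec.shape) < cfg.agriculture_prob).astype(float)
    )

    # cyclone tracks: random walks, more frequent toward the grid's west
    tracks: list[CycloneTrack] = []
    lon_span = spec.n_cols * spec.cell_size
    lat_span = spec.n_rows * spec.cell_size
    for i in range(cfg.n_cyclone_tracks):
        lon = spec.origin_lon + lon_span * rng.beta(1.0, cfg.cyclone_west_bias)
        lat = spec.origin_lat - lat_span * rng.random()
        pts = [(lon, lat)]
        for _ in range(cfg.track_points - 1):
            lon += rng.normal(0.0, cfg.track_step_deg)
            lat += rng.normal(0.0, cfg.track_step_deg)
            pts.append((lon, float(np.clip(lat, -89.0, 89.0))))
        category = int(rng.integers(1, 7))
        tracks.append(CycloneTrack(f"cyc{i:04d}", tuple(pts), category))

    # flood events: Poisson count of small integral-degree boxes
    n_floods = int(rng.poisson(cfg.flood_rate))
    floods: list[FloodEvent] = []
    lon0 = int(np.floor(spec.origin_lon))
    lat1 = int(np.ceil(spec.origin_lat))
    for i in range(n_floods):
        w = int(rng.integers(1, cfg.max_flood_extent_deg + 1))
        h = int(rng.integers(1, cfg.max_flood_extent_deg + 1))
        x = int(rng.integers(lon0, lon0 + int(lon_span) - w + 1))
        y = int(rng.integers(lat1 - int(lat_span), lat1 - h + 1))
        floods.append(FloodEvent(f"flo{i:04d}", x, y, x + w, y + h))

    # precipitation on a coarser grid, with injected deficit runs
    ck = max(cfg.drought_coarsen, 1)
    cspec = GridSpec(
        n_rows=max(cfg.n_rows // ck, 1), n_cols=max(cfg.n_cols // ck, 1),
        cell_size=cfg.cell_size * ck,
        origin_lon=cfg.origin_lon, origin_lat=cfg.origin_lat,
    )
    months = (np.arange(cfg.n_months) + cfg.start_month - 1) % 12
    precip = np.zeros((cfg.n_months, cspec.n_rows, cspec.n_cols))
    injected: dict[str, int] = {}
    arid_cols = None
    if cfg.arid_country is not None:
        strip = zones.zone_ids[0] == cfg.arid_country
        if strip.any():
            arid_cols = (
                int(np.argmax(strip)),
                int(spec.n_cols - np.argmax(strip[::-1])),
            )
    for r in range(cspec.n_rows):
        for c in range(cspec.n_cols):
            lon, lat = cspec.cell_center(r, c)
            if arid_cols is not None:
                fine_col = int((lon - spec.origin_lon) / spec.cell_size)
                if arid_cols[0] <= fine_col < arid_cols[1]:
                    precip[:, r, c] = 0.0  # hyper-arid: no rain, no droughts
                    continue
            phase = rng.uniform(0, 2 * np.pi)
            base = cfg.precip_base_mm * (
                1.0 + cfg.precip_seasonal_amp * np.sin(2 * np.pi * np.arange(12) / 12 + phase)
            )
            series = base[months] * rng.uniform(0.8, 1.2, cfg.n_months)
            n_runs = 0
            if rng.random() < cfg.drought_run_prob:
                n_runs = _inject_runs(
                    series, base, int(rng.integers(1, cfg.max_drought_runs + 1)),
                    rng, cfg.start_month,
                )
            if n_runs:
                injected[f"{r},{c}"] = n_runs
            precip[:, r, c] = series
    cube = PrecipCube(cspec, precip, cfg.start_month)

    lo, hi = cfg.urban_fraction_range
    fractions = {
        z: float(np.round(rng.uniform(lo, hi), 4)) for z in zones.countries()
    }
    order = rng.permutation(zones.countries())
    hdi = {int(z): HDI_CYCLE[i % 4] for i, z in enumerate(order)}

    truth = {
        "drought_runs_injected": injected,
        "n_flood_events": n_floods,
        "n_cyclone_tracks": cfg.n_cyclone_tracks,
        "seed": cfg.seed,
    }
    return World(spec, population, zones, agriculture, tracks, floods,
                 cube, fractions, hdi, truth)


# ---------------------------------------------------------------------------
# Extreme-country fixture
# ---------------------------------------------------------------------------

#: Event count given to every populated cell of country 1 in the fixture;
#: strictly above all nine decile boundaries (which land on counts 1..9).
EXTREME_COUNT = 12


def make_extreme_country_fixture(
    spec: GridSpec | None = None, n_countries: int = 3
) -> World:
    """World in which country 1's populated cells all carry the highest
    decile of every hazard, so its single-hazard scores are exactly 1.0
    and its multi-hazard score exactly 3.0.

    Country 1 occupies a 10×10 block: ten populated "core" cells (middle
    row) given EXTREME_COUNT events per hazard, and ninety uninhabited
    agricultural filler cells with counts 1..9 (ten each) that anchor the
    nine decile boundaries below the core count.  Remaining countries are
    populated but experience no events at all.
    """
    if n_countries < 2:
        raise ValueError("fixture needs at least 2 countries")
    need_cols = 10 + 2 * (n_countries - 1)
    if spec is None:
        spec = GridSpec(n_rows=10, n_cols=need_cols, cell_size=1.0,
                        origin_lon=0.0, origin_lat=5.0)
    if spec.n_rows < 10 or spec.n_cols < need_cols:
        raise ValueError("grid too small for the extreme-country layout")
    widths = [10] + [2] * (n_countries - 2)
    widths.append(spec.n_cols - sum(widths))
    zones = _strip_zones(spec, n_countries, widths)

    pop = np.zeros(spec.shape)
    agri = np.zeros(spec.shape)
    mid = spec.n_rows // 2 - 1  # row 4 on the default 10-row grid
    core_cells = [(mid, c) for c in range(10)]
    for r, c in core_cells:
        pop[r, c] = 1000.0
        agri[r, c] = 1.0
    filler_cells = [
        (r, c) for r in range(10) for c in range(10) if r != mid
    ]
    filler_counts = {}
    for i, (r, c) in enumerate(filler_cells):
        agri[r, c] = 1.0
        filler_counts[(r, c)] = 1 + i // 10  # counts 1..9, ten cells each

    col = 10
    for i in range(1, n_countries):
        pop[mid, col] = 500.0
        pop[mid, col + 1] = 500.0
        col += widths[i]

    counts = dict(filler_counts)
    counts.update({cell: EXTREME_COUNT for cell in core_cells})

    tracks: list[CycloneTrack] = []
    floods: list[FloodEvent] = []
    eid = 0
    for (r, c), k in sorted(counts.items()):
        lon, lat = spec.cell_center(r, c)
        x0 = int(round(lon - 0.5))
        y0 = int(round(lat - 0.5))
        for _ in range(k):
            tracks.append(CycloneTrack(f"cyc{eid:05d}", ((lon, lat),), 1))
            floods.append(FloodEvent(f"flo{eid:05d}", x0, y0, x0 + 1, y0 + 1))
            eid += 1

    # 120-month cube; deficit runs at 4-month stride never dominate any
    # calendar month's 10 samples, so medians stay at the 100 mm base
    n_months = 120
    precip = np.full((n_months, spec.n_rows, spec.n_cols), 100.0)
    for (r, c), k in counts.items():
        for j in range(k):
            precip[4 * j:4 * j + 3, r, c] = 40.0
    cube = PrecipCube(spec, precip, start_month=1)

    fractions = {z: 0.3 for z in zones.countries()}
    hdi = {z: HDI_CYCLE[(z - 1) % 4] for z in zones.countries()}
    truth = {
        "core_cells": [list(cell) for cell in core_cells],
        "core_count": EXTREME_COUNT,
        "expected_country1_single_hazard_score": 1.0,
        "expected_country1_multi_hazard_score": 3.0,
    }
    return World(spec, Raster(spec, pop), zones, Raster(spec, agri),
                 tracks, floods, cube, fractions, hdi, truth)
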