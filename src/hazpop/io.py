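"""Text-format I/O for event records, precipitation stacks and tables.

Grids travel as ESRI ASCII (.asc); the monthly precipitation cube uses a
multiband extension of the same header (extra ``nbands``/``start_month``
keys followed by one data block per month), keeping every artifact plain
text.  Tabular data are CSV with fixed column orders.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .hazards import CycloneTrack, FloodEvent, PrecipCube
from .raster import GridSpec, Raster, ZoneMap, read_raster, write_raster
from .synthetic import World

TRACK_COLUMNS = ["event_id", "point_index", "lon", "lat", "category"]
FLOOD_COLUMNS = ["event_id", "lon_min", "lat_min", "lon_max", "lat_max"]


def write_tracks_csv(tracks: Iterable[CycloneTrack], path: str | Path) -> None:
    rows = []
    for t in tracks:
        for i, (lon, lat) in enumerate(t.points):
            rows.append((t.event_id, i, lon, lat, t.category))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_tracks_csv(path: str | Path) -> list[CycloneTrack]:
    df = pd.read_csv(path)
    tracks = []
    for eid, grp in df.groupby("event_id", sort=False):
        grp = grp.sort_values("point_index")
        pts = tuple(zip(grp["lon"].astype(float), grp["lat"].astype(float)))
        tracks.append(CycloneTrack(str(eid), pts, int(grp["category"].iloc[0])))
    return tracks


def write_floods_csv(events: Iterable[FloodEvent], path: str | Path) -> None:
    rows = [(e.event_id, e.lon_min, e.lat_min, e.lon_max, e.lat_max)
            for e in events]
    pd.DataFrame(rows, columns=FLOOD_COLUMNS).to_csv(path, index=False)


def read_floods_csv(path: str | Path) -> list[FloodEvent]:
    df = pd.read_csv(path)
    return [
        FloodEvent(str(r.event_id), float(r.lon_min), float(r.lat_min),
                   float(r.lon_max), float(r.lat_max))
        for r in df.itertuples()
    ]


def write_precip(cube: PrecipCube, path: str | Path) -> None:
    s = cube.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {s.origin_lon:.12g}\n")
        fh.write(f"yllcorner {s.lat_min:.12g}\n")
        fh.write(f"cellsize {s.cell_size:.12g}\n")
        fh.write(f"NODATA_value {s.nodata:.12g}\n")
        fh.write(f"nbands {cube.n_months}\n")
        fh.write(f"start_month {cube.start_month}\n")
        for band in cube.values:
            np.savetxt(fh, band, fmt="%.12g")


def read_precip(path: str | Path) -> PrecipCube:
    with open(path) as fh:
        header = {}
        for _ in range(8):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nbands = int(header["nbands"])
    spec = GridSpec(
        n_rows=n_rows, n_cols=n_cols, cell_size=header["cellsize"],
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        nodata=header["nodata_value"],
    )
    values = data.reshape(nbands, n_rows, n_cols)
    return PrecipCube(spec, values, int(header["start_month"]))


def write_fractions_csv(fractions: dict[int, float], path: str | Path) -> None:
    pd.DataFrame(
        sorted(fractions.items()), columns=["country_id", "proportion_urban"]
    ).to_csv(path, index=False, float_format="%.10g")


def read_fractions_csv(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path)
    return dict(zip(df["country_id"].astype(int),
                    df["proportion_urban"].astype(float)))


def write_hdi_csv(hdi: dict[int, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(hdi.items()), columns=["country_id", "hdi_class"]
    ).to_csv(path, index=False)


def read_hdi_csv(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path)
    return dict(zip(df["country_id"].astype(int), df["hdi_class"].astype(str)))


def write_legend_csv(legend: dict[int, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(legend.items()), columns=["zone_id", "name"]
    ).to_csv(path, index=False)


def read_legend_csv(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path)
    return dict(zip(df["zone_id"].astype(int), df["name"].astype(str)))


# ---------------------------------------------------------------------------
# Whole-world round trip (the pipeline's inputs/ directory)
# ---------------------------------------------------------------------------

def write_world(world: World, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_raster(world.population, directory / "population.asc")
    write_raster(Raster(world.spec, world.zones.zone_ids.astype(float)),
                 directory / "zones.asc")
    write_legend_csv(dict(world.zones.legend), directory / "zones_legend.csv")
    write_raster(world.agriculture, directory / "agriculture.asc")
    write_tracks_csv(world.tracks, directory / "cyclone_tracks.csv")
    write_floods_csv(world.floods, directory / "flood_events.csv")
    write_precip(world.precip, directory / "precip.txt")
    write_fractions_csv(world.urban_fractions, directory / "urban_fractions.csv")
    write_hdi_csv(world.hdi, directory / "hdi.csv")
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(world.ground_truth, fh, indent=1, sort_keys=True)


def read_world(directory: str | Path) -> World:
    directory = Path(directory)
    population = read_raster(directory / "population.asc")
    zr = read_raster(directory / "zones.asc")
    legend = read_legend_csv(directory / "zones_legend.csv")
    zone_ids = zr.filled(0.0).astype(np.int64)
    zones = ZoneMap(population.spec, zone_ids, legend)
    agriculture = read_raster(directory / "agriculture.asc")
    tracks = read_tracks_csv(directory / "cyclone_tracks.csv")
    floods = read_floods_csv(directory / "flood_events.csv")
    precip = read_precip(directory / "precip.txt")
    fractions = read_fractions_csv(directory / "urban_fractions.csv")
    hdi = read_hdi_csv(directory / "hdi.csv")
    truth_path = directory / "ground_truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return World(population.spec, population, zones, agriculture,
                 tracks, floods, precip, fractions, hdi, truth)
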