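"""End-to-end pipeline: staged, file-backed, dataset-swappable.

Stages communicate only through ordinary files under the output directory,
so any input dataset can be replaced and the downstream stages re-run:

    inputs/    population.asc zones.asc agriculture.asc cyclone_tracks.csv
               flood_events.csv precip.txt urban_fractions.csv hdi.csv
    hazards/   freq_*.asc decile_*.asc weight_*.asc valid_mask.asc
    classify/  urban_rural.asc thresholds.csv
    exposure/  exposure_*.asc country_exposure.csv hdi_class_averages.csv
    report/    exposure_<hazard>_<stratum>.csv exposure_all.csv rank_table.csv
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .exposure import HAZARDS, build_exposure_table, hdi_class_average
from .hazards import (
    DEFAULT_CATEGORY_RADII_KM,
    DEFAULT_MIN_MEDIAN_MM,
    DecileGrid,
    FrequencyGrid,
    HazardWeightGrid,
    cyclone_frequency,
    decile_weights,
    drought_frequency,
    flood_frequency,
    to_deciles,
    valid_cell_mask,
)
from .raster import Raster, cell_areas, read_raster, resample_nearest, write_raster
from .ranking import build_rank_table, export_report
from .synthetic import World, WorldConfig, generate_world, make_extreme_country_fixture
from .urban import UrbanRuralMask, classify_urban_rural

log = logging.getLogger("hazpop")

STAGES = ("simulate", "hazards", "classify", "exposure", "rank")


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    synthetic: bool = True
    extreme_fixture: bool = False
    world: dict[str, Any] = field(default_factory=dict)
    radii_km: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_RADII_KM)
    )
    min_median_mm: float = DEFAULT_MIN_MEDIAN_MM
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "radii_km" in raw:
            raw["radii_km"] = {int(k): float(v) for k, v in raw["radii_km"].items()}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def stage_simulate(cfg: PipelineConfig) -> World:
    if cfg.extreme_fixture:
        world = make_extreme_country_fixture()
    else:
        world = generate_world(WorldConfig(seed=cfg.seed, **cfg.world))
    hio.write_world(world, cfg.outdir / "inputs")
    log.info("simulate: %d countries, %d tracks, %d floods",
             len(world.zones.countries()), len(world.tracks), len(world.floods))
    return world


def stage_hazards(cfg: PipelineConfig) -> dict[str, HazardWeightGrid]:
    indir = cfg.outdir / "inputs"
    world = hio.read_world(indir)
    outdir = cfg.outdir / "hazards"
    outdir.mkdir(parents=True, exist_ok=True)
    pop_spec = world.population.spec

    areas = cell_areas(pop_spec)
    mask = valid_cell_mask(world.population, areas, world.agriculture)
    write_raster(Raster(pop_spec, mask.astype(float)), outdir / "valid_mask.asc")

    freqs: dict[str, FrequencyGrid] = {
        "cyclone": cyclone_frequency(world.tracks, pop_spec, cfg.radii_km),
        "flood": flood_frequency(world.floods, pop_spec),
        "drought": drought_frequency(world.precip, cfg.min_median_mm),
    }
    weights: dict[str, HazardWeightGrid] = {}
    mask_raster = Raster(pop_spec, mask.astype(float))
    for hazard, freq in freqs.items():
        write_raster(Raster(freq.spec, freq.counts.astype(float)),
                     outdir / f"freq_{hazard}.asc")
        if freq.spec.same_geometry(pop_spec):
            native_mask = mask
        else:
            # carry the density/agriculture exclusion onto the hazard's
            # native grid by center-sampling before the global decile sort
            rs = resample_nearest(mask_raster, freq.spec)
            native_mask = rs.filled(0.0) > 0
        deciles = to_deciles(freq, native_mask)
        write_raster(Raster(deciles.spec, deciles.deciles.astype(float)),
                     outdir / f"decile_{hazard}.asc")
        dec_on_pop = resample_nearest(
            Raster(deciles.spec, deciles.deciles.astype(float)), pop_spec
        )
        dec_grid = DecileGrid(pop_spec, dec_on_pop.filled(0.0).astype(np.int64))
        w = decile_weights(dec_grid)
        write_raster(Raster(pop_spec, w.weights), outdir / f"weight_{hazard}.asc")
        weights[hazard] = w
        log.info("hazards/%s: %d cells with events, max count %d",
                 hazard, int((freq.counts > 0).sum()), int(freq.counts.max()))
    return weights


def stage_classify(cfg: PipelineConfig) -> UrbanRuralMask:
    world = hio.read_world(cfg.outdir / "inputs")
    outdir = cfg.outdir / "classify"
    outdir.mkdir(parents=True, exist_ok=True)
    mask = classify_urban_rural(world.population, world.zones,
                                world.urban_fractions)
    write_raster(Raster(mask.spec, mask.labels.astype(float)),
                 outdir / "urban_rural.asc")
    rows = [
        {"country_id": c, "threshold": thr, "achieved_share": share}
        for c, (thr, share) in sorted(mask.thresholds.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "thresholds.csv", index=False,
                              float_format="%.10g")
    log.info("classify: %d urban cells, %d rural cells",
             int((mask.labels == 1).sum()), int((mask.labels == 0).sum()))
    return mask


def _load_weights(cfg: PipelineConfig, pop_spec) -> dict[str, HazardWeightGrid]:
    weights = {}
    for hazard in HAZARDS:
        r = read_raster(cfg.outdir / "hazards" / f"weight_{hazard}.asc")
        if not r.spec.same_geometry(pop_spec):
            raise ValueError(f"weight grid for {hazard} is not on the "
                             "population grid; re-run the hazards stage")
        weights[hazard] = HazardWeightGrid(pop_spec, r.filled(0.0))
    return weights


def _load_urban_mask(cfg: PipelineConfig, pop_spec) -> UrbanRuralMask:
    r = read_raster(cfg.outdir / "classify" / "urban_rural.asc")
    return UrbanRuralMask(pop_spec, r.values.astype(np.int64))


def stage_exposure(cfg: PipelineConfig) -> pd.DataFrame:
    world = hio.read_world(cfg.outdir / "inputs")
    outdir = cfg.outdir / "exposure"
    outdir.mkdir(parents=True, exist_ok=True)
    weights = _load_weights(cfg, world.spec)
    urban_mask = _load_urban_mask(cfg, world.spec)
    pop = world.population.filled(0.0)
    multi = np.zeros(world.spec.shape)
    for hazard in HAZARDS:
        e = pop * weights[hazard].weights
        multi += e
        write_raster(Raster(world.spec, e), outdir / f"exposure_{hazard}.asc")
    write_raster(Raster(world.spec, multi), outdir / "exposure_multi.asc")
    table = build_exposure_table(weights, world.population, world.zones,
                                 urban_mask)
    table.to_csv(outdir / "country_exposure.csv", index=False,
                 float_format="%.10g")
    averages = hdi_class_average(table, world.hdi)
    averages.to_csv(outdir / "hdi_class_averages.csv", index=False,
                    float_format="%.10g")
    log.info("exposure: %d table rows over %d countries",
             len(table), table["country_id"].nunique())
    return table


def stage_rank(cfg: PipelineConfig) -> pd.DataFrame:
    table = pd.read_csv(cfg.outdir / "exposure" / "country_exposure.csv")
    ranks = build_rank_table(table)
    report_dir = cfg.outdir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    ranks.to_csv(report_dir / "rank_table.csv", index=False,
                 float_format="%.10g")
    export_report(table, ranks, report_dir)
    log.info("rank: %d rank rows", len(ranks))
    return ranks


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "hazards": stage_hazards,
    "classify": stage_classify,
    "exposure": stage_exposure,
    "rank": stage_rank,
}


def run_pipeline(cfg: PipelineConfig) -> None:
    """Run the configured stages in order; a failing stage aborts with its
    name while earlier stages' outputs remain on disk."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        if stage == "simulate" and not cfg.synthetic:
            log.info("simulate: skipped (non-synthetic inputs supplied)")
            continue
        log.info("== stage %s ==", stage)
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
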