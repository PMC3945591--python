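"""Population-exposure math: per-cell scores, country aggregation and
development-class averages.

Cell exposure is population × hazard weight; a country's score is the sum
of cell exposures divided by the population of the same cell set, computed
for the whole country and separately for its urban and rural strata.
Single-hazard scores lie in [0, 1]; the equally-weighted three-hazard sum
lies in [0, 3].  Strata with no population report a missing score, not 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .hazards import HazardWeightGrid
from .raster import GridSpec, Raster, ZoneMap, zonal_sum
from .urban import UrbanRuralMask

HAZARDS = ("cyclone", "drought", "flood")
ALL_HAZARDS = HAZARDS + ("multi",)
STRATA = ("total", "urban", "rural")

HDI_CLASSES = ("Low", "Medium", "High", "Very High")


@dataclass
class ExposureGrid:
    """Per-cell person-weighted hazard likelihood (population × H)."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError("exposure array shape does not match grid shape")
        if (self.values < 0).any():
            raise ValueError("exposure values must be non-negative")


def cell_exposure(pop: Raster, weights: HazardWeightGrid) -> ExposureGrid:
    """Elementwise population × H; nodata population contributes zero."""
    if not pop.spec.same_geometry(weights.spec):
        raise ValueError("population and weight grids differ")
    return ExposureGrid(pop.spec, pop.filled(0.0) * weights.weights)


def multi_hazard(
    cyc: ExposureGrid, dro: ExposureGrid, flo: ExposureGrid
) -> ExposureGrid:
    """Equally-weighted sum of the three single-hazard exposure grids."""
    if not (cyc.spec.same_geometry(dro.spec) and cyc.spec.same_geometry(flo.spec)):
        raise ValueError("exposure grids differ in geometry")
    return ExposureGrid(cyc.spec, cyc.values + dro.values + flo.values)


def country_exposure(
    e: ExposureGrid,
    pop: Raster,
    zones: ZoneMap,
    stratum_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Average population exposure per country over an optional stratum.

    Returns a frame with columns ``country_id, score, population``; a
    country whose stratum holds no population gets score NaN (missing).
    """
    if not (e.spec.same_geometry(pop.spec) and e.spec.same_geometry(zones.spec)):
        raise ValueError("exposure, population and zone grids differ")
    evals = e.values
    pvals = pop.filled(0.0)
    if stratum_mask is not None:
        stratum_mask = np.asarray(stratum_mask, dtype=bool)
        evals = np.where(stratum_mask, evals, 0.0)
        pvals = np.where(stratum_mask, pvals, 0.0)
    num = zonal_sum(Raster(e.spec, evals), zones)
    den = zonal_sum(Raster(pop.spec, pvals), zones)
    rows = []
    for country in zones.countries():
        p = den.get(country, 0.0)
        if p > 0:
            score = num.get(country, 0.0) / p
        else:
            warnings.warn(
                f"country {country} has no population in this stratum; "
                "score reported missing",
                stacklevel=2,
            )
            score = np.nan
        rows.append({"country_id": country, "score": score, "population": p})
    return pd.DataFrame(rows, columns=["country_id", "score", "population"])


def build_exposure_table(
    weights: Mapping[str, HazardWeightGrid],
    pop: Raster,
    zones: ZoneMap,
    urban_mask: UrbanRuralMask,
) -> pd.DataFrame:
    """Full country × hazard × stratum table (long format).

    ``weights`` maps each of cyclone/drought/flood to its weight grid on
    the population spec; the multi-hazard rows are derived by summation.
    """
    missing = set(HAZARDS) - set(weights)
    if missing:
        raise ValueError(f"missing weight grids for: {sorted(missing)}")
    grids = {h: cell_exposure(pop, weights[h]) for h in HAZARDS}
    grids["multi"] = multi_hazard(*(grids[h] for h in HAZARDS))
    strata_masks = {
        "total": None,
        "urban": urban_mask.stratum_mask("urban"),
        "rural": urban_mask.stratum_mask("rural"),
    }
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty strata surface as NaN rows
        for hazard in ALL_HAZARDS:
            for stratum, mask in strata_masks.items():
                df = country_exposure(grids[hazard], pop, zones, mask)
                df.insert(1, "hazard", hazard)
                df.insert(2, "stratum", stratum)
                frames.append(df)
    return pd.concat(frames, ignore_index=True)


def hdi_class_average(
    table: pd.DataFrame, hdi: Mapping[int, str]
) -> pd.DataFrame:
    """Person-weighted average score per HDI class (plus a Global row)
    for every hazard × stratum present in the table.

    Countries absent from ``hdi`` contribute to the Global row only;
    countries with a missing score are excluded from both.
    """
    bad = {c for c in set(hdi.values()) if c not in HDI_CLASSES}
    if bad:
        raise ValueError(f"unknown HDI classes: {sorted(bad)}")
    rows = []
    for (hazard, stratum), grp in table.groupby(["hazard", "stratum"], sort=False):
        scored = grp.dropna(subset=["score"])
        scored = scored[scored["population"] > 0]
        groups: dict[str, pd.DataFrame] = {"Global": scored}
        for cls in HDI_CLASSES:
            members = [c for c, k in hdi.items() if k == cls]
            groups[cls] = scored[scored["country_id"].isin(members)]
        for cls, sub in groups.items():
            if len(sub) == 0:
                avg = np.nan
            else:
                avg = float(
                    (sub["score"] * sub["population"]).sum()
                    / sub["population"].sum()
                )
            rows.append(
                {"hazard": hazard, "stratum": stratum,
                 "hdi_class": cls, "score": avg}
            )
    return pd.DataFrame(rows, columns=["hazard", "stratum", "hdi_class", "score"])


def relative_difference(value: float, reference: float) -> float:
    """Percent difference of a score from a reference score."""
    if reference == 0:
        return float("nan")
    return 100.0 * (value - reference) / reference
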