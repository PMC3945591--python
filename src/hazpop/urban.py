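"""Urban/rural classification via a per-country population threshold.

For each country the populated cells are sorted by population (descending)
and the shortest prefix whose cumulative population best matches the
national urban proportion is labeled urban; everything else zoned is rural.
The reported "threshold" is the smallest population among selected cells,
so equal-valued boundary cells cannot make the target share unattainable.
Uninhabited cells are never urban.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .raster import GridSpec, Raster, ZoneMap

URBAN = 1
RURAL = 0
UNZONED = -1


@dataclass
class UrbanRuralMask:
    """Per-cell label (1=urban, 0=rural, -1 outside any country) plus the
    per-country threshold bookkeeping."""

    spec: GridSpec
    labels: np.ndarray
    thresholds: dict[int, tuple[float, float]] = field(default_factory=dict)
    # country id -> (threshold population, achieved urban share)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != self.spec.shape:
            raise ValueError("label array shape does not match grid shape")
        bad = set(np.unique(self.labels)) - {URBAN, RURAL, UNZONED}
        if bad:
            raise ValueError(f"unexpected labels: {sorted(bad)}")

    def stratum_mask(self, stratum: str) -> np.ndarray:
        if stratum == "urban":
            return self.labels == URBAN
        if stratum == "rural":
            return self.labels == RURAL
        raise ValueError(f"unknown stratum {stratum!r}")


def urban_threshold(
    cell_pops: Sequence[float], fraction: float
) -> tuple[float, set[int], float]:
    """Pick the urban cell set for one country.

    Returns ``(threshold, selected_indices, achieved_share)`` where the
    selected set is the prefix (by population descending, original index
    ascending) whose cumulative population is closest to
    ``fraction × total``; ties prefer fewer cells.  ``threshold`` is the
    population of the last selected cell, or +inf when nothing qualifies.
    """
    pops = np.asarray(cell_pops, dtype=float)
    if (pops < 0).any():
        raise ValueError("cell populations must be non-negative")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("urban fraction must lie in [0, 1]")
    total = float(pops.sum())
    if total == 0.0:
        if fraction > 0.0:
            warnings.warn(
                "country has zero population but a positive urban fraction",
                stacklevel=2,
            )
        return math.inf, set(), 0.0

    populated = np.nonzero(pops > 0)[0]
    order = populated[np.lexsort((populated, -pops[populated]))]
    cum = np.concatenate([[0.0], np.cumsum(pops[order])])
    target = fraction * total
    k_star = int(np.argmin(np.abs(cum - target)))  # argmin takes first tie
    selected = set(int(i) for i in order[:k_star])
    threshold = float(pops[order[k_star - 1]]) if k_star > 0 else math.inf
    achieved = float(cum[k_star] / total)
    return threshold, selected, achieved


def classify_urban_rural(
    pop: Raster, zones: ZoneMap, fractions: Mapping[int, float]
) -> UrbanRuralMask:
    """Label every zoned cell urban or rural, country by country."""
    if not pop.spec.same_geometry(zones.spec):
        raise ValueError("population raster and zone map have different grids")
    labels = np.full(pop.spec.shape, UNZONED, dtype=np.int64)
    thresholds: dict[int, tuple[float, float]] = {}
    pop_vals = pop.filled(0.0)
    for country in zones.countries():
        if country not in fractions:
            name = zones.legend.get(country, str(country))
            raise KeyError(f"no urban fraction for country {name!r} (id {country})")
        cells = np.nonzero(zones.zone_ids == country)
        cell_pops = pop_vals[cells]
        threshold, selected, achieved = urban_threshold(
            cell_pops, fractions[country]
        )
        country_labels = np.full(cell_pops.shape, RURAL, dtype=np.int64)
        if selected:
            country_labels[list(selected)] = URBAN
        labels[cells] = country_labels
        thresholds[country] = (threshold, achieved)
    return UrbanRuralMask(pop.spec, labels, thresholds)
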