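"""Country ranking with shared ("competition") ranks and quintile classes.

Ranks descend by score; a group of tied countries shares the rank
1 + (number of countries with a strictly greater score), so the block of
zero-exposure countries always lands at (number of positive scores) + 1.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exposure import ALL_HAZARDS, STRATA


def rank_countries(scores: Mapping[int, float]) -> pd.DataFrame:
    """Competition ranks, descending by score.

    Missing (NaN) scores are excluded.  Returns columns
    ``country_id, score, rank`` sorted by (rank, country_id).
    """
    items = [(c, s) for c, s in scores.items() if not pd.isna(s)]
    if not items:
        return pd.DataFrame(columns=["country_id", "score", "rank"])
    ids = np.array([c for c, _ in items])
    vals = np.array([s for _, s in items], dtype=float)
    ranks = 1 + (vals[None, :] > vals[:, None]).sum(axis=1)
    df = pd.DataFrame({"country_id": ids, "score": vals, "rank": ranks})
    return df.sort_values(["rank", "country_id"], ignore_index=True)


def quintile_classes(ranked: pd.DataFrame) -> pd.DataFrame:
    """Attach a display class 1-5 splitting countries into five near-equal
    groups by rank order; tied ranks share the class of the tie group's
    first position."""
    n = len(ranked)
    out = ranked.sort_values(["rank", "country_id"], ignore_index=True)
    if n == 0:
        out["quintile"] = pd.Series(dtype=int)
        return out
    if n < 5:
        warnings.warn("fewer than 5 countries; all in class 1", stacklevel=2)
        out["quintile"] = 1
        return out
    pos = np.arange(n)
    cls = pos * 5 // n + 1
    # first position of each tied-rank group wins
    ranks = out["rank"].to_numpy()
    first_pos = {}
    for i, r in enumerate(ranks):
        first_pos.setdefault(r, i)
    out["quintile"] = [int(cls[first_pos[r]]) for r in ranks]
    return out


def build_rank_table(exposure_table: pd.DataFrame) -> pd.DataFrame:
    """Ranks + quintiles for every hazard × stratum in an exposure table."""
    frames = []
    for hazard in ALL_HAZARDS:
        for stratum in STRATA:
            sub = exposure_table[
                (exposure_table["hazard"] == hazard)
                & (exposure_table["stratum"] == stratum)
            ]
            scores = dict(zip(sub["country_id"], sub["score"]))
            ranked = quintile_classes(rank_countries(scores))
            ranked.insert(1, "hazard", hazard)
            ranked.insert(2, "stratum", stratum)
            frames.append(ranked)
    return pd.concat(frames, ignore_index=True)


def export_report(
    exposure_table: pd.DataFrame,
    rank_table: pd.DataFrame,
    outdir: str | Path,
) -> list[Path]:
    """Write one CSV per hazard × stratum plus a combined long-format CSV.

    Row order (rank then country id) and float formatting are fixed, so
    re-exporting unchanged tables is byte-identical.  Countries with a
    missing score appear with empty score/rank cells.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    combined = []
    for hazard in ALL_HAZARDS:
        for stratum in STRATA:
            exp = exposure_table[
                (exposure_table["hazard"] == hazard)
                & (exposure_table["stratum"] == stratum)
            ][["country_id", "score", "population"]]
            rk = rank_table[
                (rank_table["hazard"] == hazard)
                & (rank_table["stratum"] == stratum)
            ][["country_id", "rank", "quintile"]]
            merged = exp.merge(rk, on="country_id", how="left")
            merged = merged.sort_values(
                ["rank", "country_id"], na_position="last", ignore_index=True
            )
            merged["rank"] = merged["rank"].astype("Int64")
            merged["quintile"] = merged["quintile"].astype("Int64")
            path = outdir / f"exposure_{hazard}_{stratum}.csv"
            merged.to_csv(path, index=False, float_format="%.10g")
            written.append(path)
            long = merged.copy()
            long.insert(1, "hazard", hazard)
            long.insert(2, "stratum", stratum)
            combined.append(long)
    all_path = outdir / "exposure_all.csv"
    pd.concat(combined, ignore_index=True).to_csv(
        all_path, index=False, float_format="%.10g"
    )
    written.append(all_path)
    return written
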