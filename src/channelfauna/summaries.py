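"""Biodiversity hotspot index and strandings summaries.

The hotspot index works on a coarse grid: each of the five megafauna umbrella
groups is rasterized to binary presence (a cell scores 1 when at least one
sighting of the guild falls in it), and the five binary grids are summed, so
cells score 0 (no group present) through 5 (all groups present).

Strandings are summarized descriptively — cause composition (anthropogenic /
non-anthropogenic / unknown), live-versus-dead trends by year, and family ×
season × zone cross-tabulations. Trends are explicitly effort-uncorrected:
strandings archives carry no observer-effort measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, RasterLayer
from .records import GUILDS

logger = logging.getLogger(__name__)

__all__ = [
    "guild_presence_raster",
    "biodiversity_index",
    "classify_cause",
    "strandings_summary",
    "StrandingSummary",
    "ANTHROPOGENIC_CAUSES",
    "NON_ANTHROPOGENIC_CAUSES",
]

ANTHROPOGENIC_CAUSES = ("bycatch", "entanglement", "ship strike", "direct killing")
NON_ANTHROPOGENIC_CAUSES = (
    "disease", "poor condition", "starvation", "physical trauma",
)


def guild_presence_raster(
    sightings: pd.DataFrame, guild: str, coarse: GridSpec
) -> RasterLayer:
    """Binary presence of one umbrella group on the coarse grid.

    Cell membership uses the grid's half-open cells, so a record on a cell
    boundary lands in exactly one cell; out-of-grid records are ignored.
    """
    vals = np.zeros(coarse.shape)
    sub = sightings[sightings["guild"] == guild]
    for x, y in zip(sub["x"], sub["y"]):
        try:
            r, c = coarse.cell_of(float(x), float(y))
        except ValueError:
            continue
        vals[r, c] = 1.0
    return RasterLayer(spec=coarse, name=f"guild_{guild}", values=vals)


def biodiversity_index(guild_rasters: dict[str, RasterLayer]) -> RasterLayer:
    """Cellwise sum of the five binary guild rasters (0 = none, 5 = all)."""
    specs = {g: r.spec for g, r in guild_rasters.items()}
    first = next(iter(specs.values()))
    if any(s != first for s in specs.values()):
        raise ValueError("guild rasters do not share one GridSpec")
    total = np.zeros(first.shape)
    for r in guild_rasters.values():
        total = total + r.values
    return RasterLayer(spec=first, name="biodiversity_index", values=total)


def classify_cause(cause) -> str:
    """Map a free-text stranding cause to its category.

    Case-insensitive substring-free vocabulary match; "poor condition/
    starvation" style compounds match through their parts; anything
    unrecognized (including blank) is "unknown".
    """
    text = str(cause).strip().lower() if cause is not None else ""
    if text in ("", "nan", "none"):
        return "unknown"
    for word in ANTHROPOGENIC_CAUSES:
        if word in text or text in word:
            return "anthropogenic"
    for word in NON_ANTHROPOGENIC_CAUSES:
        if word in text or text in word:
            return "non-anthropogenic"
    return "unknown"


@dataclass
class StrandingSummary:
    """Composition and trend tables for a strandings database."""

    n_total: int
    cause_counts: dict[str, int]
    yearly: pd.DataFrame  # index year; columns n, n_alive, live_proportion
    family_season_zone: pd.DataFrame  # cross-tab with count column
    notes: dict = field(default_factory=dict)

    @property
    def cause_proportions(self) -> dict[str, float]:
        return {k: v / self.n_total for k, v in self.cause_counts.items()}


def strandings_summary(strandings: pd.DataFrame) -> StrandingSummary:
    """Effort-uncorrected composition and trend summary of strandings.

    Records missing a parseable year are excluded from the yearly trend table
    only (logged), never from composition counts.
    """
    df = strandings.copy()
    n = len(df)
    cats = df["cause"].map(classify_cause)
    cause_counts = {
        c: int((cats == c).sum())
        for c in ("anthropogenic", "non-anthropogenic", "unknown")
    }
    assert sum(cause_counts.values()) == n

    years = pd.to_datetime(df["date"], errors="coerce", format="mixed").dt.year
    missing = years.isna()
    if missing.any():
        logger.info("%d strandings lack a year; excluded from trends", missing.sum())
    trend = df[~missing].copy()
    trend["year"] = years[~missing].astype(int)
    trend["alive"] = trend["condition"].astype(str).str.lower() == "alive"
    yearly = trend.groupby("year").agg(
        n=("alive", "size"), n_alive=("alive", "sum")
    )
    yearly["live_proportion"] = yearly["n_alive"] / yearly["n"]

    df["season"] = df.get("season", pd.Series("", index=df.index)).fillna("")
    df["zone"] = df.get("zone", pd.Series("", index=df.index)).fillna("unassigned")
    xtab = (
        df.groupby(["family", "season", "zone"]).size().rename("count").reset_index()
    )
    assert xtab["count"].sum() == n
    return StrandingSummary(
        n_total=n,
        cause_counts=cause_counts,
        yearly=yearly,
        family_season_zone=xtab,
        notes={"effort_corrected": False},
    )
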