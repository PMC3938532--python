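"""Occurrence-record ingestion: QC, seasonal pooling, database splitting, zones.

Records travel as pandas DataFrames with the columns listed in
:data:`RECORD_COLUMNS`. Dates are ISO-8601; coordinates are planar; ``guild``
is one of the five megafauna umbrella groups; ``record_type`` separates at-sea
sightings from shore strandings.

The QC rules are the standard ones for opportunistic marine sightings archives:
drop records observed in Beaufort sea state above 3 (detection collapses in
rough seas), records not identified at least to taxonomic family, records
outside the study bounds, and records whose date or coordinates do not parse.
Missing sea state is kept — strandings and many archives never record it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

logger = logging.getLogger(__name__)

GUILDS = (
    "large pelagic fishes",
    "cetaceans",
    "pelagic seabirds",
    "marine turtles",
    "pinnipeds",
)

RECORD_COLUMNS = [
    "species",
    "family",
    "guild",
    "date",
    "x",
    "y",
    "record_type",
    "condition",
    "sea_state",
    "cause",
    "taxon_rank",
    "zone",
]

#: month -> season label; three calendar months per season, winter wraps the year
SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}

SEASONS = ("spring", "summer", "autumn", "winter")
SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


def assign_season(date) -> str:
    """Season label for a date (spring=MAM, summer=JJA, autumn=SON, winter=DJF)."""
    ts = pd.Timestamp(date)
    return SEASON_OF_MONTH[ts.month]


@dataclass
class StudyBounds:
    """Closed rectangle; on-edge points count as inside."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def contains(self, x: float, y: float) -> bool:
        return (self.x_min <= x <= self.x_max) and (self.y_min <= y <= self.y_max)


def qc_filter(
    records: pd.DataFrame, bounds: StudyBounds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-control a record table.

    Returns ``(kept, rejected)``; ``rejected`` carries a ``reason`` column with
    one reason per dropped record (first failing rule wins, checked in order:
    date, coordinates, sea state, family, bounds). Every input row lands in
    exactly one of the two outputs.
    """
    df = records.copy().reset_index(drop=True)
    reasons = pd.Series("", index=df.index, dtype=object)

    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    reasons[dates.isna()] = "unparseable date"

    xs = pd.to_numeric(df["x"], errors="coerce")
    ys = pd.to_numeric(df["y"], errors="coerce")
    bad_coord = (xs.isna() | ys.isna()) & (reasons == "")
    reasons[bad_coord] = "unparseable coordinates"

    sea = pd.to_numeric(df.get("sea_state"), errors="coerce")
    bad_sea = (sea > 3) & (reasons == "")
    reasons[bad_sea] = "sea state >3"

    fam = df["family"].fillna("").astype(str).str.strip()
    bad_fam = (fam == "") & (reasons == "")
    reasons[bad_fam] = "not identified to family"

    ok_so_far = reasons == ""
    inside = pd.Series(False, index=df.index)
    valid_xy = ~(xs.isna() | ys.isna())
    inside[valid_xy] = [
        bounds.contains(x, y) for x, y in zip(xs[valid_xy], ys[valid_xy])
    ]
    reasons[ok_so_far & ~inside] = "outside study area"

    kept = df[reasons == ""].copy()
    kept["date"] = dates[reasons == ""]
    kept["season"] = kept["date"].map(assign_season)
    rejected = df[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]
    logger.info("qc_filter kept %d / %d records", len(kept), len(df))
    return kept.reset_index(drop=True), rejected.reset_index(drop=True)


def split_databases(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition QC'd records into the sightings and strandings databases."""
    rt = records["record_type"].astype(str)
    unknown = ~rt.isin(["sighting", "stranding"])
    if unknown.any():
        logger.warning("dropping %d records with unknown record_type", unknown.sum())
    sightings = records[rt == "sighting"].reset_index(drop=True)
    strandings = records[rt == "stranding"].reset_index(drop=True)
    return sightings, strandings


def load_zones(path: str | Path) -> list[tuple[str, object]]:
    """Load zone polygons from GeoJSON as an ordered [(label, polygon)] list.

    Order in the file is the tie-break order for boundary points.
    """
    with open(path) as fh:
        gj = json.load(fh)
    zones = []
    for feat in gj["features"]:
        label = feat["properties"]["name"]
        zones.append((label, shape(feat["geometry"])))
    return zones


def assign_zone(records: pd.DataFrame, zones: list[tuple[str, object]]) -> pd.DataFrame:
    """Label each record with its zone (first zone whose polygon covers it).

    Points in no zone get "unassigned" with a warning. Boundary points go to
    the first matching zone, so the labelling is deterministic.
    """
    out = records.copy()
    labels = []
    n_missing = 0
    for x, y in zip(out["x"], out["y"]):
        pt = Point(float(x), float(y))
        for label, poly in zones:
            # covers() counts the boundary as inside, unlike contains()
            if poly.covers(pt):
                labels.append(label)
                break
        else:
            labels.append("unassigned")
            n_missing += 1
    if n_missing:
        logger.warning("%d records fall in no zone polygon", n_missing)
    out["zone"] = labels
    return out


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Read an occurrence-record CSV, tolerating absent optional columns."""
    df = pd.read_csv(path, dtype={"cause": str, "zone": str})
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df


def write_records_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
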