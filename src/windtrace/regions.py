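"""Endpoint attribution to named regions and seasonal percentage tables.

Trajectory endpoints (landing points for forward runs, take-off points for
backward runs) are assigned to country/province polygons, then tabulated as
per-(direction, season) counts and percentages — the shape used to report
which countries act as sources and sinks for the migrating population.

Containment uses closed polygons: a point on a boundary belongs to the
first region in priority order that covers it; anything outside all
polygons falls into the implicit catch-all region ``other``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date as _date
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence
import warnings

import pandas as pd
from shapely.geometry import Point, box, mapping, shape
from shapely.validation import make_valid

__all__ = [
    "RegionSet",
    "AttributionTable",
    "load_regions",
    "classify",
    "attribute",
    "aggregate",
    "season_of",
    "demo_regions",
    "write_regions_geojson",
    "OTHER",
]

OTHER = "other"


def season_of(d: _date) -> str:
    """Map a release date to the study's migration periods.

    April–May is the spring migration period, October–December the autumn
    one (the k=4 optimal segmentation of the monthly catches); everything
    else is the transition period.
    """
    if d.month in (4, 5):
        return "spring"
    if d.month in (10, 11, 12):
        return "autumn"
    return "transition"


@dataclass
class RegionSet:
    """Named polygons with an explicit priority order."""

    names: list[str]
    geoms: dict[str, object] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("region names must be unique")
        missing = [n for n in self.names if n not in self.geoms]
        if missing:
            raise ValueError(f"regions without geometry: {missing}")

    def __len__(self) -> int:
        return len(self.names)

    def classify(self, lat: float, lon: float) -> str:
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise ValueError("coordinates must be finite")
        pt = Point(lon, lat)
        for name in self.names:
            if self.geoms[name].covers(pt):
                return name
        return OTHER


def classify(lat: float, lon: float, regions: RegionSet) -> str:
    """Name of the first priority-ordered region containing (lat, lon)."""
    return regions.classify(lat, lon)


def load_regions(path, priority_order: Sequence[str] | None = None) -> RegionSet:
    """Read a GeoJSON FeatureCollection with ``name`` properties.

    Multi-part countries become one region (union membership).  Invalid
    geometries are repaired with ``make_valid``; irreparable ones are
    rejected.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    geoms: dict[str, object] = {}
    names: list[str] = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        name = props.get("name")
        if not name:
            raise ValueError(f"{path}: feature missing a 'name' property")
        if name in geoms:
            raise ValueError(f"{path}: duplicate region name {name!r}")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
            if not geom.is_valid:
                raise ValueError(f"{path}: invalid geometry for region {name!r}")
        geoms[name] = geom
        names.append(name)
    if priority_order is not None:
        unknown = set(priority_order) - set(names)
        if unknown:
            raise ValueError(f"priority_order names not in file: {sorted(unknown)}")
        rest = [n for n in names if n not in set(priority_order)]
        names = list(priority_order) + rest
    return RegionSet(names=names, geoms=geoms)


# -- attribution tables ----------------------------------------------------


def _round1(x: float) -> float:
    """Round half-up to one decimal (presentation convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class AttributionTable:
    """Counts and percentages of points per region and (direction, season)."""

    counts: pd.DataFrame       # rows: regions (+ other), cols: MultiIndex
    percentages: pd.DataFrame  # same shape, percent rounded to 1 decimal
    point_mode: str = "endpoints"

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_markdown(self) -> str:
        cols = ["/".join(map(str, c)) for c in self.percentages.columns]
        lines = ["| region | " + " | ".join(cols) + " |",
                 "|---" * (len(cols) + 1) + "|"]
        for name, row in self.percentages.iterrows():
            vals = " | ".join(f"{v:.1f}" for v in row)
            lines.append(f"| {name} | {vals} |")
        return "\n".join(lines)


def attribute(
    endpoints: pd.DataFrame,
    regions: RegionSet,
    group_keys: Sequence[str] = ("direction", "season"),
    point_mode: str = "endpoints",
) -> AttributionTable:
    """Tabulate labelled points into a per-group count/percentage table.

    ``endpoints`` needs columns lat, lon plus the group keys.  Groups with
    no points are omitted with a warning.  Percent = 100 * count / group
    total, rounded half-up to one decimal.
    """
    required = {"lat", "lon", *group_keys}
    missing = required - set(endpoints.columns)
    if missing:
        raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
    if endpoints.empty:
        warnings.warn("no endpoints to attribute; empty table", stacklevel=2)

    df = endpoints.copy()
    df["region"] = [
        regions.classify(la, lo) for la, lo in zip(df["lat"], df["lon"])
    ]
    row_order = regions.names + [OTHER]
    cols = {}
    for key, grp in sorted(df.groupby(list(group_keys)), key=lambda kv: kv[0]):
        counts = grp["region"].value_counts().reindex(row_order, fill_value=0)
        cols[key if isinstance(key, tuple) else (key,)] = counts
    counts_df = pd.DataFrame(cols)
    counts_df.columns = pd.MultiIndex.from_tuples(counts_df.columns,
                                                 names=list(group_keys))
    totals = counts_df.sum(axis=0)
    pct = counts_df.astype(float)
    for c in pct.columns:
        pct[c] = [_round1(100.0 * v / totals[c]) for v in counts_df[c]]
    # drop the catch-all row when nothing landed there
    if (counts_df.loc[OTHER] == 0).all():
        counts_df = counts_df.drop(index=OTHER)
        pct = pct.drop(index=OTHER)
    return AttributionTable(counts=counts_df, percentages=pct,
                            point_mode=point_mode)


def aggregate(
    table: AttributionTable, region_groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Sum member-region percentages into named groups, per column.

    Group shares are sums of the already-rounded per-region percentages,
    matching how derived shares are quoted from a printed table.
    """
    known = set(table.percentages.index)
    for gname, members in region_groups.items():
        unknown = set(members) - known
        if unknown:
            raise ValueError(
                f"group {gname!r} references unknown regions: {sorted(unknown)}"
            )
    rows = {
        gname: table.percentages.loc[list(members)].sum(axis=0)
        for gname, members in region_groups.items()
    }
    return pd.DataFrame(rows).T


# -- fixture geometry ------------------------------------------------------

#: Simplified, disjoint rectangles standing in for the four countries around
#: the study site.  SYNTHETIC — not real national borders; real analyses
#: must supply their own boundary GeoJSON.
_DEMO_BOXES = {
    "Bangladesh": (88.0, 20.5, 92.7, 26.5),   # lon_min, lat_min, lon_max, lat_max
    "India": (92.7, 21.0, 94.5, 29.0),
    "Myanmar": (94.5, 18.0, 97.6, 28.0),
    "China": (97.6, 20.0, 106.0, 30.0),
}


def demo_regions() -> RegionSet:
    """Four synthetic rectangles labelled China/Myanmar/India/Bangladesh."""
    names = ["China", "Myanmar", "India", "Bangladesh"]
    geoms = {n: box(*_DEMO_BOXES[n]) for n in names}
    return RegionSet(names=names, geoms=geoms)


def write_regions_geojson(regions: RegionSet, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"name": n},
            "geometry": mapping(regions.geoms[n]),
        }
        for n in regions.names
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
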