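"""Species hotspot rasterization and exposure tables.

Hotspot polygons (high-density distribution areas, one or more polygons
per species, optionally split by season) are overlaid on the analysis
grid. A grid cell belongs to a species when the polygon overlaps the cell
with positive area; coastal mixed cells are routed to both the sea-role
and the land-role mask, matching how mixed pixels are treated per event
type. From the masks, the module builds per-species exposure tables:

* mean exposure -- mean metric value per event type inside the hotspot,
  summed across event types into a cumulative value, normalised across
  species by the group maximum (per metric and environment), with the
  relative contribution of each event type;
* trend exposure -- mean positive-and-significant slope per event type,
  divided by the TOTAL number of hotspot cells in that environment role
  (so species whose hotspot is barely touched by increasing trends score
  low), plus the percentage of hotspot cells covered by such trends.

A species whose polygons are too small to overlap any land-role cell
(an island below the grid resolution) gets missing land rows; a species
whose hotspot holds no retained trend cell gets a zero cumulative trend.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grid import EVENT_ENVIRONMENT, GridDef, MetricLayer, canonical_type_order
from .trends import TrendLayer

logger = logging.getLogger(__name__)


@dataclass
class Hotspot:
    """One species' (merged) hotspot polygon with pass-through labels."""

    species: str
    geometry: BaseGeometry
    iucn: str | None = None
    season: str | None = None


@dataclass
class HotspotSet:
    """Validated collection of hotspots with unique species names.

    Invalid geometries are repaired with :func:`shapely.make_valid`;
    unrepairable ones are rejected naming the species.
    """

    hotspots: list[Hotspot]

    def __post_init__(self) -> None:
        names = [h.species for h in self.hotspots]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        for h in self.hotspots:
            if h.geometry.is_empty:
                raise ValueError(f"empty hotspot geometry for species {h.species!r}")
            if not h.geometry.is_valid:
                repaired = shapely.make_valid(h.geometry)
                if not repaired.is_valid or repaired.is_empty:
                    raise ValueError(
                        f"unrepairable hotspot geometry for species {h.species!r}"
                    )
                h.geometry = repaired

    @property
    def species_names(self) -> list[str]:
        return [h.species for h in self.hotspots]

    def __iter__(self):
        return iter(self.hotspots)

    def __len__(self) -> int:
        return len(self.hotspots)


def read_hotspots_geojson(path) -> HotspotSet:
    """Read a GeoJSON FeatureCollection with a ``species`` property.

    Features sharing a species (e.g. breeding and non-breeding season
    polygons) are merged into one year-round hotspot.
    """
    with open(path) as fh:
        collection = json.load(fh)
    by_species: dict[str, list[BaseGeometry]] = {}
    meta: dict[str, dict] = {}
    for feat in collection.get("features", []):
        props = feat.get("properties") or {}
        if "species" not in props:
            raise ValueError("GeoJSON feature missing required 'species' property")
        name = props["species"]
        by_species.setdefault(name, []).append(shape(feat["geometry"]))
        meta.setdefault(name, {})
        if props.get("iucn"):
            meta[name]["iucn"] = props["iucn"]
    hotspots = [
        Hotspot(name, unary_union(geoms), iucn=meta[name].get("iucn"))
        for name, geoms in by_species.items()
    ]
    return HotspotSet(hotspots)


def write_hotspots_geojson(hotspots: HotspotSet, path) -> None:
    features = []
    for h in hotspots:
        props = {"species": h.species}
        if h.iucn is not None:
            props["iucn"] = h.iucn
        if h.season is not None:
            props["season"] = h.season
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(h.geometry)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)


def rasterize_hotspots(
    hotspots: HotspotSet, grid: GridDef, rule: str = "intersects"
) -> dict[str, dict[str, np.ndarray]]:
    """Per-species boolean cell masks, split into sea-role and land-role.

    ``rule="intersects"`` (default): a cell belongs to the species when the
    polygon overlaps it with positive area (boundary contact alone does not
    count, so a polygon exactly covering one cell selects only that cell).
    ``rule="center"``: the cell centre must lie inside the polygon.
    The sea-role mask keeps cells classed sea or mixed, the land-role mask
    cells classed land or mixed.
    """
    if rule not in ("intersects", "center"):
        raise ValueError(f"unknown membership rule {rule!r}")
    lon_c, lat_c = np.meshgrid(grid.lon_centers, grid.lat_centers)
    half = grid.cell_size / 2.0
    boxes = shapely.box(lon_c - half, lat_c - half, lon_c + half, lat_c + half)

    sea_role = grid.role_mask("sea")
    land_role = grid.role_mask("land")
    masks: dict[str, dict[str, np.ndarray]] = {}
    for h in hotspots:
        if rule == "center":
            hit = shapely.contains_xy(h.geometry, lon_c, lat_c)
        else:
            candidate = shapely.intersects(h.geometry, boxes)
            hit = np.zeros(grid.shape, dtype=bool)
            ii, jj = np.nonzero(candidate)
            for i, j in zip(ii, jj):
                # positive-area overlap; boundary touching is excluded
                hit[i, j] = h.geometry.intersection(boxes[i, j]).area > 0.0
        if not hit.any():
            logger.warning("hotspot %s does not overlap the grid", h.species)
        masks[h.species] = {"sea": hit & sea_role, "land": hit & land_role}
    return masks


def _mask_mean(values: np.ndarray, mask: np.ndarray) -> float:
    sel = values[mask]
    sel = sel[np.isfinite(sel)]
    return float(sel.mean()) if sel.size else float("nan")


def species_mean_exposure(
    layers: list[MetricLayer],
    masks: dict[str, dict[str, np.ndarray]],
    hotspots: HotspotSet | None = None,
) -> pd.DataFrame:
    """Mean-exposure table: one row per species x environment x event type
    x metric, with the hotspot mean, the cumulative sum across event types
    and each type's relative contribution.

    An empty environment-role mask yields missing (NaN) rows for that
    species and environment.
    """
    iucn = {h.species: h.iucn for h in hotspots} if hotspots is not None else {}
    rows = []
    for layer in layers:
        env = EVENT_ENVIRONMENT[layer.event_type]
        for species, role_masks in masks.items():
            mask = role_masks[env]
            if not mask.any():
                logger.info(
                    "species %s has no %s-role cells; reporting missing", species, env
                )
                mean = float("nan")
            else:
                mean = _mask_mean(layer.values, mask)
            rows.append(
                {
                    "species": species,
                    "iucn": iucn.get(species),
                    "environment": env,
                    "event_type": layer.event_type,
                    "metric": layer.metric,
                    "mean_value": mean,
                    "n_cells": int(mask.sum()),
                }
            )
    table = pd.DataFrame(rows)
    grp = table.groupby(["species", "environment", "metric"])["mean_value"]
    table["cumulative"] = grp.transform(lambda s: s.sum() if s.notna().any() else np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        table["contribution"] = np.where(
            table["cumulative"] > 0, table["mean_value"] / table["cumulative"], np.nan
        )
    return table.sort_values(
        ["environment", "metric", "species", "event_type"], ignore_index=True
    )


def normalize_species(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each species' cumulative value by the maximum across species
    within its metric x environment group, yielding values in (0, 1] with
    the most exposed species at 1."""
    out = table.copy()
    out["normalized"] = np.nan
    for (env, metric), idx in out.groupby(["environment", "metric"]).groups.items():
        cum = out.loc[idx, "cumulative"]
        finite = cum[np.isfinite(cum)]
        if finite.empty:
            logger.info("no finite cumulative values for %s/%s; group skipped", env, metric)
            continue
        out.loc[idx, "normalized"] = cum / finite.max()
    return out


def species_trend_exposure(
    trend_layers: list[TrendLayer],
    masks: dict[str, dict[str, np.ndarray]],
    hotspots: HotspotSet | None = None,
) -> pd.DataFrame:
    """Trend-exposure table from positive-and-significant trend layers.

    Per species x environment x event type x metric: the mean retained
    slope inside the hotspot, the pixel-count-adjusted mean (divided by
    the TOTAL number of hotspot cells in that environment role; zero when
    no cell is retained), per-type and union coverage percentages, the
    cumulative adjusted trend and relative contributions.
    """
    for tl in trend_layers:
        if not tl.filtered:
            raise ValueError("trend layers must be filtered (positive and significant)")
    iucn = {h.species: h.iucn for h in hotspots} if hotspots is not None else {}
    rows = []
    for tl in trend_layers:
        env = EVENT_ENVIRONMENT[tl.event_type]
        retained = np.isfinite(tl.slope)
        for species, role_masks in masks.items():
            mask = role_masks[env]
            n_total = int(mask.sum())
            if n_total == 0:
                logger.info(
                    "species %s has no %s-role cells; reporting missing", species, env
                )
                rows.append(
                    {
                        "species": species,
                        "iucn": iucn.get(species),
                        "environment": env,
                        "event_type": tl.event_type,
                        "metric": tl.metric,
                        "mean_slope": np.nan,
                        "adjusted_mean": np.nan,
                        "coverage_pct": np.nan,
                        "n_cells": 0,
                        "n_retained": 0,
                    }
                )
                continue
            ret = mask & retained
            n_ret = int(ret.sum())
            mean_slope = float(tl.slope[ret].mean()) if n_ret else 0.0
            rows.append(
                {
                    "species": species,
                    "iucn": iucn.get(species),
                    "environment": env,
                    "event_type": tl.event_type,
                    "metric": tl.metric,
                    "mean_slope": mean_slope,
                    "adjusted_mean": mean_slope / n_total,
                    "coverage_pct": 100.0 * n_ret / n_total,
                    "n_cells": n_total,
                    "n_retained": n_ret,
                }
            )
    table = pd.DataFrame(rows)

    # union coverage: cells retained in >= 1 event type, per species/env/metric
    union_cov = {}
    by_env_metric: dict[tuple[str, str], list[TrendLayer]] = {}
    for tl in trend_layers:
        by_env_metric.setdefault((EVENT_ENVIRONMENT[tl.event_type], tl.metric), []).append(tl)
    for (env, metric), tls in by_env_metric.items():
        any_ret = np.zeros(tls[0].grid.shape, dtype=bool)
        for tl in tls:
            any_ret |= np.isfinite(tl.slope)
        for species, role_masks in masks.items():
            mask = role_masks[env]
            n_total = int(mask.sum())
            union_cov[(species, env, metric)] = (
                100.0 * (mask & any_ret).sum() / n_total if n_total else float("nan")
            )
    table["union_coverage_pct"] = [
        union_cov[(r.species, r.environment, r.metric)] for r in table.itertuples()
    ]

    grp = table.groupby(["species", "environment", "metric"])["adjusted_mean"]
    table["cumulative"] = grp.transform(lambda s: s.sum() if s.notna().any() else np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        table["contribution"] = np.where(
            table["cumulative"] > 0, table["adjusted_mean"] / table["cumulative"], np.nan
        )
    # deterministic event-type order within groups
    order = {
        t: k
        for env in ("sea", "land")
        for k, t in enumerate(canonical_type_order(env))
    }
    table["_o"] = table["event_type"].map(order)
    table = table.sort_values(
        ["environment", "metric", "species", "_o"], ignore_index=True
    ).drop(columns="_o")
    return table
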