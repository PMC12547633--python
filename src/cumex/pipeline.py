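"""Config-driven orchestration of the full analysis chain.

``run_pipeline`` takes a :class:`PipelineConfig` and produces, per
environment (sea / land) and metric (intensity / duration / frequency):

* cumulative-mean maps with the per-pixel dominant event type;
* cumulative-trend maps (positive-and-significant slopes only) with the
  per-pixel combination of contributing types and an area-fraction table;
* per-species exposure tables for the means (with max-normalized ranks)
  and for the trends (pixel-count-adjusted, with coverage percentages).

All inputs are either read from files or generated synthetically from
the config; every source of randomness derives from the single config
seed, so a re-run with the same config is byte-identical. Products are
plain NetCDF3 / CSV / GeoJSON files plus a JSON manifest carrying the
config hash, the seed and the package version.

The demo grid places a block of land columns on the west, a mixed
coastal column, and sea to the east; injected episodes with a linear
occurrence trend are placed in the southern half of the domain so that
trend maps and species rankings have known structure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .cumulative import CumulativeLayer, cumulative_mean, minmax_normalize
from .detection import daily_climatology, detect_events, summarize_events
from .exposure import (
    HotspotSet,
    normalize_species,
    rasterize_hotspots,
    read_hotspots_geojson,
    species_mean_exposure,
    species_trend_exposure,
    write_hotspots_geojson,
)
from .grid import (
    ENVIRONMENTS,
    EVENT_ENVIRONMENT,
    EVENT_TYPES,
    EVENT_VARIABLE,
    LAND,
    METRICS,
    MIXED,
    SEA,
    DailyFieldCube,
    GridDef,
    canonical_type_order,
)
from .io_grid import read_cube, wind_speed, write_cube
from .synthetic import (
    EpisodeSpec,
    FieldSpec,
    generate_daily_cube,
    generate_hotspots,
    inject_episodes,
)
from .trends import (
    annual_metrics,
    cumulative_trend,
    filter_positive_significant,
    ols_trend,
    trend_area_fractions,
)

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1

#: Per-variable synthetic parameters: plausible magnitudes in each
#: variable's units (degC, m/s, m/h).
DEFAULT_FIELD_PARAMS: dict[str, dict[str, float]] = {
    "sst": dict(mean_level=15.0, seasonal_amplitude=4.0, noise_sd=0.8,
                ar1_coefficient=0.7, level_trend=0.02),
    "air_temp": dict(mean_level=12.0, seasonal_amplitude=8.0, noise_sd=2.0,
                     ar1_coefficient=0.6, level_trend=0.03),
    "wind_u": dict(mean_level=6.0, seasonal_amplitude=2.0, noise_sd=2.5,
                   ar1_coefficient=0.5, level_trend=0.0),
    "wind_v": dict(mean_level=1.0, seasonal_amplitude=1.0, noise_sd=2.5,
                   ar1_coefficient=0.5, level_trend=0.0),
    "precip": dict(mean_level=0.002, seasonal_amplitude=0.001, noise_sd=0.0015,
                   ar1_coefficient=0.3, level_trend=0.0),
}

_INPUT_VARIABLES = ("sst", "air_temp", "wind_u", "wind_v", "precip")
#: Variables on which events are detected (wind speed is derived).
_DETECTION_VARIABLES = ("sst", "air_temp", "wind_speed", "precip")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration of the whole chain."""

    # analysis grid (synthetic demo grid: west land, mixed seam, east sea)
    nlat: int = 20
    nlon: int = 20
    lat_min: float = -70.0
    lon_min: float = -40.0
    cell_size: float = 1.0
    land_fraction: float = 0.3
    # synthetic record
    years: int = 31
    start_year: int = 1993
    field_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FIELD_PARAMS.items()}
    )
    # optional real inputs (NetCDF per variable); overrides synthesis
    input_paths: dict = field(default_factory=dict)
    # injected episode structure (occurrence trend in the southern half)
    injected_trend_days_per_year: float = 0.5
    injected_base_duration: int = 10
    injected_amplitude_factor: float = 5.0
    # detection
    percentile: float = 90.0
    window_days: int = 11
    smooth_days: int = 31
    min_duration_marine: int = 5
    min_duration_atmospheric: int = 3
    strict_min_duration: bool = False
    intensity_reference: str = "seasonal_mean"
    join_gap: int = 0
    # trends
    alpha: float = 0.05
    min_trend_years: int = 10
    fdr: bool = False
    # stacking
    renormalization: str = "minmax"
    # hotspots
    n_species: int = 4
    hotspot_path: str | None = None
    hotspot_rule: str = "intersects"
    # run
    seed: int = 0
    outdir: str = "cumex_out"

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def make_demo_grid(config: PipelineConfig) -> GridDef:
    """West block of land columns, one mixed coastal column, sea east."""
    n_land = int(round(config.land_fraction * config.nlon))
    n_land = min(n_land, config.nlon - 2)  # keep sea cells for marine events
    cls = np.full((config.nlat, config.nlon), SEA, dtype=object)
    cls[:, :n_land] = LAND
    cls[:, n_land] = MIXED
    return GridDef.regular(
        config.lat_min, config.lon_min, config.nlat, config.nlon,
        config.cell_size, cls,
    )


def _variable_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = list(_INPUT_VARIABLES) + ["episodes", "hotspots"]
    return {name: int(s) for name, s in zip(names, rng.integers(0, _MAX_SEED, len(names)))}


def _injection_block(grid: GridDef, variable: str) -> np.ndarray:
    """Southern-half pixels eligible for episode injection per variable."""
    block = np.zeros(grid.shape, dtype=bool)
    block[: grid.nlat // 2, :] = True
    if variable == "sst":
        block &= grid.role_mask("sea")
    return block


def _inject_occurrence_trend(
    cube: DailyFieldCube, config: PipelineConfig, rng: np.random.Generator
) -> DailyFieldCube:
    """Per eligible pixel, one episode per year whose duration grows by
    the configured rate, at random in-year positions."""
    if config.injected_trend_days_per_year <= 0:
        return cube
    # wind speed is derived; scale its episode amplitude by the u-component noise
    key = "wind_u" if cube.variable_kind == "wind_speed" else cube.variable_kind
    params = config.field_params.get(key, DEFAULT_FIELD_PARAMS.get(key, {}))
    noise_sd = params.get("noise_sd", 1.0)
    amplitude = config.injected_amplitude_factor * noise_sd
    durations = config.injected_base_duration + np.rint(
        config.injected_trend_days_per_year * np.arange(cube.n_years)
    ).astype(int)
    episodes = []
    for i, j in zip(*np.nonzero(_injection_block(cube.grid, cube.variable_kind))):
        for y, d in enumerate(durations):
            start = y * 365 + int(rng.integers(20, 365 - int(d) - 20))
            episodes.append(EpisodeSpec((int(i), int(j)), start, int(d), amplitude))
    return inject_episodes(cube, episodes)


def _build_cubes(config: PipelineConfig, grid: GridDef, seeds: dict) -> dict[str, DailyFieldCube]:
    cubes: dict[str, DailyFieldCube] = {}
    ep_rng = np.random.default_rng(seeds["episodes"])
    for var in _INPUT_VARIABLES:
        if var in config.input_paths:
            cubes[var] = read_cube(config.input_paths[var], var)
            logger.info("read %s from %s", var, config.input_paths[var])
        else:
            params = config.field_params.get(var, DEFAULT_FIELD_PARAMS[var])
            spec = FieldSpec(
                var,
                grid,
                years=config.years,
                seed=seeds[var],
                start_year=config.start_year,
                **params,
            )
            cubes[var] = generate_daily_cube(spec)
    cubes["wind_speed"] = wind_speed(cubes["wind_u"], cubes["wind_v"])
    # injected occurrence trend goes into the detection variables
    for var in _DETECTION_VARIABLES:
        if var not in config.input_paths:
            cubes[var] = _inject_occurrence_trend(cubes[var], config, ep_rng)
    return cubes


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full chain and return the product bundle as a dict.

    When ``outdir`` (or ``config.outdir``) is given, products are also
    written to disk; see :func:`write_products`.
    """
    grid = make_demo_grid(config)
    seeds = _variable_seeds(config.seed)
    products: dict = {"config": config, "grid": grid}

    logger.info("stage simulate: building daily cubes")
    cubes = _build_cubes(config, grid, seeds)
    products["cubes"] = cubes

    if config.hotspot_path:
        hotspots = read_hotspots_geojson(config.hotspot_path)
    else:
        hotspots = generate_hotspots(grid, config.n_species, seeds["hotspots"])
    products["hotspots"] = hotspots

    logger.info("stage detect: climatologies and event catalogs")
    clims = {
        var: daily_climatology(
            cubes[var], config.window_days, config.smooth_days, config.percentile
        )
        for var in _DETECTION_VARIABLES
    }
    catalogs = {}
    for etype in EVENT_TYPES:
        var = EVENT_VARIABLE[etype]
        env = EVENT_ENVIRONMENT[etype]
        min_dur = (
            config.min_duration_marine if etype == "MHW" else config.min_duration_atmospheric
        )
        catalogs[etype] = detect_events(
            cubes[var],
            clims[var],
            etype,
            min_dur,
            strict_min=config.strict_min_duration,
            intensity_reference=config.intensity_reference,
            join_gap=config.join_gap,
            domain_mask=grid.role_mask(env),
        )
        logger.info("detected %d %s events", catalogs[etype].n_events, etype)
    products["climatologies"] = clims
    products["catalogs"] = catalogs

    metric_layers = {
        (etype, metric): layer
        for etype, cat in catalogs.items()
        for metric, layer in summarize_events(cat).items()
    }
    products["metric_layers"] = metric_layers

    logger.info("stage cumulate: cumulative means and dominant types")
    cum_mean: dict[tuple[str, str], CumulativeLayer] = {}
    for env in ENVIRONMENTS:
        mask = grid.role_mask(env)
        for metric in METRICS:
            normed = [
                minmax_normalize(metric_layers[(etype, metric)], mask)
                for etype in canonical_type_order(env)
            ]
            cum_mean[(env, metric)] = cumulative_mean(
                normed, env, renormalization=config.renormalization
            )
    products["cumulative_mean"] = cum_mean

    logger.info("stage trend: per-pixel OLS, filtering, stacking")
    trend_layers = {}
    filtered = {}
    for etype, cat in catalogs.items():
        for metric, series in annual_metrics(cat).items():
            tl = ols_trend(series, config.min_trend_years)
            trend_layers[(etype, metric)] = tl
            filtered[(etype, metric)] = filter_positive_significant(
                tl, config.alpha, fdr=config.fdr
            )
    cum_trend = {}
    fractions = []
    for env in ENVIRONMENTS:
        for metric in METRICS:
            layers = [filtered[(etype, metric)] for etype in canonical_type_order(env)]
            cum_trend[(env, metric)] = cumulative_trend(
                layers, env, renormalization=config.renormalization
            )
            fractions.append(trend_area_fractions(layers, env))
    area_fractions = pd.concat(fractions, ignore_index=True)
    products["trend_layers"] = trend_layers
    products["filtered_trends"] = filtered
    products["cumulative_trend"] = cum_trend
    products["area_fractions"] = area_fractions

    logger.info("stage exposure: hotspot masks and species tables")
    masks = rasterize_hotspots(hotspots, grid, rule=config.hotspot_rule)
    mean_layers = list(metric_layers.values())
    mean_table = normalize_species(species_mean_exposure(mean_layers, masks, hotspots))
    trend_table = species_trend_exposure(list(filtered.values()), masks, hotspots)
    products["masks"] = masks
    products["mean_exposure"] = mean_table
    products["trend_exposure"] = trend_table

    products["manifest"] = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "grid_shape": list(grid.shape),
        "years": config.years,
        "n_species": len(hotspots),
    }

    if outdir is not None:
        write_products(products, Path(outdir))
    return products


# ---------------------------------------------------------------------------
# product serialization

def _layer_dataset(grid: GridDef, data: dict[str, np.ndarray], attrs: dict | None = None):
    ds = xr.Dataset(
        {name: (("lat", "lon"), arr) for name, arr in data.items()},
        coords={
            "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
        },
        attrs=attrs or {},
    )
    return ds


def _combination_codes(layer: CumulativeLayer) -> np.ndarray:
    """Bitmask code of contributing types per pixel; 0 where none."""
    weights = 1 << np.arange(len(layer.event_types))
    return np.tensordot(weights, layer.contributing.astype(int), axes=1).astype(np.int32)


def write_products(products: dict, outdir: str | Path, stages: set[str] | None = None) -> list[str]:
    """Write the product bundle; returns the relative file names written.

    ``stages`` limits output to a subset of
    {"simulate", "detect", "cumulate", "trend", "exposure", "manifest"}.
    Raw daily cubes are written only by the explicit ``simulate`` stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_stages = {"detect", "cumulate", "trend", "exposure", "manifest"}
    stages = all_stages if stages is None else stages
    written: list[str] = []

    def _track(name: str) -> Path:
        written.append(name)
        return outdir / name

    config: PipelineConfig = products["config"]
    grid: GridDef = products["grid"]

    if "simulate" in stages:
        for var, cube in products["cubes"].items():
            write_cube(cube, _track(f"cube_{var}.nc"))
        write_hotspots_geojson(products["hotspots"], _track("hotspots.geojson"))

    if "detect" in stages:
        for etype, cat in products["catalogs"].items():
            cat.to_csv(_track(f"events_{etype}.csv"))
        for etype in EVENT_TYPES:
            data = {
                metric: products["metric_layers"][(etype, metric)].values
                for metric in METRICS
            }
            _layer_dataset(grid, data, {"event_type": etype}).to_netcdf(
                _track(f"metrics_{etype}.nc"), engine="scipy"
            )

    if "cumulate" in stages:
        for (env, metric), layer in products["cumulative_mean"].items():
            ds = _layer_dataset(
                grid,
                {"cumulative": layer.values, "dominant": layer.dominant.astype(np.int32)},
                {"environment": env, "metric": metric},
            )
            ds.to_netcdf(_track(f"cumulative_mean_{env}_{metric}.nc"), engine="scipy")
        legend = pd.DataFrame(
            [
                {"environment": env, "code": k, "event_type": t}
                for env in ENVIRONMENTS
                for k, t in enumerate(canonical_type_order(env))
            ]
        )
        legend.to_csv(_track("dominant_legend.csv"), index=False)

    if "trend" in stages:
        for etype in EVENT_TYPES:
            data = {}
            for metric in METRICS:
                tl = products["trend_layers"][(etype, metric)]
                data[f"slope_{metric}"] = tl.slope
                data[f"p_{metric}"] = tl.p_value
            _layer_dataset(grid, data, {"event_type": etype}).to_netcdf(
                _track(f"trend_{etype}.nc"), engine="scipy"
            )
        combo_rows = []
        for (env, metric), layer in products["cumulative_trend"].items():
            codes = _combination_codes(layer)
            ds = _layer_dataset(
                grid,
                {"cumulative": layer.values, "combination": codes},
                {"environment": env, "metric": metric},
            )
            ds.to_netcdf(_track(f"cumulative_trend_{env}_{metric}.nc"), engine="scipy")
            for code in sorted(np.unique(codes)):
                if code == 0:
                    continue
                types = [
                    t for k, t in enumerate(layer.event_types) if code >> k & 1
                ]
                combo_rows.append(
                    {
                        "environment": env,
                        "metric": metric,
                        "code": int(code),
                        "event_types": "+".join(types),
                    }
                )
        pd.DataFrame(
            combo_rows, columns=["environment", "metric", "code", "event_types"]
        ).to_csv(_track("combination_legend.csv"), index=False)
        products["area_fractions"].to_csv(_track("area_fractions.csv"), index=False)

    if "exposure" in stages:
        products["mean_exposure"].to_csv(_track("species_mean_exposure.csv"), index=False)
        products["trend_exposure"].to_csv(_track("species_trend_exposure.csv"), index=False)
        if "simulate" not in stages:
            write_hotspots_geojson(products["hotspots"], _track("hotspots.geojson"))

    if "manifest" in stages:
        manifest = dict(products["manifest"])
        manifest["products"] = sorted(written)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append("manifest.json")
        config.to_yaml(outdir / "config.yaml")
        written.append("config.yaml")

    logger.info("wrote %d products to %s", len(written), outdir)
    return written
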