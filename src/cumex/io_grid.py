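"""Gridded daily data I/O, regridding, and wind-speed derivation.

Cubes are stored as CF-style NetCDF (dimensions time/lat/lon, a units
attribute per variable, numeric time in days since January 1 of the
start year on a 365-day no-leap calendar). Temperatures stored in kelvin
are converted to degrees Celsius on read; precipitation stays in m/h.
Real-data time axes on the standard calendar have February 29 dropped on
ingestion so that every year has 365 days.

Regridding is bilinear interpolation at the target cell centres, with
missing source cells propagating missing wherever they carry weight --
no extrapolation across the coast. Wind speed is the per-cell, per-day
hypotenuse of the u and v components.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .grid import (
    DAYS_PER_YEAR,
    SURFACE_CODES,
    SURFACE_FROM_CODE,
    VARIABLE_UNITS,
    DailyFieldCube,
    GridDef,
    LAND,
    SEA,
    _TEMPERATURE_KINDS,
)

logger = logging.getLogger(__name__)

_STANDARD_NAMES = {
    "sst": "sea_surface_temperature",
    "air_temp": "air_temperature",
    "wind_u": "eastward_wind",
    "wind_v": "northward_wind",
    "wind_speed": "wind_speed",
    "precip": "precipitation_amount",
}


def write_cube(cube: DailyFieldCube, path) -> None:
    """Write a cube as NetCDF3 with CF-style attributes and the surface
    classification as an integer-coded companion variable."""
    codes = np.vectorize(SURFACE_CODES.__getitem__, otypes=[np.int32])(
        cube.grid.surface_class
    )
    ds = xr.Dataset(
        {
            cube.variable_kind: (
                ("time", "lat", "lon"),
                cube.values,
                {
                    "units": cube.units,
                    "standard_name": _STANDARD_NAMES[cube.variable_kind],
                },
            ),
            "surface_class": (
                ("lat", "lon"),
                codes,
                {"flag_values": "0 1 2", "flag_meanings": "land sea mixed"},
            ),
        },
        coords={
            "time": (
                "time",
                np.arange(cube.n_days, dtype=np.float64),
                {
                    "units": f"days since {cube.start_year:04d}-01-01",
                    "calendar": "noleap",
                },
            ),
            "lat": ("lat", cube.grid.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", cube.grid.lon_centers, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def _edges_from_centers(centers: np.ndarray, name: str) -> np.ndarray:
    if centers.size < 2:
        raise ValueError(f"axis {name} needs at least 2 points to infer spacing")
    steps = np.diff(centers)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise ValueError(f"axis {name} is not uniformly spaced")
    step = steps[0]
    return np.concatenate((centers - step / 2.0, [centers[-1] + step / 2.0]))


def _normalize_time(ds: xr.Dataset) -> tuple[xr.Dataset, int]:
    """Validate the daily time axis; drop Feb 29 on standard calendars.

    Returns the (possibly subset) dataset and the start year.
    """
    time = ds["time"]
    units = str(time.attrs.get("units", ""))
    calendar = str(time.attrs.get("calendar", "noleap")).lower()
    vals = np.asarray(time.values, dtype=float)
    if "since" in units:
        base = pd.Timestamp(units.split("since", 1)[1].strip())
        start_year = int(base.year)
    else:
        base = None
        start_year = 1993
    if calendar in ("noleap", "365_day", ""):
        steps = np.diff(vals)
        if vals.size > 1 and not np.allclose(steps, 1.0):
            raise ValueError("time axis is not daily (step != 1 day)")
        return ds, start_year
    # standard calendar: materialize dates, drop Feb 29, re-check contiguity
    if base is None:
        raise ValueError("standard-calendar time axis needs 'days since ...' units")
    dates = base + pd.to_timedelta(vals, unit="D")
    steps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    if vals.size > 1 and not np.all(steps == 1):
        raise ValueError("time axis is not daily (step != 1 day)")
    keep = ~((dates.month == 2) & (dates.day == 29))
    if not keep.all():
        logger.info("dropping %d leap days from the record", int((~keep).sum()))
        ds = ds.isel(time=np.nonzero(keep)[0])
    return ds, start_year


def read_cube(
    path,
    variable_kind: str,
    surface_class: np.ndarray | None = None,
) -> DailyFieldCube:
    """Read a daily cube, converting units to the analysis conventions.

    The file must contain a variable matching ``variable_kind`` (or a
    common alias) with time/lat/lon axes. Temperatures in kelvin are
    converted to Celsius. Without a stored surface classification or an
    explicit ``surface_class`` array, pixels that are missing on every
    day are classed land and the rest sea.
    """
    ds = xr.open_dataset(path, decode_times=False, engine="scipy")
    try:
        aliases = {
            "sst": ("sst", "sea_surface_temperature", "tos"),
            "air_temp": ("air_temp", "t2m", "air_temperature", "tas"),
            "wind_u": ("wind_u", "u10", "uas"),
            "wind_v": ("wind_v", "v10", "vas"),
            "wind_speed": ("wind_speed", "si10"),
            "precip": ("precip", "tp", "precipitation"),
        }
        if variable_kind not in aliases:
            raise ValueError(f"unknown variable_kind {variable_kind!r}")
        name = next((n for n in aliases[variable_kind] if n in ds), None)
        if name is None:
            raise ValueError(
                f"variable {variable_kind!r} not found in {path} "
                f"(looked for {aliases[variable_kind]})"
            )
        for axis in ("time", "lat", "lon"):
            if axis not in ds[name].dims:
                raise ValueError(f"variable {name!r} is missing axis {axis!r}")
        ds, start_year = _normalize_time(ds)
        da = ds[name].transpose("time", "lat", "lon")
        values = np.asarray(da.values, dtype=float)
        units = str(da.attrs.get("units", VARIABLE_UNITS[variable_kind]))
        if variable_kind in _TEMPERATURE_KINDS and units.strip().lower() in ("k", "kelvin"):
            values = values - 273.15
            units = "degC"

        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        if surface_class is None:
            if "surface_class" in ds:
                codes = np.asarray(ds["surface_class"].values, dtype=int)
                surface_class = np.vectorize(SURFACE_FROM_CODE.__getitem__, otypes=[object])(
                    codes
                )
            else:
                all_missing = np.all(np.isnan(values), axis=0)
                surface_class = np.where(all_missing, LAND, SEA).astype(object)
        grid = GridDef(
            _edges_from_centers(lat, "lat"), _edges_from_centers(lon, "lon"), surface_class
        )
        return DailyFieldCube(variable_kind, values, grid, units, start_year)
    finally:
        ds.close()


def _axis_weights(src: np.ndarray, tgt: np.ndarray):
    """Lower index, fractional weight and validity for 1-D linear interp."""
    valid = (tgt >= src[0]) & (tgt <= src[-1])
    i0 = np.clip(np.searchsorted(src, tgt, side="right") - 1, 0, src.size - 2)
    w = (tgt - src[i0]) / (src[i0 + 1] - src[i0])
    return i0, w, valid


def regrid_bilinear(cube: DailyFieldCube, target: GridDef) -> DailyFieldCube:
    """Bilinearly interpolate a cube onto the target grid's cell centres.

    Missing source cells propagate missing wherever they carry nonzero
    weight (no extrapolation across the coast); target centres outside
    the source centre hull are missing. Identical grids round-trip the
    values unchanged.
    """
    src_lat, src_lon = cube.grid.lat_centers, cube.grid.lon_centers
    tgt_lat, tgt_lon = target.lat_centers, target.lon_centers
    if tgt_lat[-1] < src_lat[0] or tgt_lat[0] > src_lat[-1] or (
        tgt_lon[-1] < src_lon[0] or tgt_lon[0] > src_lon[-1]
    ):
        raise ValueError("source and target grids are disjoint")

    i0, wi, vlat = _axis_weights(src_lat, tgt_lat)
    j0, wj, vlon = _axis_weights(src_lon, tgt_lon)
    v = cube.values
    out = np.zeros((v.shape[0], tgt_lat.size, tgt_lon.size))
    corners = (
        (i0, j0, (1 - wi)[:, None] * (1 - wj)[None, :]),
        (i0, j0 + 1, (1 - wi)[:, None] * wj[None, :]),
        (i0 + 1, j0, wi[:, None] * (1 - wj)[None, :]),
        (i0 + 1, j0 + 1, wi[:, None] * wj[None, :]),
    )
    for ci, cj, w in corners:
        vals = v[:, ci[:, None], cj[None, :]]
        # zero-weight corners contribute nothing even when missing
        out += np.where(w == 0.0, 0.0, w * vals)
    invalid = ~(vlat[:, None] & vlon[None, :])
    out[:, invalid] = np.nan
    return DailyFieldCube(cube.variable_kind, out, target, cube.units, cube.start_year)


def wind_speed(u: DailyFieldCube, v: DailyFieldCube) -> DailyFieldCube:
    """Wind intensity sqrt(u^2 + v^2) from the 10 m components, in m/s."""
    if not u.grid.same_grid(v.grid):
        raise ValueError("u and v are on different grids")
    if u.n_days != v.n_days or u.start_year != v.start_year:
        raise ValueError("u and v time axes do not match")
    return DailyFieldCube(
        "wind_speed", np.hypot(u.values, v.values), u.grid, "m/s", u.start_year
    )
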