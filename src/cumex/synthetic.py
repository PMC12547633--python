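"""Synthetic daily fields and species hotspots with known ground truth.

Every downstream stage (climatology, event detection, cumulative maps,
trends, hotspot exposure) is exercised on data generated here, so the
statistical structure is fully controlled: a sinusoidal seasonal cycle
whose phase flips across the equator, stationary AR(1) noise, an optional
linear trend in the level, and discrete extreme episodes injected with
known start, duration and amplitude. The calendar has no leap days
(365-day years), which keeps the climatology indexing exact.

The generator makes no attempt at physical realism beyond this structure
(no ENSO, fronts, or spatial noise correlation); precipitation in
particular is plain Gaussian and may go negative, which downstream code
never assumes away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from shapely.geometry import MultiPolygon, box

from .exposure import Hotspot, HotspotSet
from .grid import (
    DAYS_PER_YEAR,
    LAND,
    MIXED,
    SEA,
    VARIABLE_KINDS,
    VARIABLE_UNITS,
    DailyFieldCube,
    GridDef,
)

logger = logging.getLogger(__name__)

#: Typical background level per variable, in the variable's units.
DEFAULT_MEAN_LEVEL = {
    "sst": 15.0,
    "air_temp": 12.0,
    "wind_u": 6.0,
    "wind_v": 1.0,
    "wind_speed": 7.0,
    "precip": 0.002,
}

#: Calendar day of the seasonal maximum: mid-January south of the equator
#: (Southern-Hemisphere seasonality is the reference), mid-July north of it.
PEAK_DOY_SOUTH = 14
PEAK_DOY_NORTH = 14 + 182


@dataclass
class FieldSpec:
    """Recipe for one synthetic daily field.

    years mirrors a 31-year record; seasonal_amplitude, noise_sd and
    level_trend are in the variable's units (trend per year);
    ar1_coefficient is the lag-1 autocorrelation of the daily noise.
    """

    variable_kind: str
    grid: GridDef
    years: int = 31
    seasonal_amplitude: float = 5.0
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.5
    level_trend: float = 0.0
    mean_level: float | None = None
    seed: int = 0
    start_year: int = 1993

    def validate(self) -> None:
        if self.variable_kind not in VARIABLE_KINDS:
            raise ValueError(f"variable_kind: unknown kind {self.variable_kind!r}")
        if self.years < 2:
            raise ValueError(f"years: must be >= 2, got {self.years}")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError(
                f"ar1_coefficient: must be in [0, 1), got {self.ar1_coefficient}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0, got {self.noise_sd}")


@dataclass
class EpisodeSpec:
    """A discrete extreme episode: ``amplitude`` is added on days
    ``[start, start + duration)`` at one pixel, on top of the noise-free
    seasonal expectation."""

    pixel: tuple[int, int]
    start: int
    duration: int
    amplitude: float

    @property
    def end(self) -> int:
        """Last day index of the episode (inclusive)."""
        return self.start + self.duration - 1


def seasonal_cycle(spec: FieldSpec) -> np.ndarray:
    """Noise-free expectation per calendar day: ``(365, nlat, nlon)``."""
    doy = np.arange(DAYS_PER_YEAR)
    lat = spec.grid.lat_centers
    peak = np.where(lat < 0, PEAK_DOY_SOUTH, PEAK_DOY_NORTH)
    level = DEFAULT_MEAN_LEVEL[spec.variable_kind] if spec.mean_level is None else spec.mean_level
    cyc = level + spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy[:, None] - peak[None, :]) / DAYS_PER_YEAR
    )
    return np.repeat(cyc[:, :, None], spec.grid.nlon, axis=2)


def generate_daily_cube(spec: FieldSpec) -> DailyFieldCube:
    """Generate a daily cube: seasonal cycle + AR(1) noise + linear trend.

    The AR(1) noise is stationary with marginal standard deviation
    ``noise_sd`` (innovations scaled by ``sqrt(1 - phi^2)``). Identical
    specs (including seed) give bit-identical cubes. For SST, cells
    classified as land are missing (NaN); mixed coastal cells keep values.
    """
    spec.validate()
    nlat, nlon = spec.grid.shape
    n_days = spec.years * DAYS_PER_YEAR

    cyc = seasonal_cycle(spec)
    values = np.tile(cyc, (spec.years, 1, 1))
    if spec.level_trend != 0.0:
        t_years = np.arange(n_days, dtype=float) / DAYS_PER_YEAR
        values += spec.level_trend * t_years[:, None, None]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        phi = spec.ar1_coefficient
        innov_sd = spec.noise_sd * np.sqrt(1.0 - phi * phi)
        eps = rng.standard_normal((n_days, nlat, nlon)) * innov_sd
        if phi > 0:
            # stationary start: x_{-1} ~ N(0, noise_sd^2)
            x_prev = rng.standard_normal((nlat, nlon)) * spec.noise_sd
            zi = (phi * x_prev)[None, :, :]
            noise, _ = lfilter([1.0], [1.0, -phi], eps, axis=0, zi=zi)
        else:
            noise = eps
        values += noise

    if spec.variable_kind == "sst":
        values[:, spec.grid.surface_class == LAND] = np.nan

    return DailyFieldCube(
        spec.variable_kind,
        values,
        spec.grid,
        VARIABLE_UNITS[spec.variable_kind],
        spec.start_year,
    )


def inject_episodes(cube: DailyFieldCube, episodes: list[EpisodeSpec]) -> DailyFieldCube:
    """Return a new cube with each episode's amplitude added on its days.

    The input cube is not modified. Overlapping episodes at one pixel add.
    """
    out = cube.copy()
    nlat, nlon = cube.grid.shape
    for ep in episodes:
        i, j = ep.pixel
        if ep.duration < 1:
            raise ValueError(f"episode duration must be >= 1, got {ep.duration}")
        if not (0 <= i < nlat and 0 <= j < nlon):
            raise ValueError(f"episode pixel {ep.pixel} outside grid {cube.grid.shape}")
        if ep.start < 0 or ep.start + ep.duration > cube.n_days:
            raise ValueError(
                f"episode days [{ep.start}, {ep.start + ep.duration}) outside "
                f"record of {cube.n_days} days"
            )
        out.values[ep.start : ep.start + ep.duration, i, j] += ep.amplitude
    return out


def _inset_box(bounds: tuple[float, float, float, float], frac: float = 0.05):
    """Box shrunk inward so it does not touch neighbouring cells."""
    lon0, lat0, lon1, lat1 = bounds
    dx, dy = (lon1 - lon0) * frac, (lat1 - lat0) * frac
    return box(lon0 + dx, lat0 + dy, lon1 - dx, lat1 - dy)


_IUCN_CYCLE = ("LC", "NT", "VU", "EN", "CR")


def generate_hotspots(grid: GridDef, n_species: int, seed: int = 0) -> HotspotSet:
    """Generate named hotspot polygons exercising the grid's edge cases.

    Guarantees: species 1 spans a land-role and a sea cell; species 2 is
    strictly marine; with ``n_species >= 3``, species 3 is smaller than a
    single grid cell and sits inside a sea-classed cell, so its land-role
    rasterization is empty (the unresolvable-island case). Remaining
    species are random rectangles. Same seed, same polygons.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    cls = grid.surface_class
    land_cells = list(zip(*np.nonzero((cls == LAND) | (cls == MIXED))))
    sea_cells = list(zip(*np.nonzero(cls == SEA)))
    if not land_cells or not sea_cells:
        raise ValueError(
            "degenerate grid: hotspot generation needs at least one land-role "
            "and one strictly-sea cell"
        )

    rng = np.random.default_rng(seed)
    hotspots: list[Hotspot] = []

    # 1: coastal species spanning land and sea.
    li, lj = land_cells[0]
    si, sj = sea_cells[0]
    geom = MultiPolygon(
        [_inset_box(grid.cell_bounds(li, lj)), _inset_box(grid.cell_bounds(si, sj))]
    )
    hotspots.append(Hotspot("sp01_coastal", geom, iucn=_IUCN_CYCLE[0]))

    if n_species >= 2:
        mi, mj = sea_cells[-1]
        hotspots.append(
            Hotspot(
                "sp02_marine",
                _inset_box(grid.cell_bounds(mi, mj)),
                iucn=_IUCN_CYCLE[1],
            )
        )
    if n_species >= 3:
        ii, ij = sea_cells[len(sea_cells) // 2]
        lon0, lat0, lon1, lat1 = grid.cell_bounds(ii, ij)
        cx, cy = 0.5 * (lon0 + lon1), 0.5 * (lat0 + lat1)
        r = 0.1 * (lon1 - lon0)  # sub-cell: 20% of a cell across
        hotspots.append(
            Hotspot("sp03_islet", box(cx - r, cy - r, cx + r, cy + r), iucn=_IUCN_CYCLE[2])
        )

    lat_lo, lat_hi = grid.lat_edges[0], grid.lat_edges[-1]
    lon_lo, lon_hi = grid.lon_edges[0], grid.lon_edges[-1]
    for k in range(4, n_species + 1):
        w = rng.uniform(0.5, 3.0) * grid.cell_size
        h = rng.uniform(0.5, 3.0) * grid.cell_size
        cx = rng.uniform(lon_lo, lon_hi)
        cy = rng.uniform(lat_lo, lat_hi)
        geom = box(
            max(lon_lo, cx - w / 2),
            max(lat_lo, cy - h / 2),
            min(lon_hi, cx + w / 2),
            min(lat_hi, cy + h / 2),
        )
        hotspots.append(
            Hotspot(f"sp{k:02d}_roamer", geom, iucn=_IUCN_CYCLE[(k - 1) % len(_IUCN_CYCLE)])
        )
    logger.debug("generated %d hotspot polygons", len(hotspots))
    return HotspotSet(hotspots[:n_species])
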