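"""Core containers shared across the pipeline: the analysis grid, daily
field cubes, and per-pixel metric layers.

The analysis runs on a regular latitude/longitude grid (1 degree by
default). Every cell carries a surface classification -- ``land``, ``sea``
or ``mixed`` for coastal cells containing both. Mixed cells play a double
role: they count as sea cells when sea-based extreme events (marine
heatwaves, extreme winds at sea) are analysed and as land cells for
land-based events (heatwaves, extreme winds on land, extreme
precipitation).

Time is handled on a 365-day no-leap calendar: day-of-record index
``t`` maps to year ``t // 365`` and calendar day ``t % 365``. Real-data
ingestion drops February 29 before analysis so that both paths share one
climatology convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DAYS_PER_YEAR = 365

LAND = "land"
SEA = "sea"
MIXED = "mixed"
SURFACE_CLASSES = (LAND, SEA, MIXED)
SURFACE_CODES = {LAND: 0, SEA: 1, MIXED: 2}
SURFACE_FROM_CODE = {v: k for k, v in SURFACE_CODES.items()}

VARIABLE_KINDS = ("sst", "air_temp", "wind_u", "wind_v", "wind_speed", "precip")
#: Units after ingestion (temperatures are converted from K to degC on read).
VARIABLE_UNITS = {
    "sst": "degC",
    "air_temp": "degC",
    "wind_u": "m/s",
    "wind_v": "m/s",
    "wind_speed": "m/s",
    "precip": "m/h",
}
_TEMPERATURE_KINDS = ("sst", "air_temp")

#: The five extreme-event types and their routing.
EVENT_TYPES = ("MHW", "HW", "wind_sea", "wind_land", "precip")
SEA_EVENT_TYPES = ("MHW", "wind_sea")
LAND_EVENT_TYPES = ("HW", "wind_land", "precip")
EVENT_ENVIRONMENT = {
    "MHW": "sea",
    "wind_sea": "sea",
    "HW": "land",
    "wind_land": "land",
    "precip": "land",
}
EVENT_VARIABLE = {
    "MHW": "sst",
    "HW": "air_temp",
    "wind_sea": "wind_speed",
    "wind_land": "wind_speed",
    "precip": "precip",
}
#: Minimum event duration in days: >=5 for the marine variable (SST),
#: >=3 for atmospheric variables.
MIN_DURATION = {"MHW": 5, "HW": 3, "wind_sea": 3, "wind_land": 3, "precip": 3}

METRICS = ("intensity", "duration", "frequency")
ENVIRONMENTS = ("sea", "land")

_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def canonical_type_order(environment: str) -> tuple[str, ...]:
    """Fixed event-type order per environment, used for deterministic
    tie-breaking and integer coding of categorical maps."""
    if environment == "sea":
        return SEA_EVENT_TYPES
    if environment == "land":
        return LAND_EVENT_TYPES
    raise ValueError(f"unknown environment {environment!r}")


def noleap_date(day_index: int, start_year: int = 1993) -> str:
    """ISO-style date label for a day-of-record index on the 365-day calendar."""
    if day_index < 0:
        raise ValueError("day_index must be non-negative")
    year = start_year + day_index // DAYS_PER_YEAR
    doy = day_index % DAYS_PER_YEAR
    for month, length in enumerate(_MONTH_LENGTHS, start=1):
        if doy < length:
            return f"{year:04d}-{month:02d}-{doy + 1:02d}"
        doy -= length
    raise AssertionError("unreachable")


@dataclass(eq=False)
class GridDef:
    """Regular lat/lon grid with a per-cell surface classification.

    Parameters
    ----------
    lat_edges, lon_edges
        Strictly increasing, uniformly spaced cell edges in degrees.
        The (shared) spacing is the cell size.
    surface_class
        ``(nlat, nlon)`` array of ``"land"`` / ``"sea"`` / ``"mixed"``.
    """

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    surface_class: np.ndarray

    def __post_init__(self) -> None:
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        for name, edges in (("lat_edges", self.lat_edges), ("lon_edges", self.lon_edges)):
            if edges.ndim != 1 or edges.size < 2:
                raise ValueError(f"{name} must be a 1-D array with at least 2 entries")
            steps = np.diff(edges)
            if np.any(steps <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError(f"{name} must be uniformly spaced")
        dlat = self.lat_edges[1] - self.lat_edges[0]
        dlon = self.lon_edges[1] - self.lon_edges[0]
        if not np.isclose(dlat, dlon, rtol=0, atol=1e-9):
            raise ValueError("lat and lon cell sizes must match")
        self.surface_class = np.asarray(self.surface_class)
        if self.surface_class.shape != self.shape:
            raise ValueError(
                f"surface_class shape {self.surface_class.shape} does not match "
                f"grid shape {self.shape}"
            )
        bad = set(np.unique(self.surface_class)) - set(SURFACE_CLASSES)
        if bad:
            raise ValueError(f"unknown surface classes: {sorted(bad)}")

    # -- geometry ---------------------------------------------------------
    @property
    def nlat(self) -> int:
        return self.lat_edges.size - 1

    @property
    def nlon(self) -> int:
        return self.lon_edges.size - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def cell_size(self) -> float:
        return float(self.lat_edges[1] - self.lat_edges[0])

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of cell ``(i, j)``."""
        return (
            float(self.lon_edges[j]),
            float(self.lat_edges[i]),
            float(self.lon_edges[j + 1]),
            float(self.lat_edges[i + 1]),
        )

    # -- surface routing --------------------------------------------------
    def class_mask(self, cls: str) -> np.ndarray:
        if cls not in SURFACE_CLASSES:
            raise ValueError(f"unknown surface class {cls!r}")
        return self.surface_class == cls

    def role_mask(self, environment: str) -> np.ndarray:
        """Cells participating in an environment: mixed coastal cells are
        routed to BOTH the sea and the land side."""
        if environment == "sea":
            return (self.surface_class == SEA) | (self.surface_class == MIXED)
        if environment == "land":
            return (self.surface_class == LAND) | (self.surface_class == MIXED)
        raise ValueError(f"unknown environment {environment!r}")

    def same_grid(self, other: "GridDef") -> bool:
        return (
            self.lat_edges.shape == other.lat_edges.shape
            and self.lon_edges.shape == other.lon_edges.shape
            and np.allclose(self.lat_edges, other.lat_edges, rtol=0, atol=1e-9)
            and np.allclose(self.lon_edges, other.lon_edges, rtol=0, atol=1e-9)
        )

    @classmethod
    def regular(
        cls,
        lat_min: float,
        lon_min: float,
        nlat: int,
        nlon: int,
        cell_size: float = 1.0,
        surface_class: np.ndarray | str | None = None,
    ) -> "GridDef":
        """Build a regular grid; ``surface_class`` may be a full array, a
        single class name, or None (all sea)."""
        lat_edges = lat_min + cell_size * np.arange(nlat + 1)
        lon_edges = lon_min + cell_size * np.arange(nlon + 1)
        if surface_class is None:
            surface_class = SEA
        if isinstance(surface_class, str):
            surface_class = np.full((nlat, nlon), surface_class, dtype=object)
        return cls(lat_edges, lon_edges, surface_class)


@dataclass(eq=False)
class DailyFieldCube:
    """One variable's daily values on a regular grid.

    ``values`` has shape ``(time, lat, lon)`` with a contiguous daily time
    axis on the 365-day calendar anchored at January 1 of ``start_year``.
    Missing cells (e.g. SST over land) are NaN.
    """

    variable_kind: str
    values: np.ndarray
    grid: GridDef
    units: str
    start_year: int = 1993

    def __post_init__(self) -> None:
        if self.variable_kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable_kind {self.variable_kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (time, lat, lon)")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"values spatial shape {self.values.shape[1:]} does not match "
                f"grid shape {self.grid.shape}"
            )

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        if self.n_days % DAYS_PER_YEAR:
            raise ValueError("record does not span whole 365-day years")
        return self.n_days // DAYS_PER_YEAR

    def copy(self) -> "DailyFieldCube":
        return DailyFieldCube(
            self.variable_kind, self.values.copy(), self.grid, self.units, self.start_year
        )


@dataclass(eq=False)
class MetricLayer:
    """Per-pixel scalar field for one event type and one metric."""

    event_type: str
    metric: str
    values: np.ndarray
    units: str
    grid: GridDef
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("layer shape does not match grid")

    @property
    def environment(self) -> str:
        return EVENT_ENVIRONMENT[self.event_type]
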