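"""Seasonally varying percentile climatology and extreme-event detection.

An extreme event is a discrete, prolonged episode in which a daily
variable exceeds its seasonally varying 90th-percentile threshold for at
least a type-specific minimum number of consecutive days (>= 5 for the
marine variable, >= 3 for atmospheric variables). The threshold for each
calendar day is the percentile of all values falling in a window centred
on that day, pooled across every year of the record, then smoothed with a
centred circular moving average -- the convention established for marine
heatwaves, applied here to all five event types. No detrending is done
before detection: events are detected on the raw record, trends included.

Event intensity is the mean anomaly relative to the seasonal (smoothed
climatological) mean over the event's days; per-pixel summaries reduce a
catalog to mean intensity, mean duration and frequency
(extreme-event days per year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .grid import (
    DAYS_PER_YEAR,
    EVENT_TYPES,
    EVENT_VARIABLE,
    MIN_DURATION,
    VARIABLE_UNITS,
    DailyFieldCube,
    GridDef,
    MetricLayer,
    noleap_date,
)

EVENT_COLUMNS = ("ilat", "ilon", "start", "end", "duration", "mean_intensity")


@dataclass(eq=False)
class Climatology:
    """Per calendar-day (1..365) threshold and seasonal mean per pixel."""

    thresholds: np.ndarray  # (365, nlat, nlon)
    seasonal_mean: np.ndarray  # (365, nlat, nlon)
    window_days: int
    smooth_days: int
    percentile: float
    grid: GridDef
    n_years: int

    def expand(self, n_days: int) -> tuple[np.ndarray, np.ndarray]:
        """Thresholds and seasonal means aligned to a day-of-record axis."""
        doy = np.arange(n_days) % DAYS_PER_YEAR
        return self.thresholds[doy], self.seasonal_mean[doy]


def daily_climatology(
    cube: DailyFieldCube,
    window_days: int = 11,
    smooth_days: int = 31,
    percentile: float = 90.0,
) -> Climatology:
    """Build the seasonally varying percentile climatology.

    For each calendar day ``d`` the threshold is the given percentile of
    all values within ``d +/- (window_days - 1) / 2`` (wrapping across the
    year boundary) pooled across all years, then smoothed with a centred
    circular moving average of ``smooth_days`` days. The seasonal mean is
    computed identically with the mean in place of the percentile. The
    baseline is the full record; no detrending.
    """
    if window_days < 1 or window_days % 2 == 0:
        raise ValueError(f"window_days must be a positive odd integer, got {window_days}")
    if smooth_days < 1 or smooth_days % 2 == 0:
        raise ValueError(f"smooth_days must be a positive odd integer, got {smooth_days}")
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if cube.n_days % DAYS_PER_YEAR:
        raise ValueError("record must span whole 365-day years")
    years = cube.n_days // DAYS_PER_YEAR
    if years < 2:
        raise ValueError(f"record must span at least 2 full years, got {years}")

    nlat, nlon = cube.grid.shape
    v = cube.values.reshape(years, DAYS_PER_YEAR, nlat, nlon)
    has_nan = bool(np.isnan(v).any())
    half = (window_days - 1) // 2
    offsets = np.arange(-half, half + 1)

    thr = np.empty((DAYS_PER_YEAR, nlat, nlon))
    mean = np.empty((DAYS_PER_YEAR, nlat, nlon))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        for d in range(DAYS_PER_YEAR):
            idx = (d + offsets) % DAYS_PER_YEAR
            pooled = v[:, idx].reshape(-1, nlat, nlon)
            if has_nan:
                thr[d] = np.nanpercentile(pooled, percentile, axis=0)
                mean[d] = np.nanmean(pooled, axis=0)
            else:
                thr[d] = np.percentile(pooled, percentile, axis=0)
                mean[d] = pooled.mean(axis=0)

    if smooth_days > 1:
        thr = uniform_filter1d(thr, size=smooth_days, axis=0, mode="wrap")
        mean = uniform_filter1d(mean, size=smooth_days, axis=0, mode="wrap")
    return Climatology(thr, mean, window_days, smooth_days, percentile, cube.grid, years)


@dataclass(eq=False)
class EventCatalog:
    """Per-pixel list of detected events for one event type.

    ``events`` is a flat table (ilat, ilon, start, end, duration,
    mean_intensity) with inclusive day indices; events at one pixel are
    non-overlapping and time-ordered. ``valid_mask`` marks pixels where
    detection ran (non-missing input inside the domain mask); frequency
    is 0 there when no event occurred and missing elsewhere.
    """

    event_type: str
    events: pd.DataFrame
    record_years: int
    grid: GridDef
    valid_mask: np.ndarray
    start_year: int = 1993
    min_duration: int | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"events table missing columns {sorted(missing)}")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_csv(self, path) -> None:
        out = self.events.copy()
        out.insert(0, "event_type", self.event_type)
        out["start_date"] = [noleap_date(s, self.start_year) for s in out["start"]]
        out["end_date"] = [noleap_date(e, self.start_year) for e in out["end"]]
        out.to_csv(path, index=False)


def _runs(exceed: np.ndarray, join_gap: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of True: (starts, ends) with exclusive ends."""
    e = np.concatenate(([0], exceed.astype(np.int8), [0]))
    d = np.diff(e)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    if join_gap > 0 and starts.size > 1:
        gaps = starts[1:] - ends[:-1]
        keep = gaps > join_gap
        starts = starts[np.concatenate(([True], keep))]
        ends = ends[np.concatenate((keep, [True]))]
    return starts, ends


def detect_events(
    cube: DailyFieldCube,
    clim: Climatology,
    event_type: str,
    min_duration: int | None = None,
    *,
    strict_min: bool = False,
    intensity_reference: str = "seasonal_mean",
    join_gap: int = 0,
    domain_mask: np.ndarray | None = None,
) -> EventCatalog:
    """Detect discrete extreme events per pixel.

    A day is extreme when its value is strictly greater than its
    calendar-day threshold; maximal runs of extreme days form candidate
    events and runs shorter than ``min_duration`` are discarded
    (``strict_min=True`` switches the keep rule from ``>=`` to ``>``).
    ``join_gap`` optionally merges runs separated by at most that many
    non-extreme days (off by default). ``mean_intensity`` is the mean over
    event days of the anomaly relative to the seasonal mean (or to the
    threshold with ``intensity_reference="threshold"``).
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event_type {event_type!r}")
    if not cube.grid.same_grid(clim.grid):
        raise ValueError("cube and climatology grids do not match")
    if intensity_reference not in ("seasonal_mean", "threshold"):
        raise ValueError(f"unknown intensity_reference {intensity_reference!r}")
    if min_duration is None:
        min_duration = MIN_DURATION[event_type]

    thr_full, mean_full = clim.expand(cube.n_days)
    ref_full = mean_full if intensity_reference == "seasonal_mean" else thr_full
    with np.errstate(invalid="ignore"):
        exceed = cube.values > thr_full
        anom = cube.values - ref_full

    valid = ~np.all(np.isnan(thr_full), axis=0)
    if domain_mask is not None:
        valid = valid & np.asarray(domain_mask, dtype=bool)

    rows = []
    for i, j in zip(*np.nonzero(valid)):
        starts, ends = _runs(exceed[:, i, j], join_gap=join_gap)
        durations = ends - starts
        keep = durations > min_duration if strict_min else durations >= min_duration
        for s, e in zip(starts[keep], ends[keep]):
            rows.append(
                (i, j, int(s), int(e) - 1, int(e - s), float(anom[s:e, i, j].mean()))
            )
    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    events = events.astype(
        {
            "ilat": int,
            "ilon": int,
            "start": int,
            "end": int,
            "duration": int,
            "mean_intensity": float,
        }
    )
    return EventCatalog(
        event_type,
        events,
        cube.n_years,
        cube.grid,
        valid,
        cube.start_year,
        min_duration,
    )


def summarize_events(catalog: EventCatalog) -> dict[str, MetricLayer]:
    """Reduce a catalog to per-pixel intensity / duration / frequency.

    intensity = mean of the events' mean intensities; duration = mean
    event duration (both missing where no events); frequency = total
    extreme-event days divided by the record length in years (0 where
    detection ran but found nothing, missing outside the valid domain).
    """
    shape = catalog.grid.shape
    intensity = np.full(shape, np.nan)
    duration = np.full(shape, np.nan)
    frequency = np.full(shape, np.nan)
    frequency[catalog.valid_mask] = 0.0

    if catalog.n_events:
        g = catalog.events.groupby(["ilat", "ilon"])
        agg = g.agg(
            intensity=("mean_intensity", "mean"),
            duration=("duration", "mean"),
            days=("duration", "sum"),
        ).reset_index()
        ii = agg["ilat"].to_numpy()
        jj = agg["ilon"].to_numpy()
        intensity[ii, jj] = agg["intensity"]
        duration[ii, jj] = agg["duration"]
        frequency[ii, jj] = agg["days"] / catalog.record_years

    var_units = VARIABLE_UNITS[EVENT_VARIABLE[catalog.event_type]]
    mk = lambda metric, vals, units: MetricLayer(
        catalog.event_type, metric, vals, units, catalog.grid
    )
    return {
        "intensity": mk("intensity", intensity, var_units),
        "duration": mk("duration", duration, "days"),
        "frequency": mk("frequency", frequency, "days/year"),
    }
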