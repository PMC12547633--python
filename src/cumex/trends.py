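"""Per-pixel trends of annual event metrics and their cumulative stacking.

Event catalogs are annualized (an event belongs to the year containing
its start day, with its full duration attributed there): per pixel and
year, the mean event intensity, the mean event duration, and the number
of extreme-event days. Frequency carries 0 in event-free years; intensity
and duration are missing there. An ordinary least-squares line of each
annual series on the (centred) year index gives a slope per year and the
two-sided t-test p-value of that slope -- plain OLS, with no correction
for serial correlation of the annual values and no multiple-testing
correction across pixels (an optional Benjamini-Hochberg step is
available but off by default, matching per-pixel significance reporting).

Only pixels with a positive AND significant slope are kept; the retained
slope layers are min-max normalized over their retained pixels, summed
and re-normalized exactly like the cumulative mean. Because several
event types can be retained at one pixel, attribution is the SET of
contributing types (a combination map), and an area-fraction table
reports the share of each environment's cells affected by one type, by
each specific combination, and in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cumulative import CumulativeLayer, _minmax
from .detection import EventCatalog
from .grid import DAYS_PER_YEAR, EVENT_ENVIRONMENT, GridDef, canonical_type_order
from .grid import MetricLayer  # noqa: F401  (re-exported for callers)

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class AnnualMetricSeries:
    """One value per year and pixel for one event type and metric."""

    event_type: str
    metric: str
    values: np.ndarray  # (years, nlat, nlon)
    grid: GridDef
    units: str


@dataclass(eq=False)
class TrendLayer:
    """Per-pixel OLS slope (units/year) and p-value for one annual series."""

    event_type: str
    metric: str
    slope: np.ndarray
    p_value: np.ndarray
    n_years: np.ndarray
    grid: GridDef
    units: str
    filtered: bool = False
    alpha: float | None = None


def annual_metrics(catalog: EventCatalog) -> dict[str, AnnualMetricSeries]:
    """Annualize a catalog into intensity / duration / frequency series.

    Events are assigned to the year containing their start day (an event
    spanning a year boundary counts fully in its start year). Frequency
    (extreme-event days) is 0 in event-free years on valid pixels;
    intensity and duration are missing there.
    """
    years = catalog.record_years
    shape = (years,) + catalog.grid.shape
    intensity = np.full(shape, np.nan)
    duration = np.full(shape, np.nan)
    frequency = np.full(shape, np.nan)
    frequency[:, catalog.valid_mask] = 0.0

    if catalog.n_events:
        ev = catalog.events.assign(year=catalog.events["start"] // DAYS_PER_YEAR)
        agg = (
            ev.groupby(["year", "ilat", "ilon"])
            .agg(
                intensity=("mean_intensity", "mean"),
                duration=("duration", "mean"),
                days=("duration", "sum"),
            )
            .reset_index()
        )
        yy = agg["year"].to_numpy()
        ii = agg["ilat"].to_numpy()
        jj = agg["ilon"].to_numpy()
        intensity[yy, ii, jj] = agg["intensity"]
        duration[yy, ii, jj] = agg["duration"]
        frequency[yy, ii, jj] = agg["days"]

    et = catalog.event_type
    g = catalog.grid
    return {
        "intensity": AnnualMetricSeries(et, "intensity", intensity, g, "field units"),
        "duration": AnnualMetricSeries(et, "duration", duration, g, "days"),
        "frequency": AnnualMetricSeries(et, "frequency", frequency, g, "days"),
    }


def ols_trend(series: AnnualMetricSeries, min_years: int = 10) -> TrendLayer:
    """Least-squares trend of an annual series per pixel.

    The year index is centred per pixel before fitting (conditioning
    only; the slope is unchanged). Pixels with fewer than ``min_years``
    non-missing years are missing, not an error. The p-value is the
    two-sided t-test on the slope; a perfectly constant series gets
    slope 0 and p 1.
    """
    years, nlat, nlon = series.values.shape
    y = series.values.reshape(years, -1)
    x = np.arange(years, dtype=float)[:, None]
    m = np.isfinite(y)
    n = m.sum(axis=0)
    eff_min = max(min_years, 3)  # df = n - 2 >= 1 needed for the t-test
    ok = n >= eff_min

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        xm = np.where(m, x, np.nan)
        ym = np.where(m, y, np.nan)
        xbar = np.nanmean(xm, axis=0)
        ybar = np.nanmean(ym, axis=0)
        dx = np.where(m, x - xbar, 0.0)
        dy = np.where(m, y - ybar, 0.0)
        sxx = (dx * dx).sum(axis=0)
        sxy = (dx * dy).sum(axis=0)
        slope = sxy / sxx
        resid = dy - slope * dx
        ss = (resid * resid).sum(axis=0)
        df = n - 2
        se = np.sqrt(ss / np.where(df > 0, df, 1) / sxx)
        t = slope / se
        p = 2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1))
        # degenerate fits: zero residual variance
        exact = ok & (ss <= 0)
        p[exact & (slope == 0)] = 1.0
        p[exact & (slope != 0)] = 0.0

    slope[~ok] = np.nan
    p[~ok] = np.nan
    return TrendLayer(
        series.event_type,
        series.metric,
        slope.reshape(nlat, nlon),
        p.reshape(nlat, nlon),
        n.reshape(nlat, nlon),
        series.grid,
        f"{series.units}/year",
    )


def fdr_adjust(p_value: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values over the non-missing pixels."""
    out = np.full(p_value.shape, np.nan)
    flat = p_value.ravel()
    idx = np.flatnonzero(np.isfinite(flat))
    if idx.size:
        out.ravel()[idx] = stats.false_discovery_control(flat[idx], method="bh")
    return out


def filter_positive_significant(
    trend: TrendLayer, alpha: float = 0.05, *, fdr: bool = False
) -> TrendLayer:
    """Keep only pixels with slope > 0 and p < alpha; all others missing."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    p = fdr_adjust(trend.p_value) if fdr else trend.p_value
    with np.errstate(invalid="ignore"):
        keep = (trend.slope > 0) & (p < alpha)
    slope = np.where(keep, trend.slope, np.nan)
    p_out = np.where(keep, trend.p_value, np.nan)
    return TrendLayer(
        trend.event_type,
        trend.metric,
        slope,
        p_out,
        trend.n_years,
        trend.grid,
        trend.units,
        filtered=True,
        alpha=alpha,
    )


def cumulative_trend(
    layers: list[TrendLayer],
    environment: str,
    *,
    renormalization: str = "minmax",
) -> CumulativeLayer:
    """Stack filtered trend layers into a cumulative [0, 1] map.

    Each retained slope layer is min-max normalized over its own retained
    pixels (non-retained pixels contribute 0), the normalized layers are
    summed, and the sum re-normalized. Attribution is the per-pixel SET
    of retained event types (``contributing``); pixels retained in no
    layer are missing.
    """
    if not layers:
        raise ValueError("need at least one trend layer")
    metric = layers[0].metric
    grid = layers[0].grid
    order = canonical_type_order(environment)
    for tl in layers:
        if not tl.filtered:
            raise ValueError("cumulative_trend expects filtered trend layers")
        if tl.metric != metric:
            raise ValueError("layers mix metrics")
        if not tl.grid.same_grid(grid):
            raise ValueError("layers are on different grids")
        if EVENT_ENVIRONMENT[tl.event_type] != environment:
            raise ValueError("environments cannot be mixed")
    layers = sorted(layers, key=lambda tl: order.index(tl.event_type))

    retained = np.stack([np.isfinite(tl.slope) for tl in layers])
    total = np.zeros(grid.shape)
    for k, tl in enumerate(layers):
        if retained[k].any():
            norm = _minmax(tl.slope, retained[k], f"{tl.event_type}/{metric} trend")
            total += np.where(retained[k], norm, 0.0)
    any_ret = retained.any(axis=0)
    total[~any_ret] = np.nan
    if any_ret.any():
        if renormalization == "minmax":
            values = _minmax(total, any_ret, f"cumulative trend {environment}/{metric}")
        elif renormalization == "sum_to_one":
            values = total / np.nansum(total)
        else:
            raise ValueError(f"unknown renormalization {renormalization!r}")
    else:
        values = total  # all missing: empty cumulative layer
    return CumulativeLayer(
        environment,
        metric,
        values,
        tuple(tl.event_type for tl in layers),
        grid,
        contributing=retained,
    )


def trend_area_fractions(
    layers: list[TrendLayer], environment: str
) -> pd.DataFrame:
    """Area accounting of positive-and-significant trends.

    Over the environment's cells (mixed coastal cells count in both
    environments): the percentage of cells with at least one retained
    type (``any``), with exactly one (``single``), with two or more
    (``multi``), and each specific combination, labelled by the canonical
    type order joined with ``+``. single + multi = any by construction.
    """
    if not layers:
        raise ValueError("need at least one trend layer")
    grid = layers[0].grid
    metric = layers[0].metric
    order = canonical_type_order(environment)
    layers = sorted(layers, key=lambda tl: order.index(tl.event_type))
    domain = grid.role_mask(environment)
    n_domain = int(domain.sum())

    retained = np.stack([np.isfinite(tl.slope) & domain for tl in layers])
    count = retained.sum(axis=0)
    pct = lambda n: 100.0 * n / n_domain if n_domain else 0.0

    rows = [
        {"combo": "any", "n_cells": int((count >= 1).sum())},
        {"combo": "single", "n_cells": int((count == 1).sum())},
        {"combo": "multi", "n_cells": int((count >= 2).sum())},
    ]
    # every specific non-empty combination present in the domain
    weights = 1 << np.arange(len(layers))
    code = np.tensordot(weights, retained.astype(int), axes=1)
    for c in sorted(np.unique(code[domain])):
        if c == 0:
            continue
        types = [layers[k].event_type for k in range(len(layers)) if c >> k & 1]
        rows.append({"combo": "+".join(types), "n_cells": int((code == c)[domain].sum())})
    table = pd.DataFrame(rows)
    table.insert(0, "metric", metric)
    table.insert(0, "environment", environment)
    table["pct"] = [pct(n) for n in table["n_cells"]]
    table["n_domain_cells"] = n_domain
    return table
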