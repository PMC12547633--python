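"""Min-max normalization, cumulative stacking and dominant-type maps.

Metric layers for the event types sharing an environment (sea: marine
heatwaves and extreme winds at sea; land: heatwaves, extreme winds on
land and extreme precipitation) are each rescaled to [0, 1] with

    x' = (x - x_min) / (x_max - x_min)

over the non-missing pixels of the analysis domain, summed with equal
weights, and the sum rescaled again to [0, 1]. The result is the
cumulative map for one metric and one environment; the per-pixel
dominant event type is the one with the largest normalized value
(ties broken by the fixed canonical type order). An alternative
re-normalization dividing the stacked layer by its domain-wide sum is
available behind a switch (``renormalization="sum_to_one"``); the
min-max form is the default because it preserves the 0-1 per-pixel
scale of the final maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import (
    EVENT_ENVIRONMENT,
    METRICS,
    GridDef,
    MetricLayer,
    canonical_type_order,
)

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("low", "medium", "high", "very high")


@dataclass(eq=False)
class CumulativeLayer:
    """Normalized stacked metric field in [0, 1] with attribution.

    ``dominant`` (mean workflow) codes the per-pixel dominant event type
    as an index into ``event_types`` (-1 where missing); ``contributing``
    (trend workflow) is a boolean ``(n_types, nlat, nlon)`` stack marking
    the types retained at each pixel.
    """

    environment: str
    metric: str
    values: np.ndarray
    event_types: tuple[str, ...]
    grid: GridDef
    dominant: np.ndarray | None = None
    contributing: np.ndarray | None = None


def _minmax(values: np.ndarray, valid: np.ndarray, what: str) -> np.ndarray:
    """Eq-style rescale of ``values`` over ``valid`` pixels; NaN elsewhere."""
    out = np.full(values.shape, np.nan)
    sel = values[valid]
    lo, hi = sel.min(), sel.max()
    if hi == lo:
        logger.warning(
            "%s has no spread (min == max == %g); normalized layer set to 0", what, lo
        )
        out[valid] = 0.0
    else:
        out[valid] = (sel - lo) / (hi - lo)
    return out


def minmax_normalize(layer: MetricLayer, domain_mask: np.ndarray | None = None) -> MetricLayer:
    """Rescale a metric layer to [0, 1] over its non-missing (masked) pixels.

    The minimum maps to 0 and the maximum to 1; a spread-free layer maps
    to all zeros with a logged warning. Pixels outside the mask or missing
    in the input stay missing.
    """
    valid = np.isfinite(layer.values)
    if domain_mask is not None:
        valid &= np.asarray(domain_mask, dtype=bool)
    if not valid.any():
        raise ValueError("cannot normalize an all-missing layer")
    out = _minmax(layer.values, valid, f"{layer.event_type}/{layer.metric}")
    return MetricLayer(layer.event_type, layer.metric, out, "1", layer.grid, normalized=True)


def _check_stack(layers: list[MetricLayer], environment: str) -> list[MetricLayer]:
    if not layers:
        raise ValueError("need at least one layer")
    metric = layers[0].metric
    grid = layers[0].grid
    for ly in layers:
        if ly.metric != metric:
            raise ValueError("layers mix metrics")
        if not ly.grid.same_grid(grid):
            raise ValueError("layers are on different grids")
        if not ly.normalized:
            raise ValueError("layers must be min-max normalized first")
        if EVENT_ENVIRONMENT[ly.event_type] != environment:
            raise ValueError(
                f"layer {ly.event_type} belongs to "
                f"{EVENT_ENVIRONMENT[ly.event_type]!r}, not {environment!r}: "
                "environments cannot be mixed"
            )
    order = canonical_type_order(environment)
    return sorted(layers, key=lambda ly: order.index(ly.event_type))


def cumulative_mean(
    layers: list[MetricLayer],
    environment: str,
    *,
    renormalization: str = "minmax",
    compute_dominant: bool = True,
) -> CumulativeLayer:
    """Equally weighted cumulative map: sum normalized layers per pixel and
    re-normalize to [0, 1]. A pixel missing in every input stays missing;
    a layer missing at a pixel contributes nothing there."""
    if renormalization not in ("minmax", "sum_to_one"):
        raise ValueError(f"unknown renormalization {renormalization!r}")
    layers = _check_stack(layers, environment)
    stack = np.stack([ly.values for ly in layers])
    any_valid = np.isfinite(stack).any(axis=0)
    with np.errstate(invalid="ignore"):
        total = np.nansum(stack, axis=0)
    total[~any_valid] = np.nan
    if renormalization == "minmax":
        values = _minmax(total, any_valid, f"cumulative {environment}/{layers[0].metric}")
    else:
        values = total / np.nansum(total)
    types = tuple(ly.event_type for ly in layers)
    dom = dominant_event(layers)[0] if compute_dominant else None
    return CumulativeLayer(
        environment, layers[0].metric, values, types, layers[0].grid, dominant=dom
    )


def dominant_event(layers: list[MetricLayer]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-pixel index of the event type with the largest normalized value.

    Returns integer codes into the returned canonical type tuple; -1 where
    every layer is missing. Exact ties go to the first type in canonical
    order.
    """
    environment = EVENT_ENVIRONMENT[layers[0].event_type]
    layers = _check_stack(layers, environment)
    stack = np.stack([ly.values for ly in layers])
    filled = np.where(np.isfinite(stack), stack, -np.inf)
    codes = np.argmax(filled, axis=0).astype(np.int32)  # first max wins ties
    codes[~np.isfinite(stack).any(axis=0)] = -1
    return codes, tuple(ly.event_type for ly in layers)


def classify_quartile(values):
    """Class labels for cumulative values: [0, 0.25) low, [0.25, 0.5)
    medium, [0.5, 0.75) high, [0.75, 1] very high. Scalars map to a label
    string, arrays element-wise (missing values map to None)."""
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0.0) | (arr[finite] > 1.0)):
        raise ValueError("values must lie in [0, 1]")
    codes = np.digitize(arr, [0.25, 0.5, 0.75])
    if arr.ndim == 0:
        if not finite:
            raise ValueError("value must be finite")
        return QUARTILE_LABELS[int(codes)]
    labels = np.array([None] * arr.size, dtype=object).reshape(arr.shape)
    labels[finite] = np.array(QUARTILE_LABELS, dtype=object)[codes[finite]]
    return labels
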