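"""Suitable-area dynamics: thresholding, spherical areas, regional splits.

Cloglog suitability maps are binarized at a threshold (typically the maxSSS
threshold from the training data), and the suitable area is summed from the
analytic spherical cell areas. Cells split into Europe vs Asia at the Ural
meridian (60 degrees E) and into polar vs non-polar at the Arctic Circle
(66.562 degrees N), both assigned by cell center with half-open boundaries
(a center exactly on the meridian counts as Asia; exactly on the circle
counts as polar).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .maxent import MaxentModel, project
from .rasters import LayerStack, Raster, cell_area_km2

URAL_MERIDIAN_E = 60.0
ARCTIC_CIRCLE_N = 66.562

__all__ = [
    "ThresholdedMap",
    "threshold_map",
    "regional_areas",
    "area_series",
    "variable_ranges",
    "URAL_MERIDIAN_E",
    "ARCTIC_CIRCLE_N",
]


@dataclass
class ThresholdedMap:
    """Binary suitability map: 1 where suitability >= t, 0 below, NaN missing."""

    binary: Raster
    t: float
    species: str = ""
    period: str = ""
    climate_model: str = ""


def threshold_map(
    suitability: Raster,
    t: float,
    species: str = "",
    period: str = "",
    climate_model: str = "",
) -> ThresholdedMap:
    """Binarize a suitability raster at threshold ``t`` in [0, 1]."""
    if not (0.0 <= t <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    vals = np.where(
        np.isnan(suitability.values), np.nan, (suitability.values >= t).astype(float)
    )
    return ThresholdedMap(
        binary=Raster(spec=suitability.spec, values=vals),
        t=t,
        species=species,
        period=period,
        climate_model=climate_model,
    )


def regional_areas(
    tmap: ThresholdedMap,
    meridian: float = URAL_MERIDIAN_E,
    polar_lat: float = ARCTIC_CIRCLE_N,
) -> dict[str, float]:
    """Suitable area in km^2: total, Europe/Asia split, and polar share.

    Every suitable cell belongs to exactly one of Europe (center lon <
    ``meridian``) or Asia, so europe + asia = total exactly; polar cells
    (center lat >= ``polar_lat``) are a subset of the total.
    """
    spec = tmap.binary.spec
    suitable = np.nan_to_num(tmap.binary.values, nan=0.0) > 0
    row_areas = cell_area_km2(spec, np.arange(spec.nrows))
    lon = spec.lon_centers()
    lat = spec.lat_centers()
    area_grid = np.broadcast_to(row_areas[:, None], suitable.shape)
    west = lon < meridian
    polar = lat >= polar_lat
    total = float(area_grid[suitable].sum())
    europe = float((area_grid * suitable * west[None, :]).sum())
    asia = float((area_grid * suitable * (~west)[None, :]).sum())
    polar_area = float((area_grid * suitable * polar[:, None]).sum())
    return {"total": total, "europe": europe, "asia": asia, "polar": polar_area}


def area_series(
    runs: Iterable[tuple[str, MaxentModel, Sequence[LayerStack], float]],
    meridian: float = URAL_MERIDIAN_E,
    polar_lat: float = ARCTIC_CIRCLE_N,
    clamp: bool = True,
) -> pd.DataFrame:
    """Assemble the per-period suitable-area table.

    ``runs`` yields (species, fitted model, stacks for its periods/scenarios,
    threshold). Each stack contributes one row keyed by its period and climate
    model labels; rows appear in input order, so reruns are reproducible.
    """
    rows = []
    for species, model, stacks, t in runs:
        for stack in stacks:
            suit = project(model, stack, clamp=clamp)
            tmap = threshold_map(
                suit, t, species=species, period=stack.period, climate_model=stack.climate_model
            )
            areas = regional_areas(tmap, meridian=meridian, polar_lat=polar_lat)
            rows.append(
                {
                    "species": species,
                    "period": stack.period,
                    "climate_model": stack.climate_model,
                    "threshold": t,
                    "total_km2": areas["total"],
                    "europe_km2": areas["europe"],
                    "asia_km2": areas["asia"],
                    "polar_km2": areas["polar"],
                }
            )
    return pd.DataFrame(rows)


def variable_ranges(tmap: ThresholdedMap, stack: LayerStack) -> pd.DataFrame:
    """Min/max of each climate variable over the suitable cells.

    Raises if the map has no suitable cell. Missing layer cells are ignored
    per variable.
    """
    suitable = np.nan_to_num(tmap.binary.values, nan=0.0) > 0
    if not suitable.any():
        raise ValueError("no suitable cells at this threshold")
    rows = []
    for name, raster in stack.layers.items():
        vals = raster.values[suitable]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            rows.append({"variable": name, "min": float("nan"), "max": float("nan")})
        else:
            rows.append({"variable": name, "min": float(vals.min()), "max": float(vals.max())})
    return pd.DataFrame(rows)
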