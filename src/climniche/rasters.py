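"""Gridded climate layers: ESRI ASCII I/O, cropping, point extraction, cell areas.

Layers live on an unprojected WGS84 lon/lat grid described by :class:`GridSpec`
(lower-left corner + square cell size, the ESRI ASCII convention). Values are
stored north-row-first, with missing cells as NaN in memory and as the grid's
``nodata`` sentinel on disk. Cell areas are computed analytically on a sphere
of radius 6371 km, so thresholded suitability maps can be turned into km^2
totals without reprojection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "Raster",
    "LayerStack",
    "SWDTable",
    "read_ascii_grid",
    "write_ascii_grid",
    "crop",
    "extract_swd",
    "cell_area_km2",
    "correlation_matrix",
    "write_swd",
    "read_swd",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: ``ncols`` x ``nrows`` square cells of ``cellsize``
    degrees with lower-left corner at (``xll``, ``yll``)."""

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if not (-180.0 - 1e-9 <= self.xll and self.xll + self.ncols * self.cellsize <= 180.0 + 1e-9):
            raise ValueError("grid longitudes must lie within [-180, 180]")
        if not (-90.0 - 1e-9 <= self.yll and self.yll + self.nrows * self.cellsize <= 90.0 + 1e-9):
            raise ValueError("grid latitudes must lie within [-90, 90]")

    @property
    def xmax(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east (column order)."""
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (row order, row 0 = north)."""
        return self.ymax - (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_index(self, lon, lat):
        """Map points to (row, col) by half-open cells [west, east) x [south, north).

        Returns integer arrays plus a boolean mask of points inside the grid.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        row_from_south = np.floor((lat - self.yll) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_south
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return row, col, inside


@dataclass
class Raster:
    """A single layer: a GridSpec plus an (nrows, ncols) float array, NaN = missing."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid "
                f"({self.spec.nrows}, {self.spec.ncols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~np.isnan(self.values)


@dataclass
class LayerStack:
    """Named co-registered rasters (e.g. bio1..bio19) on one grid.

    ``period`` labels the climate period/scenario (current, LGM, MH, LIG,
    2070-rcp26, ...), ``climate_model`` the source GCM where applicable.
    """

    layers: dict[str, Raster]
    period: str = "current"
    climate_model: str = ""

    def __post_init__(self) -> None:
        specs = {r.spec for r in self.layers.values()}
        if len(specs) > 1:
            raise ValueError("all layers in a stack must share one GridSpec")
        if not self.layers:
            raise ValueError("a stack needs at least one layer")

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.layers.values())).spec

    @property
    def variables(self) -> list[str]:
        return list(self.layers.keys())

    def complete_mask(self) -> np.ndarray:
        """Cells where every layer has data."""
        m = np.ones((self.spec.nrows, self.spec.ncols), dtype=bool)
        for r in self.layers.values():
            m &= r.mask
        return m

    def values_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stack values into an (n_cells, n_vars) matrix over ``mask`` cells
        (row-major order)."""
        if mask is None:
            mask = self.complete_mask()
        return np.column_stack([r.values[mask] for r in self.layers.values()])

    def relabel(self, period: str | None = None, climate_model: str | None = None) -> "LayerStack":
        return LayerStack(
            layers=dict(self.layers),
            period=self.period if period is None else period,
            climate_model=self.climate_model if climate_model is None else climate_model,
        )


@dataclass
class SWDTable:
    """'Samples with data': per-point environmental values.

    ``data`` has columns ``species, lon, lat`` followed by one column per
    variable; ``n_excluded`` counts points dropped for falling outside the
    grid or on a missing cell in any layer.
    """

    data: pd.DataFrame
    n_excluded: int = 0

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("species", "lon", "lat")]

    @property
    def values(self) -> np.ndarray:
        return self.data[self.variables].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (header then row-major values, north row first)."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: bad header line {i + 1}: {line.strip()!r}") from exc
        else:
            break
    else:
        i += 1
    data_lines = lines[i:]
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header keyword(s): {', '.join(missing)}")
    nodata = header.get("nodata_value", -9999.0)
    spec = GridSpec(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )
    rows: list[list[float]] = []
    count = 0
    for j, line in enumerate(data_lines):
        if not line.strip():
            continue
        vals = line.split()
        try:
            row = [float(v) for v in vals]
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value on line {i + j + 1}") from exc
        rows.append(row)
        count += len(row)
    if count != spec.ncols * spec.nrows:
        # Identify the first offending line for the error message.
        for j, row in enumerate(rows):
            if len(row) != spec.ncols:
                raise ValueError(
                    f"{path}: line {i + j + 1} has {len(row)} values, expected {spec.ncols}"
                )
        raise ValueError(
            f"{path}: {count} values found, header declares {spec.ncols * spec.nrows}"
        )
    values = np.array([v for row in rows for v in row], dtype=float).reshape(
        spec.nrows, spec.ncols
    )
    values[values == nodata] = np.nan
    return Raster(spec=spec, values=values)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid; NaN cells are written as the nodata sentinel."""
    spec = raster.spec
    vals = raster.values.copy()
    vals[np.isnan(vals)] = spec.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.xll:.10g}\n")
        fh.write(f"yllcorner {spec.yll:.10g}\n")
        fh.write(f"cellsize {spec.cellsize:.12g}\n")
        fh.write(f"NODATA_value {spec.nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Cropping and extraction


def crop(stack: LayerStack, bbox: tuple[float, float, float, float]) -> LayerStack:
    """Crop a stack to the cells whose centers fall inside ``bbox``.

    ``bbox`` is (lon_min, lon_max, lat_min, lat_max); containment is half-open
    ([min, max) on both axes) so each cell center lands in at most one box.
    """
    lon_min, lon_max, lat_min, lat_max = bbox
    spec = stack.spec
    lons = spec.lon_centers()
    lats = spec.lat_centers()
    col_sel = np.where((lons >= lon_min) & (lons < lon_max))[0]
    row_sel = np.where((lats >= lat_min) & (lats < lat_max))[0]
    if col_sel.size == 0 or row_sel.size == 0:
        raise ValueError("bbox does not overlap the grid")
    r0, r1 = row_sel[0], row_sel[-1] + 1
    c0, c1 = col_sel[0], col_sel[-1] + 1
    new_spec = GridSpec(
        ncols=c1 - c0,
        nrows=r1 - r0,
        xll=spec.xll + c0 * spec.cellsize,
        yll=spec.ymax - r1 * spec.cellsize,
        cellsize=spec.cellsize,
        nodata=spec.nodata,
    )
    layers = {
        name: Raster(spec=new_spec, values=r.values[r0:r1, c0:c1].copy())
        for name, r in stack.layers.items()
    }
    return LayerStack(layers=layers, period=stack.period, climate_model=stack.climate_model)


def extract_swd(stack: LayerStack, points: Iterable[tuple[float, float]] | np.ndarray,
                label: str) -> SWDTable:
    """Build an SWD table for ``points`` ((lon, lat) pairs) against a stack.

    Points outside the grid, or on a cell missing in any layer, are dropped
    and counted in ``n_excluded``.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if pts.size == 0:
        return SWDTable(
            data=pd.DataFrame(columns=["species", "lon", "lat", *stack.variables]),
            n_excluded=0,
        )
    pts = pts.reshape(-1, 2)
    spec = stack.spec
    row, col, inside = spec.cell_index(pts[:, 0], pts[:, 1])
    n_excluded = int((~inside).sum())
    row, col, pts_in = row[inside], col[inside], pts[inside]
    cols: dict[str, np.ndarray] = {}
    keep = np.ones(len(pts_in), dtype=bool)
    for name, r in stack.layers.items():
        v = r.values[row, col]
        cols[name] = v
        keep &= ~np.isnan(v)
    n_excluded += int((~keep).sum())
    data = pd.DataFrame(
        {
            "species": label,
            "lon": pts_in[keep, 0],
            "lat": pts_in[keep, 1],
            **{name: v[keep] for name, v in cols.items()},
        }
    )
    return SWDTable(data=data, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Spherical cell areas


def cell_area_km2(spec: GridSpec, row_index: int | np.ndarray) -> float | np.ndarray:
    """Area of a cell in the given row (row 0 = north), in km^2.

    A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)) on a sphere of
    radius 6371 km; constant along a row.
    """
    row = np.asarray(row_index)
    lat_top = spec.ymax - row * spec.cellsize
    lat_bot = lat_top - spec.cellsize
    dlam = math.radians(spec.cellsize)
    area = (
        EARTH_RADIUS_KM**2
        * dlam
        * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    )
    if np.isscalar(row_index):
        return float(area)
    return area


# ---------------------------------------------------------------------------
# Correlation


def correlation_matrix(swd: SWDTable, threshold: float = 0.9
                       ) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pearson correlations among an SWD table's variables.

    Returns the symmetric correlation matrix (unit diagonal) and the list of
    variable pairs with |r| >= ``threshold``. Constant variables yield NaN
    correlations and are flagged with r = NaN.
    """
    if len(swd) < 3:
        raise ValueError("correlation needs at least 3 complete rows")
    X = swd.data[swd.variables]
    corr = X.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    flagged: list[tuple[str, str, float]] = []
    names = swd.variables
    sds = X.std(ddof=1)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = corr.loc[a, b]
            if np.isnan(r) and (sds[a] == 0 or sds[b] == 0):
                flagged.append((a, b, float("nan")))
            elif abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    return corr, flagged


# ---------------------------------------------------------------------------
# SWD text I/O


def write_swd(swd: SWDTable, path: str | Path) -> None:
    """Write an SWD table as comma-delimited text with a header row."""
    swd.data.to_csv(path, index=False)


def read_swd(path: str | Path) -> SWDTable:
    """Read an SWD table written by :func:`write_swd`."""
    return SWDTable(data=pd.read_csv(path), n_excluded=0)
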