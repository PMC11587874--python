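"""Occurrence records: loading, validation, spatial thinning, sampling bias.

Presence-only datasets assembled from museum collections, sequence databases,
citizen science and literature are spatially biased toward well-collected
regions. This module provides the standard counter-measures: distance-based
thinning of clustered records (keeping the more recent record when two fall
within the minimum distance) and a kernel-density "bias surface" from which
effort-matched background points are drawn for maximum-entropy modeling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .rasters import GridSpec, Raster, EARTH_RADIUS_KM

logger = logging.getLogger(__name__)

VALID_SOURCES = {"collection", "sequence-db", "citizen-science", "literature"}

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "BiasSurface",
    "load_occurrences",
    "geodesic_distance_km",
    "pairwise_distances_km",
    "thin",
    "kde_bias_surface",
    "sample_background",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    """One presence record: species label, WGS84 coordinates, optional year/source."""

    species: str
    lon: float
    lat: float
    year: int | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass
class OccurrenceSet:
    """An ordered collection of records for one species."""

    species: str
    records: list[OccurrenceRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.species != self.species:
                raise ValueError(
                    f"record species {r.species!r} does not match set species {self.species!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return np.array([(r.lon, r.lat) for r in self.records], dtype=float).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "lon": [r.lon for r in self.records],
                "lat": [r.lat for r in self.records],
                "year": [r.year for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


@dataclass
class BiasSurface:
    """Per-cell collecting-effort weights on a grid, normalized to sum 1.

    ``weights`` is (nrows, ncols) with NaN at missing cells; non-missing
    weights are non-negative and sum to 1 (within 1e-9).
    """

    grid: GridSpec
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("weight array shape does not match grid")
        w = self.weights[~np.isnan(self.weights)]
        if (w < -1e-12).any():
            raise ValueError("bias weights must be non-negative")
        if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("bias weights must sum to 1 over non-missing cells")

    def renormalized(self, mask: np.ndarray | None = None) -> "BiasSurface":
        """Return a copy restricted to ``mask`` (True = keep) and renormalized."""
        w = self.weights.copy()
        if mask is not None:
            w[~mask] = np.nan
        total = np.nansum(w)
        if total <= 0:
            raise ValueError("no positive weight left after masking")
        return BiasSurface(grid=self.grid, weights=w / total)

    def to_raster(self) -> Raster:
        return Raster(spec=self.grid, values=self.weights.copy())


# ---------------------------------------------------------------------------
# Loading


def load_occurrences(path: str | Path, species: str) -> OccurrenceSet:
    """Read a delimited text file (comma or tab) of occurrence records.

    Requires columns ``species``, ``lon``, ``lat``; ``year`` and ``source``
    are optional. Rows with malformed or out-of-range coordinates are rejected
    with a log entry; exact duplicate (lon, lat) pairs are collapsed, keeping
    the most recent year (ties by file order). Raises if the file holds no
    valid rows for the requested species.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"species", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    df = df[df["species"].astype(str) == species]
    if len(df) == 0:
        raise ValueError(f"{path}: no rows for species {species!r}")

    records: list[OccurrenceRecord] = []
    n_rejected = 0
    for idx, row in df.iterrows():
        try:
            lon = float(row["lon"])
            lat = float(row["lat"])
        except (TypeError, ValueError):
            logger.warning("%s row %s: malformed coordinates, rejected", path.name, idx)
            n_rejected += 1
            continue
        if not (math.isfinite(lon) and math.isfinite(lat)):
            logger.warning("%s row %s: non-finite coordinates, rejected", path.name, idx)
            n_rejected += 1
            continue
        year = None
        if "year" in df.columns and pd.notna(row.get("year")):
            try:
                year = int(row["year"])
            except (TypeError, ValueError):
                year = None
        source = None
        if "source" in df.columns and pd.notna(row.get("source")):
            source = str(row["source"])
        try:
            records.append(
                OccurrenceRecord(species=species, lon=lon, lat=lat, year=year, source=source)
            )
        except ValueError as exc:
            logger.warning("%s row %s: %s, rejected", path.name, idx, exc)
            n_rejected += 1

    if not records:
        raise ValueError(f"{path}: all rows for species {species!r} were rejected")

    # Deduplicate identical coordinates, preferring the most recent year.
    best: dict[tuple[float, float], OccurrenceRecord] = {}
    order: list[tuple[float, float]] = []
    for rec in records:
        key = (rec.lon, rec.lat)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            old = best[key]
            if (rec.year is not None) and (old.year is None or rec.year > old.year):
                best[key] = rec
    deduped = [best[k] for k in order]
    n_dupes = len(records) - len(deduped)
    logger.info(
        "%s: %d record(s) loaded for %s (%d rejected, %d duplicate coordinate(s) collapsed)",
        path.name, len(deduped), species, n_rejected, n_dupes,
    )
    return OccurrenceSet(species=species, records=deduped)


# ---------------------------------------------------------------------------
# Geodesic distances


def geodesic_distance_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points, sphere R = 6371 km."""
    lon1, lat1 = math.radians(a[0]), math.radians(a[1])
    lon2, lat2 = math.radians(b[0]), math.radians(b[1])
    s = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def pairwise_distances_km(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle distances for (n, 2) lon/lat coords."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    lon = np.radians(coords[:, 0])[:, None]
    lat = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    s = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    s = np.clip(s, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(s))


# ---------------------------------------------------------------------------
# Spatial thinning


def thin(
    occ: OccurrenceSet,
    min_distance_km: float = 50.0,
    prefer: Literal["recent", "first"] = "recent",
) -> OccurrenceSet:
    """Distance-based spatial thinning.

    Records are ordered by preference (``recent``: year descending with
    unknown years last, file order breaking ties; ``first``: file order) and
    scanned greedily: a record is kept iff it lies more than
    ``min_distance_km`` from every record already kept. The result is
    deterministic and maximal under that order, and every retained pair is
    separated by > ``min_distance_km``.
    """
    if min_distance_km <= 0:
        raise ValueError("min_distance_km must be positive")
    n = len(occ.records)
    if n == 0:
        return OccurrenceSet(species=occ.species, records=[])
    if prefer == "recent":
        order = sorted(
            range(n),
            key=lambda i: (
                0 if occ.records[i].year is not None else 1,
                -(occ.records[i].year or 0),
                i,
            ),
        )
    elif prefer == "first":
        order = list(range(n))
    else:
        raise ValueError(f"unknown preference {prefer!r}")

    dist = pairwise_distances_km(occ.coords())
    kept: list[int] = []
    for i in order:
        if all(dist[i, j] > min_distance_km for j in kept):
            kept.append(i)
    return OccurrenceSet(species=occ.species, records=[occ.records[i] for i in kept])


# ---------------------------------------------------------------------------
# KDE bias surface


def _nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference bandwidth h = 4 * 1.06 * min(sd, IQR/1.34) * n^(-1/5).

    The Gaussian kernel standard deviation used in the estimate is h/4, the
    convention of the classic two-dimensional KDE implementation (MASS kde2d
    with bandwidth.nrd).
    """
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = sd
    return 4.0 * 1.06 * spread * n ** (-1.0 / 5.0)


def kde_bias_surface(
    occ: OccurrenceSet,
    grid: GridSpec,
    bandwidth: tuple[float, float] | None = None,
    mask: np.ndarray | None = None,
) -> BiasSurface:
    """Gaussian-product kernel density of occurrences, evaluated at cell centers.

    Duplicate coordinates collapse to single points before estimation; the
    density is computed in lon/lat degrees (unprojected grid) and renormalized
    to sum 1 over non-missing cells. ``bandwidth`` overrides the per-axis
    kernel standard deviations; ``mask`` (True = valid) marks cells to keep.
    """
    coords = np.unique(occ.coords(), axis=0)
    if coords.shape[0] < 2:
        raise ValueError(
            "kernel density needs >= 2 distinct coordinates; jitter the records "
            "or use a uniform bias surface"
        )
    if bandwidth is None:
        hx = _nrd_bandwidth(coords[:, 0]) / 4.0
        hy = _nrd_bandwidth(coords[:, 1]) / 4.0
        # Degenerate spread on an axis (all points aligned): fall back to one cell.
        hx = hx if hx > 0 else grid.cellsize
        hy = hy if hy > 0 else grid.cellsize
    else:
        hx, hy = bandwidth
        if hx <= 0 or hy <= 0:
            raise ValueError("bandwidths must be positive")

    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    # Separable Gaussian kernels: density(x, y) = mean_i N(x; xi, hx) N(y; yi, hy).
    gx = np.exp(-0.5 * ((lon_c[None, :] - coords[:, 0][:, None]) / hx) ** 2)  # (n, ncols)
    gy = np.exp(-0.5 * ((lat_c[None, :] - coords[:, 1][:, None]) / hy) ** 2)  # (n, nrows)
    dens = gy.T @ gx  # (nrows, ncols)
    if mask is not None:
        dens = np.where(mask, dens, np.nan)
    total = np.nansum(dens)
    if not np.isfinite(total) or total <= 0:
        raise ValueError("kernel density has no mass on the grid")
    return BiasSurface(grid=grid, weights=dens / total)


# ---------------------------------------------------------------------------
# Background sampling


def sample_background(
    bias: BiasSurface, n: int = 10_000, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` background points (cell centers) with probability ~ bias weight.

    Sampling is with replacement, reproducible for a fixed seed; zero-weight
    and missing cells are never drawn. Returns an (n, 2) array of (lon, lat).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = bias.weights.ravel()
    valid = np.where(np.nan_to_num(w, nan=0.0) > 0)[0]
    if valid.size == 0:
        raise ValueError("bias surface has no cell with positive weight")
    p = w[valid] / w[valid].sum()
    idx = rng.choice(valid, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(idx, bias.weights.shape)
    lon = bias.grid.lon_centers()[cols]
    lat = bias.grid.lat_centers()[rows]
    return np.column_stack([lon, lat])
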