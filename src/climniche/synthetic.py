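"""Synthetic climate stacks and virtual species with known ground truth.

Real studies of this kind consume 19 bioclimatic rasters per climate period
and presence records collected with strong spatial bias. This module generates
desk-scale stand-ins with the same shapes and formats: inter-correlated
climate surfaces (latitudinal/longitudinal gradients plus smoothed, linearly
mixed Gaussian noise), "period" variants produced by additive offsets
(warming, precipitation change), and virtual species whose suitability is a
known Gaussian (bell) response to a few driver variables — so both "too cold"
and "too hot" limits exist. Every generator is a pure function of its
specification and seed, and each virtual species carries a truth record
(drivers, cutoff, true occupied area) for recovery tests.

The default grid spans 40-65 E x 50-75 N at 0.25 degrees (100 x 100 cells),
deliberately straddling both the Europe/Asia meridian (60 E) and the Arctic
Circle (66.562 N) so regional area accounting is exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .occurrences import BiasSurface, OccurrenceRecord, OccurrenceSet
from .rasters import GridSpec, LayerStack, Raster, SWDTable, cell_area_km2, extract_swd

__all__ = [
    "SyntheticClimateSpec",
    "VirtualSpecies",
    "make_climate_stack",
    "make_scenario",
    "sample_presences",
    "two_species_scenario",
    "recovery_scenario",
    "warming_scenario",
    "DEFAULT_GRID",
]

DEFAULT_GRID = GridSpec(ncols=100, nrows=100, xll=40.0, yll=50.0, cellsize=0.25)


def _ar1_correlation(p: int, rho: float = 0.6) -> np.ndarray:
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SyntheticClimateSpec:
    """Recipe for a correlated synthetic climate stack.

    Variables are named bio1..bioN. By default the first 11 behave like
    temperature summaries (cooling poleward at 0.5 units per degree latitude,
    smooth noise of amplitude 2) and the rest like precipitation summaries
    (drying eastward at 5 units per degree longitude, amplitude 60), with an
    AR(1)-style target correlation (rho = 0.6) between adjacent variable
    indices. All arrays may be overridden per variable.
    """

    grid: GridSpec = DEFAULT_GRID
    n_vars: int = 19
    seed: int = 0
    corr_length: int = 8  # smoothing window, in cells
    lat_slopes: np.ndarray | None = None  # units per degree latitude
    lon_slopes: np.ndarray | None = None  # units per degree longitude
    offsets: np.ndarray | None = None
    noise_amps: np.ndarray | None = None
    target_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = self.n_vars
        # Same 11:8 temperature:precipitation proportion as the bio1..bio19 set.
        n_temp = max(1, int(round(p * 11 / 19))) if p > 1 else 1
        temp_like = np.arange(p) < n_temp
        if self.lat_slopes is None:
            self.lat_slopes = np.where(temp_like, -0.5, 0.0)
        if self.lon_slopes is None:
            self.lon_slopes = np.where(temp_like, 0.0, -5.0)
        if self.offsets is None:
            self.offsets = np.where(temp_like, 10.0, 500.0)
        if self.noise_amps is None:
            self.noise_amps = np.where(temp_like, 2.0, 60.0)
        if self.target_corr is None:
            self.target_corr = _ar1_correlation(p)
        for name in ("lat_slopes", "lon_slopes", "offsets", "noise_amps"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (p,):
                raise ValueError(f"{name} must have shape ({p},)")
            setattr(self, name, arr)
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        if self.target_corr.shape != (p, p) or not np.allclose(
            self.target_corr, self.target_corr.T
        ):
            raise ValueError("target correlation must be a symmetric (p, p) matrix")

    @property
    def variables(self) -> list[str]:
        return [f"bio{i + 1}" for i in range(self.n_vars)]


def _smooth_unit_fields(rng: np.random.Generator, n: int, shape: tuple[int, int],
                        corr_length: int) -> np.ndarray:
    """Independent spatially smooth fields with zero mean and unit variance."""
    noise = rng.standard_normal((n, *shape))
    if corr_length > 1:
        noise = ndimage.uniform_filter(noise, size=(1, corr_length, corr_length),
                                       mode="nearest")
    flat = noise.reshape(n, -1)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)
    return flat.reshape(n, *shape)


def make_climate_stack(spec: SyntheticClimateSpec, period: str = "current",
                       climate_model: str = "synthetic") -> LayerStack:
    """Generate the correlated climate stack described by ``spec``.

    Each variable is a planar gradient plus ``noise_amps``-scaled smooth noise;
    the noise fields are linearly mixed through the matrix square root of the
    target correlation, so their empirical inter-variable correlations
    approximate the target. Deterministic (bit-identical) for a fixed seed.
    Raises if the target correlation is not positive semi-definite.
    """
    eigval, eigvec = np.linalg.eigh(spec.target_corr)
    if eigval.min() < -1e-8:
        raise ValueError("target correlation matrix is not positive semi-definite")
    A = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None))) @ eigvec.T

    rng = np.random.default_rng(spec.seed)
    shape = (spec.grid.nrows, spec.grid.ncols)
    base = _smooth_unit_fields(rng, spec.n_vars, shape, spec.corr_length)
    mixed = np.tensordot(A, base, axes=(1, 0))

    lon = spec.grid.lon_centers()
    lat = spec.grid.lat_centers()
    lon_g, lat_g = np.meshgrid(lon, lat)
    lat0 = lat.mean()
    lon0 = lon.mean()
    layers: dict[str, Raster] = {}
    for v, name in enumerate(spec.variables):
        vals = (
            spec.offsets[v]
            + spec.lat_slopes[v] * (lat_g - lat0)
            + spec.lon_slopes[v] * (lon_g - lon0)
            + spec.noise_amps[v] * mixed[v]
        )
        layers[name] = Raster(spec=spec.grid, values=vals)
    return LayerStack(layers=layers, period=period, climate_model=climate_model)


def make_scenario(stack: LayerStack, deltas: Mapping[str, float], period: str) -> LayerStack:
    """Additive climate scenario: offset the named variables, relabel the period.

    E.g. ``{"bio1": 2.0}`` warms the annual-mean-temperature surrogate by 2
    units everywhere. Raises on variables absent from the stack.
    """
    unknown = [v for v in deltas if v not in stack.layers]
    if unknown:
        raise ValueError(f"unknown variable(s): {', '.join(unknown)}")
    layers = {}
    for name, raster in stack.layers.items():
        vals = raster.values.copy()
        if name in deltas:
            vals = vals + deltas[name]
        layers[name] = Raster(spec=raster.spec, values=vals)
    return LayerStack(layers=layers, period=period, climate_model=stack.climate_model)


# ---------------------------------------------------------------------------
# Virtual species


@dataclass
class VirtualSpecies:
    """A species with a known climatic niche.

    ``drivers`` maps variable names to (optimum mu, tolerance sigma); the
    suitability at a cell is the product over drivers of the Gaussian bell
    exp(-(z - mu)^2 / (2 sigma^2)) (a ``logistic`` rising response
    1/(1 + exp(-(z - mu)/sigma)) is available as an option). Suitability lies
    in (0, 1].
    """

    name: str
    drivers: dict[str, tuple[float, float]]
    response: str = "gaussian"

    def suitability(self, stack: LayerStack) -> Raster:
        suit = np.ones((stack.spec.nrows, stack.spec.ncols))
        for var, (mu, sigma) in self.drivers.items():
            if var not in stack.layers:
                raise ValueError(f"stack lacks driver variable {var!r}")
            z = stack.layers[var].values
            if self.response == "gaussian":
                suit = suit * np.exp(-((z - mu) ** 2) / (2.0 * sigma**2))
            elif self.response == "logistic":
                suit = suit / (1.0 + np.exp(-(z - mu) / sigma))
            else:
                raise ValueError(f"unknown response {self.response!r}")
        mask = stack.complete_mask()
        suit = np.where(mask, suit, np.nan)
        return Raster(spec=stack.spec, values=suit)

    def true_area_km2(self, stack: LayerStack, cutoff: float) -> float:
        """Occupied area: total cell area where true suitability >= cutoff."""
        suit = self.suitability(stack).values
        rows = np.arange(stack.spec.nrows)
        area = cell_area_km2(stack.spec, rows)[:, None]
        occupied = np.nan_to_num(suit, nan=0.0) >= cutoff
        return float((area * occupied).sum())

    def truth_record(self, stack: LayerStack, cutoff: float) -> dict:
        return {
            "name": self.name,
            "response": self.response,
            "drivers": {v: {"mu": mu, "sigma": sigma} for v, (mu, sigma) in self.drivers.items()},
            "cutoff": cutoff,
            "true_area_km2": self.true_area_km2(stack, cutoff),
        }

    def save_truth(self, stack: LayerStack, cutoff: float, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth_record(stack, cutoff), indent=1))


def sample_presences(
    species: VirtualSpecies,
    stack: LayerStack,
    n: int,
    bias: BiasSurface | None = None,
    seed: int = 0,
    year_range: tuple[int, int] = (1980, 2020),
) -> OccurrenceSet:
    """Draw presence records with probability ~ suitability x collecting bias.

    ``bias=None`` means uniform effort. Cells are drawn with replacement;
    coordinates are cell centers with sub-cell jitter (points stay inside
    their cell); record years are uniform over ``year_range`` to exercise
    recency-preferring thinning. Deterministic by seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    suit = np.nan_to_num(species.suitability(stack).values, nan=0.0)
    if bias is not None:
        if bias.grid != stack.spec:
            raise ValueError("bias surface grid does not match the stack")
        suit = suit * np.nan_to_num(bias.weights, nan=0.0)
    w = suit.ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability x bias is zero everywhere")
    idx = rng.choice(w.size, size=n, replace=True, p=w / total)
    rows, cols = np.unravel_index(idx, suit.shape)
    spec = stack.spec
    jitter = rng.uniform(-0.499, 0.499, size=(n, 2)) * spec.cellsize
    lon = spec.lon_centers()[cols] + jitter[:, 0]
    lat = spec.lat_centers()[rows] + jitter[:, 1]
    years = rng.integers(year_range[0], year_range[1] + 1, size=n)
    records = [
        OccurrenceRecord(
            species=species.name, lon=float(lon[i]), lat=float(lat[i]),
            year=int(years[i]), source="collection",
        )
        for i in range(n)
    ]
    return OccurrenceSet(species=species.name, records=records)


# ---------------------------------------------------------------------------
# Packaged scenarios


def two_species_scenario(
    spec: SyntheticClimateSpec | None = None,
    offset_sd: float = 3.0,
    n_per_species: int = 200,
    seed: int = 0,
    driver_vars: tuple[str, ...] = ("bio1",),
    tolerance_sd: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Two virtual species differing only in the stated drivers' optima.

    Species A's optima sit at the grid means of the driver variables; species
    B's are shifted by ``offset_sd`` grid standard deviations on each driver.
    Returns a per-record feature table (``species`` label + all variables at
    the sampled points) and a truth record naming the discriminating
    variables. ``offset_sd = 0`` yields exchangeable niches (a null pair).
    """
    if offset_sd < 0:
        raise ValueError("offset must be >= 0")
    if spec is None:
        spec = SyntheticClimateSpec(seed=seed)
    stack = make_climate_stack(spec)
    drivers_a: dict[str, tuple[float, float]] = {}
    drivers_b: dict[str, tuple[float, float]] = {}
    for var in driver_vars:
        field_vals = stack.layers[var].values
        mu, sd = float(np.nanmean(field_vals)), float(np.nanstd(field_vals))
        drivers_a[var] = (mu, tolerance_sd * sd)
        drivers_b[var] = (mu + offset_sd * sd, tolerance_sd * sd)
    sp_a = VirtualSpecies(name="species_A", drivers=drivers_a)
    sp_b = VirtualSpecies(name="species_B", drivers=drivers_b)
    frames = []
    for i, sp in enumerate((sp_a, sp_b)):
        occ = sample_presences(sp, stack, n=n_per_species, seed=seed * 2 + i + 1)
        swd = extract_swd(stack, occ.coords(), label=sp.name)
        frames.append(swd.data)
    table = pd.concat(frames, ignore_index=True)
    truth = {
        "offset_variables": list(driver_vars),
        "offset_sd": offset_sd,
        "positive_species": sp_b.name,
        "species": [sp_a.name, sp_b.name],
    }
    return table, truth


@dataclass
class RecoveryScenario:
    """A full generated modeling problem with its ground truth attached."""

    stack: LayerStack
    species: VirtualSpecies
    occurrences: OccurrenceSet
    presence_swd: SWDTable
    background_swd: SWDTable
    background_points: np.ndarray
    true_cutoff: float
    true_area_km2: float


def recovery_scenario(
    seed: int = 0,
    n_presence: int = 200,
    n_background: int = 2000,
    n_vars: int = 6,
    grid: GridSpec = DEFAULT_GRID,
) -> RecoveryScenario:
    """The package's standard parameter-recovery problem.

    A 100 x 100 climate stack and one virtual species with a climatic optimum
    localized in both map directions: Gaussian niches (tolerance a quarter of
    a grid standard deviation, occupying roughly 15% of the study grid) on one
    temperature-like and one precipitation-like driver. ``n_presence`` presences are sampled proportionally to suitability
    under uniform effort, plus ``n_background`` uniform background points. The
    truth cutoff is the grid mean suitability: under suitability-proportional
    sampling against uniform background, that is the population optimum of the
    sensitivity-plus-specificity rule, so the maxSSS-thresholded model area is
    directly comparable with the true occupied area at this cutoff.
    """
    spec = SyntheticClimateSpec(grid=grid, n_vars=n_vars, seed=seed)
    stack = make_climate_stack(spec)
    # One temperature-like (latitudinal) and one precipitation-like
    # (longitudinal) driver give a niche localized in both directions.
    lat_driver = spec.variables[0]
    lon_candidates = [v for i, v in enumerate(spec.variables) if spec.lon_slopes[i] != 0]
    lon_driver = lon_candidates[0] if lon_candidates else spec.variables[-1]
    drivers = {}
    for var in (lat_driver, lon_driver):
        vals = stack.layers[var].values
        drivers[var] = (float(np.nanmean(vals)), 0.25 * float(np.nanstd(vals)))
    species = VirtualSpecies(name="virtual", drivers=drivers)
    occ = sample_presences(species, stack, n=n_presence, seed=seed + 1)
    presence_swd = extract_swd(stack, occ.coords(), label=species.name)

    rng = np.random.default_rng(seed + 2)
    mask = stack.complete_mask()
    valid = np.where(mask.ravel())[0]
    idx = rng.choice(valid, size=n_background, replace=True)
    rows, cols = np.unravel_index(idx, mask.shape)
    bg_pts = np.column_stack([grid.lon_centers()[cols], grid.lat_centers()[rows]])
    background_swd = extract_swd(stack, bg_pts, label="background")

    suit = species.suitability(stack).values
    cutoff = float(np.nanmean(suit))
    return RecoveryScenario(
        stack=stack,
        species=species,
        occurrences=occ,
        presence_swd=presence_swd,
        background_swd=background_swd,
        background_points=bg_pts,
        true_cutoff=cutoff,
        true_area_km2=species.true_area_km2(stack, cutoff),
    )


def warming_scenario(
    seed: int = 0, warming: float = 2.0, grid: GridSpec = DEFAULT_GRID, n_vars: int = 6
) -> tuple[LayerStack, LayerStack, VirtualSpecies]:
    """A baseline stack, a uniformly warmed variant, and a warm-adapted species.

    The species' thermal optimum sits near the value found just south of the
    Arctic Circle on the baseline stack, so warming the temperature-like
    variables shifts its suitable band poleward: the true (and modeled)
    suitable area above the Circle increases under the warmed stack.
    """
    spec = SyntheticClimateSpec(grid=grid, n_vars=n_vars, seed=seed)
    stack = make_climate_stack(spec, period="baseline")
    temp_like = [v for i, v in enumerate(spec.variables) if spec.lat_slopes[i] != 0]
    warmed = make_scenario(stack, {v: warming for v in temp_like}, period=f"warmed+{warming:g}")
    bio1 = stack.layers["bio1"].values
    lat = grid.lat_centers()
    # optimum = baseline bio1 averaged over the band 2-5 degrees below the Circle
    band = (lat >= 61.5) & (lat <= 64.5)
    mu = float(bio1[band, :].mean())
    sigma = float(np.nanstd(bio1)) * 0.5
    species = VirtualSpecies(name="warm_adapted", drivers={"bio1": (mu, sigma)})
    return stack, warmed, species
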