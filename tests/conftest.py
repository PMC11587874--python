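"""Shared fixtures: small synthetic grids, stacks and SWD tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from climniche.rasters import GridSpec, LayerStack, Raster, SWDTable
from climniche.synthetic import SyntheticClimateSpec, make_climate_stack


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(ncols=40, nrows=40, xll=50.0, yll=55.0, cellsize=0.5)


@pytest.fixture(scope="session")
def small_stack(small_grid) -> LayerStack:
    spec = SyntheticClimateSpec(grid=small_grid, n_vars=4, seed=7, corr_length=4)
    return make_climate_stack(spec)


def make_swd(X: np.ndarray, label: str, names: list[str] | None = None) -> SWDTable:
    """Wrap a plain value matrix as an SWD table with dummy coordinates."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = names or [f"bio{i + 1}" for i in range(X.shape[1])]
    n = X.shape[0]
    data = pd.DataFrame(
        {"species": [label] * n, "lon": np.zeros(n), "lat": np.zeros(n)}
    )
    for i, name in enumerate(names):
        data[name] = X[:, i]
    return SWDTable(data=data)


@pytest.fixture(scope="session")
def swd_factory():
    return make_swd
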