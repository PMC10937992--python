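import numpy as np
import pandas as pd
import pytest

from airexposure.grids import ConcentrationField, Grid, PopulationGrid, RegionSet


@pytest.fixture
def grid4() -> Grid:
    return Grid.regular(4, 4, resolution=0.1)


@pytest.fixture
def toy_field(grid4) -> ConcentrationField:
    rng = np.random.default_rng(7)
    dates = pd.date_range("2010-01-01", periods=30, freq="D")
    vals = rng.gamma(shape=4.0, scale=4.0, size=(30, 4, 4))
    return ConcentrationField("PM25", grid4, dates, vals)


@pytest.fixture
def toy_pop(grid4) -> PopulationGrid:
    rng = np.random.default_rng(11)
    return PopulationGrid(grid4, rng.integers(0, 500, size=(4, 4)).astype(float))


@pytest.fixture
def quadrant_regions(grid4) -> RegionSet:
    labels = np.zeros((4, 4), dtype=int)
    labels[:2, 2:] = 1
    labels[2:, :2] = 2
    labels[2:, 2:] = 3
    return RegionSet(region_ids=["A", "B", "C", "D"], labels=labels)
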