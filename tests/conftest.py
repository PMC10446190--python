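import numpy as np
import pytest

from trophamp.grid_io import Grid, GriddedField
from trophamp.synthetic import SyntheticConfig, default_members


def make_grid(nlat=4, nlon=4, land_cells=(), lat0=None, dlat=None):
    """Small regular grid; ``land_cells`` is a list of (i, j) indices."""
    if dlat is None:
        dlat = 180.0 / nlat
    if lat0 is None:
        lat0 = -90.0 + dlat / 2
    lat = lat0 + dlat * np.arange(nlat)
    lon = (360.0 / nlon) * (np.arange(nlon) + 0.5)
    mask = np.ones((nlat, nlon), dtype=bool)
    for i, j in land_cells:
        mask[i, j] = False
    return Grid(lat=lat, lon=lon, ocean_mask=mask)


def make_field(grid, years, values, var_name="npp", units="mol C m-2 yr-1"):
    values = np.asarray(values, dtype=np.float64).copy()
    values[:, ~grid.ocean_mask] = np.nan
    return GriddedField(grid=grid, years=np.asarray(years), values=values,
                        var_name=var_name, units=units)


def constant_field(grid, years, value, **kw):
    ny = len(years)
    return make_field(grid, years, np.full((ny,) + grid.shape, float(value)), **kw)


@pytest.fixture
def grid4():
    return make_grid(4, 4, land_cells=[(0, 0), (2, 3)])


@pytest.fixture
def small_config():
    """12x24 ensemble, short year range, fast to generate."""
    return SyntheticConfig(
        seed=7,
        grid_shape=(12, 24),
        year_range=(1980, 2060),
        reference_window=(1995, 2014),
        target_window=(2050, 2059),
        noise_sd=0.05,
        members=default_members((0.0, 0.1, 0.2)),
    )


@pytest.fixture
def small_config_noisefree(small_config):
    from dataclasses import replace
    return replace(small_config, noise_sd=0.0)
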