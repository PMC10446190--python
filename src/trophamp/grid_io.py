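"""Data model and NetCDF I/O for annual gridded ocean fields.

Fields live on a regular lat-lon grid with an ocean mask shared by every
field of one analysis.  Files follow the ISIMIP-style per-variable layout:
one variable per NetCDF file with dimensions ``(time, lat, lon)``, a CF
``units`` attribute and ``_FillValue`` on land.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import xarray as xr

__all__ = [
    "Grid",
    "GriddedField",
    "ClassScheme",
    "MemberOutput",
    "read_gridded_netcdf",
    "write_gridded_netcdf",
    "area_weighted_mean",
]

_FILL = np.float64(1.0e20)


def _check_regular(coord: np.ndarray, name: str) -> None:
    if coord.ndim != 1 or coord.size < 1:
        raise ValueError(f"{name} must be a 1-d coordinate array")
    if coord.size > 1:
        steps = np.diff(coord)
        if not np.all(steps > 0):
            raise ValueError(f"{name} must be strictly ascending")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{name} spacing is not regular")


@dataclass(frozen=True)
class Grid:
    """Regular lat-lon grid with cosine-latitude area weights.

    ``lat`` and ``lon`` are cell-center coordinates (degrees, lat ascending);
    ``ocean_mask`` is True on ocean cells.  Area weights are relative and
    depend only on latitude.
    """

    lat: np.ndarray
    lon: np.ndarray
    ocean_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=np.float64))
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=np.float64))
        object.__setattr__(self, "ocean_mask", np.asarray(self.ocean_mask, dtype=bool))
        _check_regular(self.lat, "lat")
        _check_regular(self.lon, "lon")
        if self.ocean_mask.shape != self.shape:
            raise ValueError(
                f"ocean_mask shape {self.ocean_mask.shape} != grid shape {self.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def cell_area(self) -> np.ndarray:
        """Relative cell area, proportional to cos(latitude), > 0 everywhere."""
        w = np.cos(np.deg2rad(self.lat))
        w = np.maximum(w, 1e-12)  # guard poles at |lat| = 90
        return np.broadcast_to(w[:, None], self.shape).copy()

    def same_layout(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def require_compatible(self, other: "Grid") -> None:
        if not self.same_layout(other):
            raise ValueError("grids differ in coordinates")
        if not np.array_equal(self.ocean_mask, other.ocean_mask):
            raise ValueError("ocean masks differ between fields of one analysis")


@dataclass
class GriddedField:
    """One variable on a Grid with an integer annual time axis.

    ``values`` has shape ``(n_years, n_lat, n_lon)``; NaN marks missing data
    and every land cell is NaN for all years.
    """

    grid: Grid
    years: np.ndarray
    values: np.ndarray
    var_name: str
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.years.ndim != 1:
            raise ValueError("years must be 1-d")
        if self.years.size > 1:
            d = np.diff(self.years)
            if not np.all(d == 1):
                raise ValueError("years must be strictly increasing and contiguous")
        expected = (self.years.size,) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        land = ~self.grid.ocean_mask
        if land.any() and not np.all(np.isnan(self.values[:, land])):
            raise ValueError("land cells must be missing (NaN) in all years")

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def year_index(self, year: int) -> int:
        idx = int(year - self.years[0])
        if idx < 0 or idx >= self.n_years:
            raise ValueError(f"year {year} outside data range "
                             f"{self.years[0]}-{self.years[-1]}")
        return idx

    def sel_years(self, start: int, end: int) -> np.ndarray:
        """Values for the inclusive year window, shape (n, nlat, nlon)."""
        i0, i1 = self.year_index(start), self.year_index(end)
        return self.values[i0 : i1 + 1]


@dataclass(frozen=True)
class ClassScheme:
    """Ordered consumer classes on a weight, length or trophic-level axis.

    ``bins`` are ``(lo, hi)`` intervals in the axis units (g, cm or TL);
    the last bin may be open-ended (``hi = inf``).  ``trophic_distance``
    optionally gives the number of transfer steps separating each class
    from primary producers (used by the synthetic generator).
    """

    axis: str
    bins: tuple[tuple[float, float], ...]
    labels: tuple[str, ...]
    trophic_distance: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.axis not in ("weight", "length", "trophic_level"):
            raise ValueError(f"unknown class axis {self.axis!r}")
        if len(self.bins) != len(self.labels):
            raise ValueError("bins and labels differ in length")
        for (lo, hi) in self.bins:
            if not hi > lo:
                raise ValueError(f"degenerate bin ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(self.bins[:-1], self.bins[1:]):
            if lo2 < hi:
                raise ValueError("bins overlap or are out of order")
        if np.isinf([hi for _, hi in self.bins[:-1]]).any():
            raise ValueError("only the last bin may be open-ended")
        if self.trophic_distance is not None:
            d = np.asarray(self.trophic_distance, dtype=float)
            if d.size != len(self.bins):
                raise ValueError("trophic_distance length mismatch")
            # non-decreasing: equal distances model size-independent warming
            # impacts (flat-profile members); default schemes are strict
            if d.size > 1 and not np.all(np.diff(d) >= 0):
                raise ValueError("trophic_distance must be non-decreasing")

    @property
    def n_classes(self) -> int:
        return len(self.bins)


@dataclass
class MemberOutput:
    """Outputs of one (ecosystem-model, forcing-model) pair.

    ``tcb`` is total consumer biomass (all organisms above trophic level 1);
    for generated ensembles it equals the sum of the per-class fields.
    """

    mem_name: str
    esm_name: str
    tcb: GriddedField
    class_biomass: list[tuple[str, GriddedField]]
    class_scheme: ClassScheme

    def __post_init__(self) -> None:
        for _, f in self.class_biomass:
            self.tcb.grid.require_compatible(f.grid)
        # tcb-only views (no class fields) are allowed for aggregate analyses
        if self.class_biomass and len(self.class_biomass) != self.class_scheme.n_classes:
            raise ValueError("class_biomass does not match class_scheme")


# ---------------------------------------------------------------------------
# NetCDF I/O

_LAT_NAMES = ("lat", "latitude", "y")
_LON_NAMES = ("lon", "longitude", "x")
_TIME_NAMES = ("time", "year", "years")


def _find_dim(dims: Sequence[str], candidates: Sequence[str], what: str) -> str:
    for c in candidates:
        if c in dims:
            return c
    raise ValueError(f"cannot identify {what} dimension among {tuple(dims)}")


def _years_from_time(coord: xr.DataArray) -> np.ndarray:
    vals = coord.values
    if np.issubdtype(np.asarray(vals).dtype, np.number):
        years = np.asarray(vals)
        if not np.allclose(years, np.round(years)):
            raise ValueError("time coordinate is not an annual (integer-year) axis")
        return np.round(years).astype(np.int64)
    try:
        years = coord.dt.year.values.astype(np.int64)
    except (AttributeError, TypeError) as exc:
        raise ValueError("unsupported time coordinate") from exc
    if np.unique(years).size != years.size:
        raise ValueError("sub-annual time axis: more than one sample per year")
    return years


def read_gridded_netcdf(path: str | Path, var_name: str) -> GriddedField:
    """Read one variable from a CF-style NetCDF file into a GriddedField.

    The ocean mask is inferred from missing values (a cell missing in every
    year is land); latitude orientation and axis order are normalised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, decode_times=True) as ds:
        if var_name not in ds:
            raise KeyError(f"variable {var_name!r} not found in {path}")
        da = ds[var_name]
        tdim = _find_dim(da.dims, _TIME_NAMES, "time")
        ydim = _find_dim(da.dims, _LAT_NAMES, "lat")
        xdim = _find_dim(da.dims, _LON_NAMES, "lon")
        da = da.transpose(tdim, ydim, xdim)
        lat = da[ydim].values.astype(np.float64)
        if lat.size > 1 and lat[0] > lat[-1]:
            da = da.isel({ydim: slice(None, None, -1)})
            lat = da[ydim].values.astype(np.float64)
        lon = da[xdim].values.astype(np.float64)
        years = _years_from_time(da[tdim])
        values = da.values.astype(np.float64)
        units = str(da.attrs.get("units", ""))
    _check_regular(lat, "lat")
    _check_regular(lon, "lon")
    values = np.where(np.abs(values) >= np.abs(_FILL) * 0.999, np.nan, values)
    ocean = ~np.all(np.isnan(values), axis=0)
    grid = Grid(lat=lat, lon=lon, ocean_mask=ocean)
    return GriddedField(grid=grid, years=years, values=values,
                        var_name=var_name, units=units)


def write_gridded_netcdf(field: GriddedField, path: str | Path) -> None:
    """Write a GriddedField as a one-variable CF-style NetCDF file."""
    da = xr.DataArray(
        field.values,
        dims=("time", "lat", "lon"),
        coords={
            "time": field.years.astype(np.float64),
            "lat": field.grid.lat,
            "lon": field.grid.lon,
        },
        name=field.var_name,
        attrs={"units": field.units},
    )
    da["time"].attrs["units"] = "year"
    da["lat"].attrs["units"] = "degrees_north"
    da["lon"].attrs["units"] = "degrees_east"
    encoding = {field.var_name: {"_FillValue": _FILL, "dtype": "float64"}}
    da.to_dataset().to_netcdf(path, encoding=encoding)


# ---------------------------------------------------------------------------
# Area weighting

def area_weighted_mean(
    field_slice: np.ndarray,
    grid: Grid,
    subset_mask: Optional[np.ndarray] = None,
    weighted: bool = True,
) -> float:
    """Cosine-latitude weighted mean over ocean (optionally a subset).

    NaN cells are excluded.  ``weighted=False`` falls back to plain cell
    counting for sensitivity checks.
    """
    values = np.asarray(field_slice, dtype=np.float64)
    if values.shape != grid.shape:
        raise ValueError(f"slice shape {values.shape} != grid shape {grid.shape}")
    mask = grid.ocean_mask & np.isfinite(values)
    if subset_mask is not None:
        mask = mask & np.asarray(subset_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty subset: no unmasked ocean cell")
    w = grid.cell_area if weighted else np.ones(grid.shape)
    return float(np.sum(w[mask] * values[mask]) / np.sum(w[mask]))


def area_fraction(
    mask: np.ndarray,
    grid: Grid,
    within: Optional[np.ndarray] = None,
    weighted: bool = True,
) -> float:
    """Area fraction of ``mask`` within ``within`` (default: all ocean)."""
    base = grid.ocean_mask if within is None else (grid.ocean_mask & within)
    if not base.any():
        raise ValueError("empty subset")
    w = grid.cell_area if weighted else np.ones(grid.shape)
    return float(np.sum(w[base & mask]) / np.sum(w[base]))
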