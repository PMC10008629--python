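"""Readers/writers for synthetic inputs: NetCDF raster stacks and occurrence CSVs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from arcbio.synthetic_data.environment import EnvStack
from arcbio.synthetic_data.grid import Grid
from arcbio.synthetic_data.species import OCCURRENCE_COLUMNS

# the scipy backend writes classic NetCDF3 and needs no external C library
NETCDF_ENGINE = "scipy"


def env_to_dataset(env: EnvStack) -> xr.Dataset:
    grid = env.grid
    ds = xr.Dataset(
        {var: (("year", "lat", "lon"), arr) for var, arr in env.data.items()},
        coords={"year": list(env.years), "lat": grid.lat_centers, "lon": grid.lon_centers},
    )
    ds["region_id"] = (("lat", "lon"), grid.region_id)
    ds["land_mask"] = (("lat", "lon"), grid.land_mask.astype(np.int8))
    ds.attrs["cell_size_deg"] = grid.cell_size_deg
    return ds


def write_env_netcdf(env: EnvStack, path) -> None:
    env_to_dataset(env).to_netcdf(path, engine=NETCDF_ENGINE)


def read_env_netcdf(path) -> EnvStack:
    with xr.open_dataset(path, engine=NETCDF_ENGINE) as ds:
        ds = ds.load()
    grid = Grid(
        lat_centers=ds["lat"].values.astype(float),
        lon_centers=ds["lon"].values.astype(float),
        cell_size_deg=float(ds.attrs["cell_size_deg"]),
        region_id=ds["region_id"].values.astype(int),
        land_mask=ds["land_mask"].values.astype(bool),
    )
    data = {
        str(v): ds[v].values.astype(float)
        for v in ds.data_vars
        if v not in ("region_id", "land_mask")
    }
    return EnvStack(grid=grid, years=[int(y) for y in ds["year"].values], data=data)


def write_raster_netcdf(arrays: dict[str, np.ndarray], grid: Grid, path, year_coord=None) -> None:
    """Write named rasters (2-D, or 3-D with a leading year axis) to one NetCDF file."""
    data_vars = {}
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            data_vars[name] = (("lat", "lon"), arr)
        else:
            data_vars[name] = (("year", "lat", "lon"), arr)
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    if year_coord is not None:
        coords["year"] = list(year_coord)
    xr.Dataset(data_vars, coords=coords).to_netcdf(path, engine=NETCDF_ENGINE)


def write_occurrences_csv(occ: pd.DataFrame, path) -> None:
    occ[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def read_occurrences_csv(path) -> pd.DataFrame:
    occ = pd.read_csv(path)
    missing = set(OCCURRENCE_COLUMNS) - set(occ.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    return occ[OCCURRENCE_COLUMNS]
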