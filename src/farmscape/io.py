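"""File formats: CSV tables and NetCDF rasters (xarray, scipy backend)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec
from .synthetic import CLIMATE_LAYERS, PERIODS, ClimateConfig, ClimateRaster


def write_societies(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_societies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "lat", "lon", "family", "hunt", "gather", "fish", "agri", "pastoral"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"society table missing columns: {sorted(missing)}")
    return df


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    return df


read_origins = read_occurrences  # same schema: species, lat, lon


def climate_to_dataset(raster: ClimateRaster) -> xr.Dataset:
    g = raster.grid
    coords = {"lat": g.lat_centers, "lon": g.lon_centers}
    data = {}
    for period in PERIODS:
        for k, name in enumerate(CLIMATE_LAYERS):
            data[f"{period}__{name}"] = (("lat", "lon"), raster.data[period][k])
    data["valid_mask"] = (("lat", "lon"), raster.mask.astype(np.int8))
    ds = xr.Dataset(data, coords=coords)
    ds.attrs.update(
        lat_min=g.lat_min, lat_max=g.lat_max, lon_min=g.lon_min, lon_max=g.lon_max,
        n_lat=g.n_lat, n_lon=g.n_lon,
    )
    return ds


def write_climate(raster: ClimateRaster, path: str | Path) -> None:
    climate_to_dataset(raster).to_netcdf(path, engine="scipy")


def read_climate(path: str | Path) -> ClimateRaster:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    a = ds.attrs
    grid = GridSpec(
        n_lat=int(a["n_lat"]), n_lon=int(a["n_lon"]),
        lat_min=float(a["lat_min"]), lat_max=float(a["lat_max"]),
        lon_min=float(a["lon_min"]), lon_max=float(a["lon_max"]),
    )
    data = {
        period: np.stack([ds[f"{period}__{name}"].to_numpy() for name in CLIMATE_LAYERS])
        for period in PERIODS
    }
    raster = ClimateRaster(
        grid=grid, data=data, mask=ds["valid_mask"].to_numpy().astype(bool),
        config=ClimateConfig(),
    )
    raster.validate()
    return raster


def write_grid_stack(
    grids: dict[str, np.ndarray], grid: GridSpec, path: str | Path, dtype=np.float32
) -> None:
    """One NetCDF file holding several same-grid layers (e.g. per-species maps)."""
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    ds = xr.Dataset(
        {name: (("lat", "lon"), arr.astype(dtype)) for name, arr in grids.items()},
        coords=coords,
    )
    ds.to_netcdf(path, engine="scipy")


def read_grid_stack(path: str | Path) -> dict[str, np.ndarray]:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    return {name: ds[name].to_numpy() for name in ds.data_vars}
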