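"""File formats: NetCDF forcing/grids, CSV tables, and run manifests.

NetCDF files use CF-style dimensions ``cell``, ``layer`` and ``time`` and
are written with xarray's SciPy backend (NetCDF3, no external library
needed).  The variable-name table:

==================  ==============================  =====================
variable            dimensions                      units
==================  ==============================  =====================
latitude            (cell)                          degrees_north
longitude           (cell)                          degrees_east
area                (cell)                          m2
land                (cell)                          0/1 mask
permafrost          (cell)                          0/1 mask
layer_thickness     (layer)                         m
soil_temperature    (cell, time)                    degC (column mean)
soil_temperature_layers (cell, layer, time)         degC
water_scalar        (cell, time)                    1
oxygen_scalar       (cell, time)                    1
nitrogen_scalar     (cell, time)                    1
litter_input        (cell, time)                    g C m-2 yr-1
sand_fraction       (cell)                          1
clay_fraction       (cell)                          1
==================  ==============================  =====================

Small cases round-trip through CSV as well (grids, observations, tidy
ensemble tables); parameter sets use the CSV/JSON round trip on
:class:`~soilcarbon.params.ParameterSpace`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .calibration import ObservationSet
from .forcing import ForcingSeries
from .grid import Grid, SoilColumn, column_layout

__all__ = [
    "save_grid_csv",
    "load_grid_csv",
    "save_forcing_netcdf",
    "load_forcing_netcdf",
    "save_observations_csv",
    "load_observations_csv",
    "ensemble_frame",
    "save_endpoints_netcdf",
    "write_manifest",
]

_ENGINE = "scipy"  # NetCDF3 backend, available without the netCDF4 library


def save_grid_csv(grid: Grid, path) -> None:
    """One row per cell: ids, coordinates, area, masks."""
    pd.DataFrame({
        "cell_id": np.asarray(grid.cell_ids),
        "latitude": grid.latitude,
        "longitude": grid.longitude,
        "area": grid.area,
        "land": np.asarray(grid.land, dtype=int),
        "permafrost": np.asarray(grid.permafrost, dtype=int),
    }).to_csv(path, index=False)


def load_grid_csv(path) -> Grid:
    df = pd.read_csv(path)
    return Grid(
        cell_ids=df["cell_id"].to_numpy(),
        latitude=df["latitude"].to_numpy(float),
        longitude=df["longitude"].to_numpy(float),
        area=df["area"].to_numpy(float),
        land=df["land"].to_numpy(bool),
        permafrost=df["permafrost"].to_numpy(bool),
    )


def save_forcing_netcdf(forcing: ForcingSeries, path, column: SoilColumn = None) -> None:
    """Write a ForcingSeries (and optionally the soil column) as NetCDF."""
    column = column if column is not None else column_layout()
    ds = xr.Dataset(
        data_vars={
            "soil_temperature": (("cell", "time"), forcing.temperature),
            "soil_temperature_layers": (("cell", "layer", "time"),
                                        forcing.temperature_layers),
            "water_scalar": (("cell", "time"), forcing.water),
            "oxygen_scalar": (("cell", "time"), forcing.oxygen),
            "nitrogen_scalar": (("cell", "time"), forcing.nitrogen),
            "litter_input": (("cell", "time"), forcing.litter),
            "sand_fraction": (("cell",), forcing.sand),
            "clay_fraction": (("cell",), forcing.clay),
            "layer_thickness": (("layer",), column.thickness),
        },
        coords={"time": ("time", np.asarray(forcing.time, dtype=float))},
        attrs={"resolution": forcing.resolution,
               "litter_units": "g C m-2 yr-1",
               "temperature_units": "degC"},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def load_forcing_netcdf(path) -> ForcingSeries:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return ForcingSeries(
            time=ds["time"].values.astype(float),
            temperature=ds["soil_temperature"].values,
            temperature_layers=ds["soil_temperature_layers"].values,
            water=ds["water_scalar"].values,
            oxygen=ds["oxygen_scalar"].values,
            nitrogen=ds["nitrogen_scalar"].values,
            litter=ds["litter_input"].values,
            sand=ds["sand_fraction"].values,
            clay=ds["clay_fraction"].values,
            resolution=str(ds.attrs["resolution"]),
        )


def save_observations_csv(obs: ObservationSet, path) -> None:
    pd.DataFrame({
        "cell_index": obs.cell_index,
        "z": obs.z,
        "sigma": obs.sigma,
        "depth_top": obs.interval[:, 0],
        "depth_bottom": obs.interval[:, 1],
        "source": list(obs.source),
    }).to_csv(path, index=False)


def load_observations_csv(path) -> ObservationSet:
    df = pd.read_csv(path)
    return ObservationSet(
        cell_index=df["cell_index"].to_numpy(int),
        z=df["z"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float),
        interval=df[["depth_top", "depth_bottom"]].to_numpy(float),
        source=tuple(df["source"]),
    )


def ensemble_frame(runs) -> pd.DataFrame:
    """Tidy (member, year, global_total_pg, valid) table from EnsembleRuns.

    Year 0 is the initial (steady-state) total; invalid members appear with
    NaN totals so member accounting stays complete.
    """
    rows = []
    for r in runs:
        for year, total in enumerate(r.trajectory):
            rows.append((r.member, year, total, r.valid))
    return pd.DataFrame(rows, columns=["member", "year", "global_total_pg",
                                       "valid"])


def save_endpoints_netcdf(model, states_start, states_end, grid, path) -> None:
    """Per-cell start/end soil-C stocks (g C m-2) of one ensemble, NetCDF.

    ``states_*`` are (M, n_cells) per-cell totals (see
    :func:`~soilcarbon.projection.cell_totals`).
    """
    ds = xr.Dataset(
        data_vars={
            "stock_start": (("member", "cell"), np.asarray(states_start, float)),
            "stock_end": (("member", "cell"), np.asarray(states_end, float)),
            "area": (("cell",), np.asarray(grid.area, float)),
        },
        attrs={"model": model.kind, "units": "g C m-2"},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def write_manifest(run_dir, entries: dict) -> Path:
    """Write ``manifest.json`` listing a run's artifacts and settings."""
    run_dir = Path(run_dir)
    path = run_dir / "manifest.json"
    payload = {}
    for key, value in entries.items():
        if isinstance(value, Path):
            value = str(value)
        payload[key] = value
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
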