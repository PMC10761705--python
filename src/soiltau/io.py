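"""File I/O: CSV for site tables and incubation series, NetCDF (via
xarray's scipy backend) for gridded fields and forcing, JSON for
posterior summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .types import IncubationSeries, Posterior, ScenarioForcing, TauMaps

_NC_ENGINE = "scipy"  # netCDF3 backend, no external library needed


# ---------------------------------------------------------------------------
# incubation series
# ---------------------------------------------------------------------------

def write_series_csv(series_list, path, metadata_path=None):
    """Write flux series as tidy CSV (site_id, time_d, flux_mgC_g_d) with a
    per-site metadata sidecar."""
    path = Path(path)
    rows = []
    meta_rows = []
    for s in series_list:
        for t, fl in zip(s.times, s.fluxes):
            rows.append({"site_id": s.site_id, "time_d": t, "flux_mgC_g_d": fl})
        meta_rows.append({
            "site_id": s.site_id, "c_tot": s.c_tot, "incubation_t": s.incubation_t,
            "duration": s.duration, **s.metadata,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".meta.csv")
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    return path, meta_path


def read_series_csv(path, metadata_path=None):
    """Read flux series written by :func:`write_series_csv`."""
    path = Path(path)
    meta_path = Path(metadata_path) if metadata_path else path.with_suffix(".meta.csv")
    data = pd.read_csv(path)
    meta = pd.read_csv(meta_path).set_index("site_id") if meta_path.exists() else None
    out = []
    for site_id, grp in data.groupby("site_id", sort=False):
        times = grp["time_d"].to_numpy(float)
        fluxes = grp["flux_mgC_g_d"].to_numpy(float)
        kw = {"c_tot": None, "incubation_t": np.nan, "duration": float(times[-1]),
              "metadata": {}}
        if meta is not None and site_id in meta.index:
            row = meta.loc[site_id].to_dict()
            kw["c_tot"] = row.pop("c_tot", None)
            kw["incubation_t"] = row.pop("incubation_t", np.nan)
            kw["duration"] = row.pop("duration", float(times[-1]))
            kw["metadata"] = row
        out.append(IncubationSeries(site_id=str(site_id), times=times,
                                    fluxes=fluxes, **kw))
    return out


# ---------------------------------------------------------------------------
# gridded products
# ---------------------------------------------------------------------------

def world_to_dataset(world) -> xr.Dataset:
    coords = {"lat": ("lat", world.lat, {"units": "degrees_north"}),
              "lon": ("lon", world.lon, {"units": "degrees_east"}),
              "pool": ("pool", ["fast", "slow", "passive"])}
    data = {name: (("lat", "lon"), fld) for name, fld in world.covariates.items()}
    data["true_tau"] = (("pool", "lat", "lon"), world.true_tau,
                        {"units": "yr", "long_name": "intrinsic turnover time at 15C"})
    data["true_fractions"] = (("pool", "lat", "lon"), world.true_fractions)
    data["soc_stock"] = (("lat", "lon"), world.soc_stock, {"units": "gC m-2"})
    data["npp"] = (("lat", "lon"), world.npp, {"units": "gC m-2 yr-1"})
    data["tau_apparent"] = (("lat", "lon"), world.tau_a, {"units": "yr"})
    data["land_mask"] = (("lat", "lon"), world.land_mask.astype(np.int8))
    return xr.Dataset(data, coords=coords, attrs={"Conventions": "CF-1.8"})


def write_world_netcdf(world, path):
    world_to_dataset(world).to_netcdf(path, engine=_NC_ENGINE)
    return Path(path)


def forcing_to_dataset(forcing: ScenarioForcing, lat, lon) -> xr.Dataset:
    coords = {"time": ("time", forcing.years, {"units": "year"}),
              "lat": ("lat", lat, {"units": "degrees_north"}),
              "lon": ("lon", lon, {"units": "degrees_east"})}
    dims = ("time", "lat", "lon")
    return xr.Dataset(
        {"npp": (dims, forcing.npp, {"units": "gC m-2 yr-1"}),
         "tas": (dims, forcing.tas, {"units": "degC"}),
         "pr": (dims, forcing.pr, {"units": "mm yr-1"})},
        coords=coords,
        attrs={"scenario": forcing.scenario, "model": forcing.model,
               "Conventions": "CF-1.8"},
    )


def write_forcing_netcdf(forcing: ScenarioForcing, lat, lon, path):
    forcing_to_dataset(forcing, lat, lon).to_netcdf(path, engine=_NC_ENGINE)
    return Path(path)


def read_forcing_netcdf(path) -> ScenarioForcing:
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        return ScenarioForcing(
            years=ds["time"].values.astype(int),
            npp=ds["npp"].values, tas=ds["tas"].values, pr=ds["pr"].values,
            scenario=str(ds.attrs.get("scenario", "")),
            model=str(ds.attrs.get("model", "")),
        )


def taumaps_to_dataset(maps: TauMaps) -> xr.Dataset:
    coords = {"pool": ("pool", ["fast", "slow", "passive"])}
    if maps.lat is not None:
        coords["lat"] = ("lat", maps.lat, {"units": "degrees_north"})
        coords["lon"] = ("lon", maps.lon, {"units": "degrees_east"})
    dims3 = ("pool", "lat", "lon")
    return xr.Dataset(
        {"tau": (dims3, maps.tau, {"units": "yr"}),
         "tau_std": (dims3, maps.tau_std, {"units": "yr"}),
         "fraction": (dims3, maps.fractions),
         "tau_weighted": (("lat", "lon"), maps.weighted, {"units": "yr"})},
        coords=coords, attrs={"Conventions": "CF-1.8"},
    )


def write_taumaps_netcdf(maps: TauMaps, path):
    taumaps_to_dataset(maps).to_netcdf(path, engine=_NC_ENGINE)
    return Path(path)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def posterior_to_json(post: Posterior, path=None):
    doc = {
        "acceptance_rate": post.acceptance_rate,
        "burn_in": post.burn_in,
        "sigma": post.sigma,
        "n_draws": int(post.chains.shape[0]),
        **post.summaries,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc
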