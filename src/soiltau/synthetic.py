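"""Synthetic worlds with known ground truth for every pipeline stage.

The generator emulates (i) incubation CO2-flux series as noisy
realizations of the three-pool forward model, (ii) a gridded world whose
covariates are smoothed Gaussian random fields plus latitudinal
gradients, with intrinsic turnover times tied to the covariates through a
smooth, learnable mapping (positively correlated with mean annual
temperature), stocks constructed at the refined model's closed-form
steady state, and (iii) an ESM-like ensemble generated by the
reduced-complexity model itself with spatially uniform, deliberately
biased intrinsic turnover times — so every calibration stage has an exact
recoverable truth.

Default magnitudes follow field-typical values: global-mean intrinsic
turnover near (0.3, 6.7, 400) yr for the fast/slow/passive pools at
15 degC, CMIP6-like scenario ramps, and a ~30% ensemble overestimate of
turnover times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .emulator import run_emulator, steady_state
from .kinetics import default_q10, forward_flux
from .refined import apparent_turnover, refined_decay_rates
from .types import (EmulatorParams, IncubationSeries, PoolParams, PoolState,
                    RefinedParams, ScenarioForcing, Trajectory)

#: scenario ramps by 2100 relative to the 2000-2014 baseline:
#: warming (degC), NPP gain (fraction, CO2 fertilization in the ESMs),
#: precipitation gain (fraction)
SCENARIOS = {
    "ssp126": {"dT": 1.8, "npp_gain": 0.15, "pr_gain": 0.02},
    "ssp245": {"dT": 3.2, "npp_gain": 0.29, "pr_gain": 0.04},
    "ssp585": {"dT": 5.2, "npp_gain": 0.50, "pr_gain": 0.07},
}

#: assumed warming of the 2000-2014 baseline above the 1850-1900 mean (degC)
PREINDUSTRIAL_OFFSET = 0.85

# per-model reduced-complexity truths for the synthetic ensemble
_MODEL_Q10 = (1.7, 1.9, 2.1, 1.8, 2.0)
_MODEL_B = (0.7, 0.9, 0.8, 0.75, 0.85)
_MODEL_RF = (0.40, 0.45, 0.50, 0.42, 0.48)
_MODEL_RS = (0.08, 0.10, 0.12, 0.09, 0.11)
_MODEL_T_BIAS = (1.2, -0.8, 0.5, -0.3, 0.9)
_MODEL_PR_FAC = (1.15, 0.90, 1.05, 0.95, 1.10)
_MODEL_NPP_FAC = (1.10, 0.95, 1.05, 0.98, 1.08)


@dataclass
class WorldConfig:
    """Ground-truth constants of the synthetic world."""

    lat_range: tuple = (-55.0, 70.0)
    lon_range: tuple = (-180.0, 180.0)
    # refined-model truth (carbon quality-temperature ordered Q10)
    q10: tuple = (2.0, 2.8, 3.2)
    b: float = 0.5
    r_f: float = 0.45
    r_s: float = 0.05
    r_root_frac: float = 0.07
    # covariate -> log10(tau at 15 degC) mapping; slopes are per degC MAT
    tau_center: tuple = (0.3, 6.68, 398.0)
    mat_slope: tuple = (0.022, 0.026, 0.024)
    ndvi_slope: tuple = (0.10, 0.0, 0.0)
    soc_slope: tuple = (0.0, -0.008, -0.006)
    tau_jitter: tuple = (0.03, 0.025, 0.02)
    ocean_fraction: float = 0.15
    hist_years: tuple = (2000, 2014)
    tas_noise: float = 0.2     # interannual sd, degC
    pr_noise: float = 0.03     # fractional
    npp_noise: float = 0.02    # fractional


@dataclass
class SyntheticWorld:
    """Gridded ground truth: covariates, turnover, stocks and climate."""

    lat: np.ndarray
    lon: np.ndarray
    covariates: dict                  # name -> (nlat, nlon) field
    true_tau: np.ndarray              # (3, nlat, nlon), yr at 15 degC
    true_fractions: np.ndarray        # (3, nlat, nlon)
    pools: PoolState                  # steady-state stocks, gC m^-2
    soc_stock: np.ndarray             # total, gC m^-2 (0-1 m)
    npp: np.ndarray                   # climatological, gC m^-2 yr^-1
    tau_a: np.ndarray                 # apparent turnover truth, yr
    land_mask: np.ndarray
    climate: ScenarioForcing          # observed yearly series 2000-2014
    true_params: RefinedParams
    config: WorldConfig = field(default_factory=WorldConfig)

    @property
    def n_cells(self) -> int:
        return int(self.land_mask.sum())

    def climatology(self) -> dict:
        return {
            "tas": self.climate.tas.mean(axis=0),
            "pr": self.climate.pr.mean(axis=0),
            "npp": self.climate.npp.mean(axis=0),
        }


@dataclass
class EsmMember:
    name: str
    params: EmulatorParams
    forcing: dict      # scenario -> ScenarioForcing (2000-2100)
    pools: dict        # scenario -> Trajectory (2000-2100)


@dataclass
class EsmEnsemble:
    members: list
    tau_bias_factor: float
    preindustrial_offset: float = PREINDUSTRIAL_OFFSET

    @property
    def tau_i(self) -> np.ndarray:
        """(n_models, 3) array of the members' uniform turnover times."""
        return np.stack([m.params.tau_i for m in self.members])


# ---------------------------------------------------------------------------
# incubation series
# ---------------------------------------------------------------------------

def gen_incubation_series(
    pool_params: PoolParams,
    c_tot: float,
    temperature: float,
    duration: float,
    sampling_interval: float = 7.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    site_id: str = "synthetic",
    metadata: dict | None = None,
) -> IncubationSeries:
    """Noisy realization of the three-pool flux model.

    Noiseless fluxes follow the forward model exactly; measurement noise
    is i.i.d. zero-mean Gaussian with standard deviation ``noise_sd``.
    """
    if c_tot <= 0:
        raise ValueError("c_tot must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    pool_params.validate()
    times = np.arange(0.0, duration + 0.5 * sampling_interval, sampling_interval)
    times = times[times <= duration]
    fluxes = forward_flux(pool_params, c_tot, times)
    if noise_sd > 0:
        fluxes = fluxes + np.random.default_rng(seed).normal(0.0, noise_sd, times.shape)
    meta = {"aerobic": True, "substrate_added": False}
    meta.update(metadata or {})
    return IncubationSeries(
        site_id=site_id, times=times, fluxes=fluxes, c_tot=float(c_tot),
        incubation_t=float(temperature), duration=float(duration), metadata=meta,
    )


# ---------------------------------------------------------------------------
# gridded world
# ---------------------------------------------------------------------------

def _grf(rng, shape, sigma=2.0):
    """Smoothed, unit-variance Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                        mode=("nearest", "wrap"))
    return (f - f.mean()) / (f.std() + 1e-12)


def gen_world(n_lat: int = 20, n_lon: int = 20, seed: int = 0,
              config: WorldConfig | None = None) -> SyntheticWorld:
    """Generate a gridded world with known turnover truth.

    Deterministic under ``seed``; grids smaller than 2x2 are rejected.
    """
    if n_lat < 2 or n_lon < 2:
        raise ValueError("grid must be at least 2x2")
    cfg = config or WorldConfig()
    rng = np.random.default_rng(seed)
    shape = (n_lat, n_lon)

    lat_lo, lat_hi = cfg.lat_range
    dlat = (lat_hi - lat_lo) / n_lat
    lat = lat_lo + dlat * (np.arange(n_lat) + 0.5)
    lon_lo, lon_hi = cfg.lon_range
    dlon = (lon_hi - lon_lo) / n_lon
    lon = lon_lo + dlon * (np.arange(n_lon) + 0.5)
    lat2d = np.repeat(lat[:, None], n_lon, axis=1)

    g = [_grf(rng, shape) for _ in range(15)]
    mat = np.clip(27.0 - 0.55 * np.abs(lat2d) + 5.0 * g[0], -20.0, 32.0)
    map_ = np.clip(150.0 + 2300.0 * np.exp(-((np.abs(lat2d) / 28.0) ** 2))
                   + 400.0 * g[1], 60.0, 4000.0)
    ndvi = np.clip(0.05 + 0.012 * (mat + 20.0) + 8e-5 * map_ + 0.10 * g[2],
                   0.02, 0.95)
    npp = np.clip(40.0 + 1250.0 * ndvi * map_ / (map_ + 1000.0) + 30.0 * g[3],
                  20.0, 1500.0)
    clay = np.clip(0.22 + 0.09 * g[4], 0.03, 0.55)
    silt = np.clip(0.32 + 0.08 * g[5], 0.05, 0.60)
    sand = np.maximum(1.0 - 0.03 - clay - silt, 0.02)
    total_tex = clay + silt + sand
    over = total_tex > 1.0
    scale = np.where(over, 0.97 / total_tex, 1.0)
    clay, silt, sand = clay * scale, silt * scale, sand * scale
    soc_pct = np.clip(6.5 - 0.16 * mat + 8e-4 * map_ + 0.8 * g[6], 0.4, 14.0)
    bulk_density = np.clip(1.45 - 0.045 * soc_pct + 0.07 * g[7], 0.5, 1.8)
    ph = np.clip(7.4 - 9e-4 * map_ + 0.5 * g[8], 3.8, 8.8)
    tn = np.clip(soc_pct / (11.0 + 2.0 * np.clip(g[9], -2, 2)), 0.02, 1.5)
    cn = soc_pct / tn

    land_mask = g[10] > np.quantile(g[10], cfg.ocean_fraction)

    centers = np.log10(np.asarray(cfg.tau_center))
    tau = np.empty((3, n_lat, n_lon))
    for p in range(3):
        log_tau = (
            centers[p]
            + cfg.mat_slope[p] * (mat - 10.0)
            + cfg.ndvi_slope[p] * (ndvi - 0.5)
            + cfg.soc_slope[p] * (soc_pct - 5.0)
            + cfg.tau_jitter[p] * g[12 + p]
        )
        tau[p] = 10.0**log_tau
    if not (np.all(tau[0] < tau[1]) and np.all(tau[1] < tau[2])):
        raise RuntimeError("generated turnover times violate pool ordering")

    # observed yearly climate, flat in the mean with interannual noise
    years = np.arange(cfg.hist_years[0], cfg.hist_years[1] + 1)
    ny = len(years)
    tas_series = mat[None] + cfg.tas_noise * rng.standard_normal((ny,) + shape)
    pr_series = map_[None] * (1.0 + cfg.pr_noise * rng.standard_normal((ny,) + shape))
    npp_series = npp[None] * (1.0 + cfg.npp_noise * rng.standard_normal((ny,) + shape))
    climate = ScenarioForcing(years, npp_series, tas_series, pr_series,
                              scenario="historical", model="obs")
    p_max = float(pr_series.max())

    params = RefinedParams(
        tau_i=tau, q10=np.asarray(cfg.q10, dtype=float), b=cfg.b, r_f=cfg.r_f,
        r_s=cfg.r_s, clay=clay, p_max=p_max, t_ref=15.0,
        r_root_frac=cfg.r_root_frac,
    )
    params.validate()

    # stocks at the refined model's steady state under climatological forcing
    tas_clim = tas_series.mean(axis=0)
    pr_clim = pr_series.mean(axis=0)
    npp_clim = npp_series.mean(axis=0)
    k = refined_decay_rates(tau, tas_clim, pr_clim, clay,
                            cfg.r_root_frac * npp_clim, params)
    pools = steady_state(npp_clim, k[0], k[1], k[2], cfg.r_f, cfg.r_s)
    soc_stock = pools.total()
    fractions = pools.pools / soc_stock
    tau_a = apparent_turnover(pools, k)

    covariates = {
        "mat": mat, "map": map_, "ndvi": ndvi, "bulk_density": bulk_density,
        "ph": ph, "soc": soc_pct, "tn": tn, "cn": cn, "silt": silt,
        "sand": sand, "clay": clay,
    }
    return SyntheticWorld(
        lat=lat, lon=lon, covariates=covariates, true_tau=tau,
        true_fractions=fractions, pools=pools, soc_stock=soc_stock,
        npp=npp_clim, tau_a=tau_a, land_mask=land_mask, climate=climate,
        true_params=params, config=cfg,
    )


def gen_site_records(
    world: SyntheticWorld,
    n_sites: int = 300,
    seed: int = 0,
    log10_noise_sd: float = 0.1,
    frac_noise_sd: float = 0.05,
    t_inc_range: tuple = (10.0, 30.0),
    q10_fn=default_q10,
):
    """Sample site-level inversion results from the world's truth.

    Turnover times carry multiplicative lognormal noise (``log10_noise_sd``
    dex); each site also reports its incubation temperature and the
    turnover value at that temperature, consistent with the Q10
    normalization (so re-normalizing recovers the noisy 15-degC value).
    Returns a pandas DataFrame with predictor and target columns.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    land = np.flatnonzero(world.land_mask.reshape(-1))
    if n_sites > len(land):
        raise ValueError("more sites than land cells")
    cells = rng.choice(land, size=n_sites, replace=False)
    ii, jj = np.unravel_index(cells, world.land_mask.shape)

    data = {"site_id": [f"site{n:04d}" for n in range(n_sites)],
            "lat": world.lat[ii], "lon": world.lon[jj]}
    for name, fld in world.covariates.items():
        data[name] = fld[ii, jj]
    t_inc = rng.uniform(*t_inc_range, size=n_sites)
    data["t_inc"] = t_inc
    q10 = np.asarray(q10_fn(t_inc), dtype=float)
    for p, pool in enumerate(("fast", "slow", "passive")):
        tau15 = world.true_tau[p, ii, jj] * 10.0 ** (
            log10_noise_sd * rng.standard_normal(n_sites))
        data[f"tau_{pool}"] = tau15
        data[f"tau_{pool}_at_tinc"] = tau15 / q10 ** ((t_inc - 15.0) / 10.0)
    fr = world.true_fractions[:, ii, jj] * np.exp(
        frac_noise_sd * rng.standard_normal((3, n_sites)))
    fr /= fr.sum(axis=0)
    for p, pool in enumerate(("fast", "slow", "passive")):
        data[f"f_{pool}"] = fr[p]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# ESM-like ensemble
# ---------------------------------------------------------------------------

def carbon_weighted_mean_tau(world: SyntheticWorld) -> np.ndarray:
    """Per-pool mean of the world's turnover maps weighted by pool stock
    (land cells, area-weighted)."""
    from .budget import cell_areas

    areas = cell_areas(world.lat, world.lon) * world.land_mask
    w = world.pools.pools * areas
    return (world.true_tau * w).sum(axis=(1, 2)) / w.sum(axis=(1, 2))


def gen_esm_ensemble(
    world: SyntheticWorld,
    n_models: int = 3,
    scenarios=("ssp126", "ssp245", "ssp585"),
    tau_bias_factor: float = 1.3,
    seed: int = 0,
    end_year: int = 2100,
) -> EsmEnsemble:
    """Generate an ensemble of synthetic ESMs with biased uniform tau_i.

    Each member is the reduced-complexity model itself, run from its own
    steady state over 2000-``end_year``, with spatially uniform intrinsic
    turnover times equal to the world's carbon-weighted mean times
    ``tau_bias_factor`` and member-specific (Q10, b, r_f, r_s) and
    climate/NPP biases.  Calibration on this output can therefore recover
    the generating parameters exactly up to optimizer tolerance.
    """
    if len(scenarios) == 0:
        raise ValueError("scenarios list must not be empty")
    if tau_bias_factor <= 0:
        raise ValueError("tau_bias_factor must be positive")
    if n_models > len(_MODEL_Q10):
        raise ValueError(f"at most {len(_MODEL_Q10)} synthetic models supported")
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenarios {sorted(unknown)}")

    tau_base = carbon_weighted_mean_tau(world) * tau_bias_factor
    years = np.arange(2000, end_year + 1)
    ramp = np.clip((years - 2014) / (2100 - 2014), 0.0, None)
    shape = world.land_mask.shape
    mat = world.covariates["mat"]
    map_ = world.covariates["map"]
    npp_clim = world.npp

    members = []
    for m in range(n_models):
        forcings, first_pass = {}, []
        for s_idx, scen in enumerate(scenarios):
            scen_cfg = SCENARIOS[scen]
            rng = np.random.default_rng([seed, m, s_idx])
            ny = len(years)
            tas = (mat[None] + _MODEL_T_BIAS[m] + scen_cfg["dT"] * ramp[:, None, None]
                   + 0.2 * rng.standard_normal((ny,) + shape))
            pr = (map_[None] * _MODEL_PR_FAC[m]
                  * (1.0 + scen_cfg["pr_gain"] * ramp[:, None, None])
                  * (1.0 + 0.03 * rng.standard_normal((ny,) + shape)))
            npp = (npp_clim[None] * _MODEL_NPP_FAC[m]
                   * (1.0 + scen_cfg["npp_gain"] * ramp[:, None, None])
                   * (1.0 + 0.02 * rng.standard_normal((ny,) + shape)))
            forcings[scen] = ScenarioForcing(years.copy(), npp, tas, pr,
                                             scenario=scen, model=f"ESM-{m}")
            first_pass.append(pr.max())
        p_max = float(max(first_pass))
        params = EmulatorParams(
            tau_i=tau_base.copy(), q10=_MODEL_Q10[m], t_ref=15.0,
            r_f=_MODEL_RF[m], r_s=_MODEL_RS[m], b=_MODEL_B[m], p_max=p_max,
        )
        params.validate()
        pools = {}
        for scen, forc in forcings.items():
            hist = forc.subset(2000, 2014)
            from .emulator import actual_decay_rate
            k0 = actual_decay_rate(params.tau_i, hist.tas.mean(axis=0),
                                   hist.pr.mean(axis=0), params)
            state0 = steady_state(hist.npp.mean(axis=0), k0[0], k0[1], k0[2],
                                  params.r_f, params.r_s)
            traj = run_emulator(params, forc, state0=state0)
            if not np.all(np.isfinite(traj.pools)) or np.any(traj.pools < 0):
                raise RuntimeError("synthetic ESM produced invalid pools")
            pools[scen] = traj
        members.append(EsmMember(name=f"ESM-{m}", params=params,
                                 forcing=forcings, pools=pools))
    return EsmEnsemble(members=members, tau_bias_factor=tau_bias_factor)
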