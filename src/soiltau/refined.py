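"""Observationally constrained three-pool model.

Decay rates extend the reduced-complexity form with mineral protection
and rhizosphere priming:

    k_p = (1/tau_i,p) * F(T) * F(P) * F(M) * F(RP_p)

F(T) uses pool-specific Q10 values (larger for more recalcitrant pools,
the carbon quality-temperature ordering) referenced to 15 degC.  F(M) is
an empirical clay-content scalar; F(RP) a Michaelis-Menten function of
root respiration (taken as a fixed fraction of NPP) applied to the slow
and passive pools only.

Calibration identifies the global scalars (Q10 per pool, b, r_f, r_s)
from gridded pool stocks and apparent turnover times under climatological
forcing; per-cell heterogeneity enters through the tau_i maps and clay.
"""

from __future__ import annotations

import numpy as np

from .emulator import _advance, steady_state
from .optimize import de_minimize
from .types import PoolState, RefinedParams, ScenarioForcing, Trajectory

#: DE bounds for (q10_fast, dq10_slow, dq10_passive, b, r_f, r_s); the
#: slow/passive Q10 are parameterized as non-negative increments so the
#: carbon quality-temperature ordering holds by construction.
DEFAULT_REFINED_BOUNDS = (
    (1.0, 4.0), (0.0, 2.5), (0.0, 2.5), (0.05, 3.0), (0.0, 1.0), (0.0, 1.0)
)


def modifier_M(clay):
    """Mineral-protection scalar as a function of clay fraction."""
    clay = np.asarray(clay, dtype=float)
    if np.any((clay < 0) | (clay > 1)):
        raise ValueError("clay fraction must lie in [0, 1]")
    return np.where(
        clay < 0.033,
        24.2 * clay,
        -2.1 * clay**2 + 6.2 * clay + 0.6,
    )


def modifier_RP(r_root):
    """Rhizosphere-priming scalar as a function of root respiration
    (gC m^-2 yr^-1); saturates at 1/3.47 for large root respiration."""
    r_root = np.asarray(r_root, dtype=float)
    if np.any(r_root < 0):
        raise ValueError("root respiration must be non-negative")
    return 1.0 / (1.0 + 2.47 * r_root / (13.01 + r_root))


def refined_decay_rates(tau_i, t, p, clay, r_root, params: RefinedParams) -> np.ndarray:
    """All-pool decay rates (3, ...) for given climate and modifiers."""
    tau_i = np.asarray(tau_i, dtype=float)
    t = np.asarray(t, dtype=float)
    f_t = params.q10.reshape((3,) + (1,) * t.ndim) ** ((t - params.t_ref) / 10.0)
    f_p = (np.asarray(p, dtype=float) / params.p_max) ** params.b
    f_m = modifier_M(clay)
    f_rp = modifier_RP(r_root)
    rp = np.stack([np.ones_like(f_rp * 1.0), f_rp, f_rp])  # fast pool unprimed
    return f_t * f_p * f_m * rp / tau_i


def refined_decay_rate(pool, tau_i, t, p, clay, r_root, params: RefinedParams):
    """Single-pool rate; ``pool`` is 'fast', 'slow' or 'passive' or 0..2."""
    idx = {"fast": 0, "slow": 1, "passive": 2}.get(pool, pool)
    f_t = params.q10[idx] ** ((np.asarray(t, dtype=float) - params.t_ref) / 10.0)
    f_p = (np.asarray(p, dtype=float) / params.p_max) ** params.b
    f_rp = modifier_RP(r_root) if idx > 0 else 1.0
    return f_t * f_p * modifier_M(clay) * f_rp / np.asarray(tau_i, dtype=float)


def apparent_turnover(state: PoolState, rates) -> np.ndarray:
    """Flux-weighted (realized) turnover time per cell (yr):
    tau_a = sum_p C_p / sum_p k_p C_p."""
    rates = np.asarray(rates, dtype=float)
    outflux = (rates * state.pools).sum(axis=0)
    return state.pools.sum(axis=0) / outflux


def _rates_for_year(params: RefinedParams, tas, pr, npp):
    r_root = params.r_root_frac * np.asarray(npp, dtype=float)
    return refined_decay_rates(params.tau_i, tas, pr, params.clay, r_root, params)


def project(
    params: RefinedParams,
    state0: PoolState,
    forcing: ScenarioForcing,
) -> Trajectory:
    """Run the refined model over a yearly forcing series.

    ``pools[t]`` is the state at the start of ``years[t]``; deterministic
    (no stochastic elements).
    """
    ny = len(forcing.years)
    pools = np.empty((ny,) + state0.pools.shape)
    pools[0] = state0.pools
    cur = state0.pools.copy()
    for t in range(ny - 1):
        k = _rates_for_year(params, forcing.tas[t], forcing.pr[t], forcing.npp[t])
        cur, _ = _advance(cur, forcing.npp[t], k, params.r_f, params.r_s, 1.0)
        pools[t + 1] = cur
    return Trajectory(years=forcing.years.copy(), pools=pools)


def closed_form_steady_state(params: RefinedParams, tas, pr, npp) -> PoolState:
    """Equilibrium pools under constant (climatological) forcing."""
    k = _rates_for_year(params, tas, pr, npp)
    return steady_state(npp, k[0], k[1], k[2], params.r_f, params.r_s)


def spin_up(
    params: RefinedParams,
    forcing: ScenarioForcing,
    tol: float = 1e-3,
    max_cycles: int = 200,
    state0: PoolState | None = None,
    mask=None,
):
    """Cycle the baseline forcing until carbon input balances decomposition.

    The convergence criterion is the cycle-mean |NPP - total
    decomposition| falling below ``tol`` times the cycle-mean NPP in every
    (unmasked) cell.  Starting from the closed-form steady state under the
    cycle-mean forcing (the default) this typically converges within a few
    cycles.

    Returns
    -------
    (PoolState, n_cycles)
    """
    if max_cycles < 30:
        raise ValueError("max_cycles must be at least 30")
    mean_npp = forcing.npp.mean(axis=0)
    if state0 is None:
        state0 = closed_form_steady_state(
            params, forcing.tas.mean(axis=0), forcing.pr.mean(axis=0), mean_npp
        )
    if mask is None:
        mask = np.ones(mean_npp.shape, dtype=bool)
    cur = state0.pools.copy()
    ny = len(forcing.years)
    for cycle in range(1, max_cycles + 1):
        resp_sum = np.zeros(mean_npp.shape)
        for t in range(ny):
            k = _rates_for_year(params, forcing.tas[t], forcing.pr[t], forcing.npp[t])
            cur, resp = _advance(cur, forcing.npp[t], k, params.r_f, params.r_s, 1.0)
            resp_sum += resp
        imbalance = np.abs(mean_npp - resp_sum / ny)
        if np.all(imbalance[mask] < tol * np.maximum(mean_npp[mask], 1e-12)):
            return PoolState(cur), cycle
    return PoolState(cur), max_cycles


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_refined(
    obs_pools,
    obs_tau_a,
    climatology: dict,
    tau_i,
    clay,
    p_max: float,
    bounds=DEFAULT_REFINED_BOUNDS,
    seed: int = 0,
    popsize: int = 40,
    maxiter: int = 300,
    mask=None,
    r_root_frac: float = 0.07,
    stock_weight: float = 1.0,
    tau_weight: float = 1.0,
):
    """Identify (Q10 per pool, b, r_f, r_s) from gridded observations.

    Parameters
    ----------
    obs_pools : array (3, nlat, nlon)
        Observed pool stocks (gridded SOC times per-pool fractions).
    obs_tau_a : array (nlat, nlon)
        Observed apparent turnover time (yr), e.g. radiocarbon-derived.
    climatology : dict with 'tas', 'pr', 'npp' fields (2000-2014 means).
    tau_i : array (3, nlat, nlon)
        Intrinsic turnover maps at 15 degC.
    clay : array (nlat, nlon)

    The combined objective is the per-pool normalized RMSE of the modeled
    steady-state stocks plus the mean squared error of log apparent
    turnover, equally weighted.  Cells with zero/non-finite SOC are
    masked out.  Returns (RefinedParams, info dict).
    """
    obs_pools = np.asarray(obs_pools, dtype=float)
    obs_tau_a = np.asarray(obs_tau_a, dtype=float)
    tau_i = np.asarray(tau_i, dtype=float)
    clay_arr = np.asarray(clay, dtype=float)
    grid_shape = obs_tau_a.shape
    tas = np.asarray(climatology["tas"], dtype=float).reshape(-1)
    pr = np.asarray(climatology["pr"], dtype=float).reshape(-1)
    npp = np.asarray(climatology["npp"], dtype=float).reshape(-1)

    valid = (
        np.isfinite(obs_pools).all(axis=0) & np.isfinite(obs_tau_a)
        & (obs_pools.sum(axis=0) > 0)
    ).reshape(-1)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool).reshape(-1)
    cells = np.flatnonzero(valid)

    obs_c = obs_pools.reshape(3, -1)[:, cells]          # (3, nc)
    obs_log_tau = np.log(obs_tau_a.reshape(-1)[cells])
    tau_c = tau_i.reshape(3, -1)[:, cells]
    x = (tas[cells] - 15.0) / 10.0                      # Q10 exponent
    f_p = (pr[cells] / p_max)
    f_m = modifier_M(clay_arr.reshape(-1)[cells])
    f_rp = modifier_RP(r_root_frac * npp[cells])
    npp_c = npp[cells]
    norm = np.abs(obs_c).mean(axis=1) + 1e-12           # (3,)
    log_fp = np.log(np.maximum(f_p, 1e-12))

    def objective(theta):  # (1, pop, 6) -> (1, pop)
        th = theta[0]
        q10 = np.stack([th[:, 0], th[:, 0] + th[:, 1], th[:, 0] + th[:, 1] + th[:, 2]])
        b, r_f, r_s = th[:, 3], th[:, 4], th[:, 5]
        fp_b = np.exp(b[None, :] * log_fp[:, None])     # (nc, pop)
        base = fp_b * f_m[:, None]                      # (nc, pop)
        k_f = q10[0][None, :] ** x[:, None] * base / tau_c[0][:, None]
        k_s = q10[1][None, :] ** x[:, None] * base * f_rp[:, None] / tau_c[1][:, None]
        k_p = q10[2][None, :] ** x[:, None] * base * f_rp[:, None] / tau_c[2][:, None]
        c_f = npp_c[:, None] / k_f
        c_s = r_f[None, :] * npp_c[:, None] / k_s
        c_p = r_f[None, :] * r_s[None, :] * npp_c[:, None] / k_p
        model = np.stack([c_f, c_s, c_p])               # (3, nc, pop)
        obs3 = obs_c[:, :, None]
        stock_err = np.sqrt(((model - obs3) ** 2).mean(axis=1)) / norm[:, None]
        tau_a = model.sum(axis=0) / (k_f * c_f + k_s * c_s + k_p * c_p)
        tau_err = ((np.log(tau_a) - obs_log_tau[:, None]) ** 2).mean(axis=0)
        return (stock_weight * stock_err.sum(axis=0) + tau_weight * tau_err)[None, :]

    res = de_minimize(objective, bounds, n_problems=1, seed=seed,
                      popsize=popsize, maxiter=maxiter)
    th = res.x[0]
    q10 = np.array([th[0], th[0] + th[1], th[0] + th[1] + th[2]])
    params = RefinedParams(
        tau_i=tau_i, q10=q10, b=float(th[3]), r_f=float(th[4]), r_s=float(th[5]),
        clay=clay_arr, p_max=p_max, t_ref=15.0, r_root_frac=r_root_frac,
    )
    params.validate()
    info = {
        "objective": float(res.fun[0]),
        "n_gen": res.n_gen,
        "degenerate": bool(res.degenerate[0]),
        "n_cells": len(cells),
        "mask": valid.reshape(grid_shape),
    }
    return params, info
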