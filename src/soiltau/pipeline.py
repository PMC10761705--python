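"""End-to-end orchestration: synthetic world -> constrained projections.

``run_pipeline`` wires every stage together on a synthetic world: sample
site-level inversions, upscale turnover maps, generate a biased ESM-like
ensemble, diagnose the reduced-complexity emulator per cell, calibrate
the refined model against "observed" stocks and apparent turnover for
each SOC x NPP data combination, spin up, bias-correct each ESM's future
forcing and project to 2100.  ``run_sensitivity`` re-wires the stages for
the sensitivity experiments (alternative temperature scaling of the site
normalization, ESM-sourced turnover or Q10, reduced vs refined model
form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import budget as bud
from .emulator import actual_decay_rate, calibrate_grid, steady_state, _advance
from .forcing import bias_correct_forcing
from .kinetics import activation_energy_from_q10, default_q10, normalize_arrhenius
from .refined import closed_form_steady_state, project, spin_up
from .synthetic import (EsmEnsemble, SyntheticWorld, _grf, gen_esm_ensemble,
                        gen_site_records, gen_world)
from .types import (PoolState, RefinedParams, ScenarioForcing, Trajectory)
from .upscaling import fit_all_models, predict_maps

SENSITIVITY_VARIANTS = ("SE1", "SE2", "SE3", "SE4", "SE5", "SE6")


@dataclass
class PipelineResult:
    world: SyntheticWorld
    sites: object
    tau_models: dict
    frac_models: dict
    tau_maps: object
    ensemble: EsmEnsemble
    emulator_fits: dict          # (model, scenario) -> calibrate_grid output
    refined_members: list        # [(label, RefinedParams, info)]
    spin_states: list            # [(PoolState, n_cycles)]
    corrected_forcing: dict      # (model, scenario) -> ScenarioForcing
    constrained: dict            # (model, scenario) -> mean Trajectory over combos
    original_delta: dict         # (model, scenario) -> DeltaResult
    constrained_delta: dict      # (model, scenario) -> DeltaResult
    delta_t: dict                # (model, scenario) -> warming above preindustrial
    budget: object
    summary: dict = field(default_factory=dict)


def covariate_source_combinations(world: SyntheticWorld, seed: int = 0):
    """Two climate x two soil covariate sources (truth plus a smoothly
    perturbed alternative of each), mimicking dataset disagreement."""
    rng = np.random.default_rng([seed, 77])
    shape = world.land_mask.shape
    cov = world.covariates
    clim_b = {
        "mat": cov["mat"] + 0.4 + 0.3 * _grf(rng, shape),
        "map": cov["map"] * (1.04 + 0.02 * _grf(rng, shape)),
    }
    soil_keys = ("bulk_density", "ph", "soc", "tn", "cn", "silt", "sand")
    soil_b = {k: cov[k] * (1.0 + 0.03 * _grf(rng, shape)) for k in soil_keys}
    combos = []
    for clim in ({}, clim_b):
        for soil in ({}, soil_b):
            combos.append({**cov, **clim, **soil})
    return combos


def _observation_sources(world: SyntheticWorld, seed: int = 0):
    """Two gridded SOC and two NPP 'datasets' (truth + perturbed)."""
    rng = np.random.default_rng([seed, 101])
    shape = world.land_mask.shape
    soc = {
        "soc_a": world.soc_stock,
        "soc_b": world.soc_stock * (1.0 + 0.05 * _grf(rng, shape)),
    }
    npp = {
        "npp_a": world.npp,
        "npp_b": world.npp * (1.0 + 0.04 * _grf(rng, shape)),
    }
    return soc, npp


def global_warming(forcing: ScenarioForcing, lat, lon,
                   baseline=(2000, 2014), period=(2080, 2099),
                   preindustrial_offset: float = 0.85) -> float:
    """Area-weighted global warming of ``period`` above the 1850-1900 mean."""
    areas = bud.cell_areas(lat, lon)
    w = areas / areas.sum()

    def mean_t(window):
        sel = (forcing.years >= window[0]) & (forcing.years <= window[1])
        return float((forcing.tas[sel].mean(axis=0) * w).sum())

    return mean_t(period) - mean_t(baseline) + preindustrial_offset


def calibrate_refined_ensemble(world, tau_maps, seed: int = 0, maxiter: int = 250,
                               popsize: int = 30):
    """Refined-model calibration for each SOC x NPP data combination."""
    from .refined import calibrate_refined

    soc_sources, npp_sources = _observation_sources(world, seed)
    clim = world.climatology()
    members = []
    for soc_name, soc in soc_sources.items():
        for npp_name, npp in npp_sources.items():
            obs_pools = soc[None] * tau_maps.fractions
            clim_combo = {**clim, "npp": npp}
            params, info = calibrate_refined(
                obs_pools, world.tau_a, clim_combo, tau_maps.tau,
                world.covariates["clay"], world.true_params.p_max,
                seed=seed, mask=world.land_mask, maxiter=maxiter, popsize=popsize,
            )
            members.append((f"{soc_name}+{npp_name}", params, info))
    return members


def _extend_forcing_with_history(world, corrected: ScenarioForcing) -> ScenarioForcing:
    """Projection forcing 2000-2100: observed history then corrected future."""
    hist = world.climate
    sel = corrected.years > hist.years[-1]
    return ScenarioForcing(
        years=np.concatenate([hist.years, corrected.years[sel]]),
        npp=np.concatenate([hist.npp, corrected.npp[sel]]),
        tas=np.concatenate([hist.tas, corrected.tas[sel]]),
        pr=np.concatenate([hist.pr, corrected.pr[sel]]),
        scenario=corrected.scenario, model=corrected.model,
    )


def run_pipeline(
    seed: int = 0,
    n_lat: int = 20,
    n_lon: int = 20,
    n_models: int = 3,
    scenarios=("ssp126", "ssp245", "ssp585"),
    n_sites: int = 300,
    tau_bias_factor: float = 1.3,
    calibrate_emulator: bool = True,
    cv_config: dict | None = None,
    refined_maxiter: int = 250,
    world: SyntheticWorld | None = None,
) -> PipelineResult:
    """Run the full constrained-projection analysis on a synthetic world."""
    if world is None:
        world = gen_world(n_lat, n_lon, seed)
    sites = gen_site_records(world, n_sites=n_sites, seed=seed + 1)
    tau_models, frac_models = fit_all_models(sites, cv_config=cv_config, seed=seed)
    tau_maps = predict_maps(
        tau_models, frac_models, covariate_source_combinations(world, seed),
        lat=world.lat, lon=world.lon, mask=world.land_mask,
    )
    ensemble = gen_esm_ensemble(world, n_models=n_models, scenarios=scenarios,
                                tau_bias_factor=tau_bias_factor, seed=seed)

    emulator_fits = {}
    if calibrate_emulator:
        for member in ensemble.members:
            for scen in scenarios:
                emulator_fits[(member.name, scen)] = calibrate_grid(
                    member.pools[scen], member.forcing[scen],
                    member.params.tau_i, member.params.q10, member.params.t_ref,
                    member.params.p_max, mask=world.land_mask, seed=seed,
                )

    refined_members = calibrate_refined_ensemble(world, tau_maps, seed=seed,
                                                 maxiter=refined_maxiter)
    spin_states = [
        spin_up(params, world.climate, mask=world.land_mask)
        for _, params, _ in refined_members
    ]

    obs_clim = world.climatology()
    corrected, constrained = {}, {}
    original_delta, constrained_delta, delta_t = {}, {}, {}
    points = {"dt": [], "soc_c": [], "soc_o": []}
    for member in ensemble.members:
        for scen in scenarios:
            key = (member.name, scen)
            corr = bias_correct_forcing(member.forcing[scen], obs_clim)
            corrected[key] = corr
            run_forcing = _extend_forcing_with_history(world, corr)
            trajs = [
                project(params, state, run_forcing)
                for (_, params, _), (state, _) in zip(refined_members, spin_states)
            ]
            mean_traj = Trajectory(trajs[0].years.copy(),
                                   np.mean([t.pools for t in trajs], axis=0))
            constrained[key] = mean_traj
            constrained_delta[key] = bud.delta_stock(
                mean_traj, world.lat, world.lon, mask=world.land_mask,
                scenario=scen, model=member.name)
            original_delta[key] = bud.delta_stock(
                member.pools[scen], world.lat, world.lon, mask=world.land_mask,
                scenario=scen, model=member.name)
            delta_t[key] = global_warming(member.forcing[scen], world.lat,
                                          world.lon,
                                          preindustrial_offset=ensemble.preindustrial_offset)
            points["dt"].append(delta_t[key])
            points["soc_c"].append(_soc_change_from_2020(mean_traj, world))
            points["soc_o"].append(_soc_change_from_2020(member.pools[scen], world))

    budget_result = None
    if len(points["dt"]) >= 3:
        budget_result = bud.budget_reduction(points["dt"], points["soc_c"],
                                             points["soc_o"])

    result = PipelineResult(
        world=world, sites=sites, tau_models=tau_models, frac_models=frac_models,
        tau_maps=tau_maps, ensemble=ensemble, emulator_fits=emulator_fits,
        refined_members=refined_members, spin_states=spin_states,
        corrected_forcing=corrected, constrained=constrained,
        original_delta=original_delta, constrained_delta=constrained_delta,
        delta_t=delta_t, budget=budget_result,
    )
    result.summary = summarize(result)
    return result


def _soc_change_from_2020(traj: Trajectory, world, period=(2080, 2099)) -> float:
    """Global stock change (PgC) of the period mean relative to 2020."""
    fld = traj.period_mean_total(*period) - traj.state_at(2020).total()
    return bud.global_total(fld, world.lat, world.lon, mask=world.land_mask)


def ensemble_mean_delta(deltas: dict, scenario: str) -> np.ndarray:
    fields = [d.field for (m, s), d in deltas.items() if s == scenario]
    return np.mean(fields, axis=0)


def reversal_statistics(result: PipelineResult, scenario: str = "ssp585") -> dict:
    """Sink-to-source reversal diagnostics for one scenario's ensemble mean."""
    world = result.world
    orig = ensemble_mean_delta(result.original_delta, scenario)
    cons = ensemble_mean_delta(result.constrained_delta, scenario)
    m = world.land_mask
    frac_below = float(np.mean(cons[m] < orig[m]))
    return {
        "scenario": scenario,
        "fraction_cells_constrained_below_original": frac_below,
        "original_total_pgc": bud.global_total(orig, world.lat, world.lon, mask=m),
        "constrained_total_pgc": bud.global_total(cons, world.lat, world.lon, mask=m),
    }


def summarize(result: PipelineResult) -> dict:
    """Headline numbers of a pipeline run."""
    world = result.world
    out = {
        "n_land_cells": int(world.land_mask.sum()),
        "cv_r2": {p: result.tau_models[p].cv_r2 for p in ("fast", "slow", "passive")},
        "spinup_total_stock_pgc": [
            bud.global_total(state.total(), world.lat, world.lon, mask=world.land_mask)
            for state, _ in result.spin_states
        ],
    }
    scen_names = sorted({s for (_, s) in result.original_delta})
    out["delta_soc_pgc"] = {
        s: {
            "original": float(np.mean([d.total_pgc for (m2, s2), d in
                                       result.original_delta.items() if s2 == s])),
            "constrained": float(np.mean([d.total_pgc for (m2, s2), d in
                                          result.constrained_delta.items() if s2 == s])),
        }
        for s in scen_names
    }
    if result.budget is not None:
        out["budget_reduction_fraction"] = dict(result.budget.reduction_fraction)
    return out


# ---------------------------------------------------------------------------
# sensitivity experiments
# ---------------------------------------------------------------------------

def run_reduced_percell(tau_3g, q10_pool, t_ref, b_cell, r_f_cell, r_s_cell,
                        p_max, forcing: ScenarioForcing,
                        state0: PoolState | None = None) -> Trajectory:
    """Reduced-complexity run with per-cell tau maps, transfer coefficients
    and moisture exponents, and per-pool Q10 (climate-only modifiers)."""
    tau_3g = np.asarray(tau_3g, dtype=float)
    q10_pool = np.asarray(q10_pool, dtype=float).reshape(3, *([1] * (tau_3g.ndim - 1)))
    ny = len(forcing.years)

    def rates(t_fld, p_fld):
        f_t = q10_pool ** ((np.asarray(t_fld) - t_ref) / 10.0)
        f_p = (np.asarray(p_fld) / p_max) ** b_cell
        return f_t * f_p / tau_3g

    if state0 is None:
        k0 = rates(forcing.tas[:15].mean(axis=0), forcing.pr[:15].mean(axis=0))
        state0 = steady_state(forcing.npp[:15].mean(axis=0), k0[0], k0[1], k0[2],
                              r_f_cell, r_s_cell)
    pools = np.empty((ny,) + state0.pools.shape)
    pools[0] = state0.pools
    cur = state0.pools.copy()
    for t in range(ny - 1):
        k = rates(forcing.tas[t], forcing.pr[t])
        cur, _ = _advance(cur, forcing.npp[t], k, r_f_cell, r_s_cell, 1.0)
        pools[t + 1] = cur
    return Trajectory(forcing.years.copy(), pools)


def arrhenius_site_tau(sites, q10_fn=default_q10):
    """Re-normalize site turnover times to 15 degC with an Arrhenius factor
    whose activation energy matches Q10 at each site's incubation
    temperature.  Returns a copy of the site table with replaced tau_*."""
    out = sites.copy()
    t_inc = out["t_inc"].to_numpy(float)
    ea = activation_energy_from_q10(q10_fn(t_inc), t_inc)
    for pool in ("fast", "slow", "passive"):
        out[f"tau_{pool}"] = normalize_arrhenius(
            out[f"tau_{pool}_at_tinc"].to_numpy(float), t_inc, ea)
    return out


def _ensemble_mean_passive_tau(ensemble: EsmEnsemble) -> float:
    return float(ensemble.tau_i[:, 2].mean())


def run_sensitivity(variant: str, ctx: PipelineResult, seed: int = 0) -> dict:
    """Run one sensitivity experiment on a completed pipeline context.

    default : reproduce the pipeline's constrained projection wiring.
    SE1 : Arrhenius (not Q10) site normalization -> new tau maps -> refined.
    SE2 : passive-pool tau from the ESM ensemble mean -> refined.
    SE3 : reduced model, data tau maps, calibrated pool-specific Q10.
    SE4 : reduced model, data tau maps, each ESM's own Q10 and T_ref.
    SE5 : reduced model, ESM's own tau, calibrated Q10.
    SE6 : SE4 but with the ensemble-mean ESM passive tau.

    SE3-SE6 use each ESM's native (uncorrected) forcing and its per-cell
    diagnosed (r_f, r_s, b).  Returns a dict with per-(model, scenario)
    DeltaResults and, for SE1, the alternative tau maps.
    """
    world = ctx.world
    scenarios = sorted({s for (_, s) in ctx.original_delta})
    out = {"variant": variant, "delta": {}}

    if variant in ("default", "SE1", "SE2"):
        tau_maps = ctx.tau_maps
        if variant == "SE1":
            alt_sites = arrhenius_site_tau(ctx.sites)
            tau_models, frac_models = fit_all_models(alt_sites, seed=seed)
            tau_maps = predict_maps(
                tau_models, frac_models, covariate_source_combinations(world, seed),
                lat=world.lat, lon=world.lon, mask=world.land_mask)
            out["tau_maps"] = tau_maps
        elif variant == "SE2":
            tau = tau_maps.tau.copy()
            tau[2] = np.where(world.land_mask, _ensemble_mean_passive_tau(ctx.ensemble),
                              np.nan)
            from .types import TauMaps
            tau_maps = TauMaps(tau=tau, tau_std=tau_maps.tau_std,
                               fractions=tau_maps.fractions,
                               weighted=tau_maps.weighted, lat=world.lat, lon=world.lon)
            out["tau_maps"] = tau_maps
        refined_members = (ctx.refined_members if variant == "default"
                           else calibrate_refined_ensemble(world, tau_maps, seed=seed))
        spin_states = (ctx.spin_states if variant == "default" else
                       [spin_up(p, world.climate, mask=world.land_mask)
                        for _, p, _ in refined_members])
        for member in ctx.ensemble.members:
            for scen in scenarios:
                key = (member.name, scen)
                run_forcing = _extend_forcing_with_history(world, ctx.corrected_forcing[key])
                trajs = [project(p, st, run_forcing)
                         for (_, p, _), (st, _) in zip(refined_members, spin_states)]
                mean_traj = Trajectory(trajs[0].years.copy(),
                                       np.mean([t.pools for t in trajs], axis=0))
                out["delta"][key] = bud.delta_stock(
                    mean_traj, world.lat, world.lon, mask=world.land_mask,
                    scenario=scen, model=member.name)
        return out

    if variant not in ("SE3", "SE4", "SE5", "SE6"):
        raise ValueError(f"unknown sensitivity variant {variant!r}")
    if not ctx.emulator_fits:
        raise ValueError("SE3-SE6 require emulator calibration in the context")

    q10_cal = np.mean([p.q10 for _, p, _ in ctx.refined_members], axis=0)
    tau_data = ctx.tau_maps.tau
    tau_pass_esm = _ensemble_mean_passive_tau(ctx.ensemble)

    for member in ctx.ensemble.members:
        grid_ndim = world.land_mask.ndim
        tau_esm = member.params.tau_i.reshape((3,) + (1,) * grid_ndim) * np.ones_like(tau_data)
        if variant == "SE3":
            tau, q10, t_ref = tau_data, q10_cal, 15.0
        elif variant == "SE4":
            tau, q10, t_ref = tau_data, np.full(3, member.params.q10), member.params.t_ref
        elif variant == "SE5":
            tau, q10, t_ref = tau_esm, q10_cal, 15.0
        else:  # SE6
            tau = tau_data.copy()
            tau[2] = tau_pass_esm
            q10, t_ref = np.full(3, member.params.q10), member.params.t_ref
        tau = np.where(np.isfinite(tau), tau, 1.0)
        for scen in scenarios:
            fit = ctx.emulator_fits[(member.name, scen)]
            b_cell = np.where(np.isfinite(fit["b"]), fit["b"], 1.0)
            rf_cell = np.where(np.isfinite(fit["r_f"]), fit["r_f"], 0.0)
            rs_cell = np.where(np.isfinite(fit["r_s"]), fit["r_s"], 0.0)
            traj = run_reduced_percell(
                tau, q10, t_ref, b_cell, rf_cell, rs_cell,
                member.params.p_max, member.forcing[scen])
            out["delta"][(member.name, scen)] = bud.delta_stock(
                traj, world.lat, world.lon, mask=world.land_mask,
                scenario=scen, model=member.name)
    return out


def sensitivity_global_mean(result: dict) -> float:
    """Mean global stock change (PgC) across a variant's model x scenario runs."""
    return float(np.mean([d.total_pgc for d in result["delta"].values()]))
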