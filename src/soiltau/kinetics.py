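"""Three-pool deconvolution of incubation CO2-flux time series.

The total flux from an incubated sample is modeled as the sum of three
independently depleting first-order pools,

    R(t) = sum_p k_p * C_tot * f_p * exp(-k_p t),

with decay rates k ordered fast > slow > passive and partition
coefficients f summing to one.  Parameters are inverted by a constrained
Metropolis-Hastings random walk under uniform priors, and the resulting
turnover times are normalized to a reference temperature of 15 degC with
a (temperature-dependent) Q10 factor.
"""

from __future__ import annotations

import numpy as np

from .types import DAYS_PER_YEAR, IncubationSeries, PoolParams, Posterior

R_GAS = 8.31446  # J mol^-1 K^-1
KELVIN = 273.15

#: Uniform prior ranges (d^-1 for rates); overridable per call.
DEFAULT_PRIORS = {
    "k_fast": (1e-3, 1.0),
    "k_slow": (1e-5, 1e-2),
    "k_passive": (1e-8, 1e-4),
    "f": (0.0, 1.0),
}

MIN_DURATION_DAYS = 180.0  # "longer than 6 months"


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_records(records):
    """Apply the record-selection criteria to a list of IncubationSeries.

    A record is kept iff it parses, lasted at least 180 days, was aerobic,
    reports the initial carbon content, received no substrate addition and
    shows declining respiration (mean flux over the first 10% of
    observation times exceeds the mean over the last 10%).

    Returns
    -------
    kept : list of IncubationSeries
    rejected : list of (IncubationSeries, reason)
        ``reason`` names the first failing criterion: one of
        "unparseable", "duration", "aerobic", "c_tot", "substrate",
        "no_decline".
    """
    kept, rejected = [], []
    for rec in records:
        reason = _rejection_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


def _rejection_reason(rec: IncubationSeries):
    if rec.times is None or rec.fluxes is None:
        return "unparseable"
    times = np.asarray(rec.times, dtype=float)
    fluxes = np.asarray(rec.fluxes, dtype=float)
    if times.size == 0 or fluxes.size != times.size or np.any(np.diff(times) <= 0):
        return "unparseable"
    if rec.duration < MIN_DURATION_DAYS:
        return "duration"
    if not rec.aerobic:
        return "aerobic"
    if rec.c_tot is None or not np.isfinite(rec.c_tot) or rec.c_tot <= 0:
        return "c_tot"
    if rec.substrate_added:
        return "substrate"
    span = times[-1] - times[0]
    head = fluxes[times <= times[0] + 0.1 * span]
    tail = fluxes[times >= times[-1] - 0.1 * span]
    if not head.mean() > tail.mean():
        return "no_decline"
    return None


# ---------------------------------------------------------------------------
# forward model and likelihood
# ---------------------------------------------------------------------------

def forward_flux(params: PoolParams, c_tot: float, times) -> np.ndarray:
    """Total CO2 flux of the three-pool model at the given times (days)."""
    params.validate()
    if c_tot <= 0:
        raise ValueError("c_tot must be positive")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("negative times are not allowed")
    return _flux(params.k, params.f, c_tot, times)


def _flux(k, f, c_tot, times):
    # (3, nt) pool-resolved fluxes summed over pools
    return np.einsum(
        "p,pt->t", k * f * c_tot, np.exp(-np.outer(k, times))
    )


def log_likelihood(params: PoolParams, series: IncubationSeries, sigma: float) -> float:
    """Gaussian log-likelihood (up to an additive constant) of a series."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if series.times.shape != series.fluxes.shape:
        raise ValueError("times and fluxes have mismatched shapes")
    model = forward_flux(params, series.c_tot, series.times)
    resid = model - series.fluxes
    return -0.5 * float(resid @ resid) / sigma**2


# ---------------------------------------------------------------------------
# Metropolis-Hastings sampler
# ---------------------------------------------------------------------------

def _check_prior_feasibility(priors):
    kf, ks, kp = priors["k_fast"], priors["k_slow"], priors["k_passive"]
    for name, (lo, hi) in (("k_fast", kf), ("k_slow", ks), ("k_passive", kp)):
        if not (0 < lo < hi):
            raise ValueError(f"invalid prior range for {name}")
    if not (kf[1] > ks[0] and ks[1] > kp[0]):
        raise ValueError("prior ranges make the ordering k_fast > k_slow > k_passive infeasible")


def mh_sample(
    series: IncubationSeries,
    priors: dict | None = None,
    n_iter: int = 20000,
    seed: int = 0,
    proposal_config: dict | None = None,
    sigma: float | None = None,
) -> Posterior:
    """Invert pool parameters from one flux series by Metropolis-Hastings.

    The walk is component-wise Gaussian on (ln k_fast, ln k_slow,
    ln k_passive, f_fast, f_slow) with f_passive = 1 - f_fast - f_slow.
    Proposals violating the rate ordering, the simplex constraint or the
    uniform prior boxes are rejected, so every retained draw is a valid
    PoolParams.  The likelihood sigma defaults to the sample standard
    deviation of the observed fluxes (pass ``sigma`` to override, e.g.
    with a known instrument error).  Step sizes adapt toward ~30%
    acceptance during the burn-in (first 20% of sweeps) and are frozen
    afterwards.  Deterministic under ``seed``.
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be at least 1000")
    priors = {**DEFAULT_PRIORS, **(priors or {})}
    _check_prior_feasibility(priors)
    cfg = {"scales": (0.4, 0.4, 0.6, 0.06, 0.06), "target_accept": 0.3,
           "adapt_interval": 100}
    cfg.update(proposal_config or {})

    times = np.asarray(series.times, dtype=float)
    obs = np.asarray(series.fluxes, dtype=float)
    if times.shape != obs.shape or times.size < 3:
        raise ValueError("series times/fluxes mismatch")
    if sigma is None:
        sigma = float(np.std(obs, ddof=1))
        if sigma == 0:
            raise ValueError("sigma undefined: zero-variance flux series")
    elif sigma <= 0:
        raise ValueError("sigma must be positive")
    c_tot = float(series.c_tot)

    log_k_lo = np.log([priors["k_fast"][0], priors["k_slow"][0], priors["k_passive"][0]])
    log_k_hi = np.log([priors["k_fast"][1], priors["k_slow"][1], priors["k_passive"][1]])
    f_lo, f_hi = priors["f"]

    inv_two_sigma2 = 0.5 / sigma**2

    def log_post(x):
        logk, ff, fs = x[:3], x[3], x[4]
        fp = 1.0 - ff - fs
        if np.any(logk < log_k_lo) or np.any(logk > log_k_hi):
            return -np.inf
        if not (logk[0] > logk[1] > logk[2]):
            return -np.inf
        for fv in (ff, fs, fp):
            if fv < f_lo or fv > f_hi:
                return -np.inf
        k = np.exp(logk)
        f = np.array([ff, fs, fp])
        resid = _flux(k, f, c_tot, times) - obs
        return -inv_two_sigma2 * float(resid @ resid)

    rng = np.random.default_rng(seed)
    x = np.concatenate([0.5 * (log_k_lo + log_k_hi), [0.1, 0.3]])
    lp = log_post(x)
    if not np.isfinite(lp):
        raise RuntimeError("could not initialize chain inside the prior")

    ndim = 5
    scales = np.array(cfg["scales"], dtype=float)
    burn_in = int(0.2 * n_iter)
    chain = np.empty((n_iter, 6))
    lp_chain = np.empty(n_iter)
    acc = np.zeros(ndim, dtype=int)
    acc_window = np.zeros(ndim, dtype=int)
    n_prop = 0

    for it in range(n_iter):
        for j in range(ndim):
            prop = x.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_prop = log_post(prop)
            n_prop += 1
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                acc[j] += 1
                acc_window[j] += 1
        if it < burn_in and (it + 1) % cfg["adapt_interval"] == 0:
            rate = acc_window / cfg["adapt_interval"]
            scales *= np.clip(np.exp(rate - cfg["target_accept"]), 0.5, 2.0)
            acc_window[:] = 0
        k = np.exp(x[:3])
        chain[it] = (k[0], k[1], k[2], x[3], x[4], 1.0 - x[3] - x[4])
        lp_chain[it] = lp

    retained = chain[burn_in:]
    retained_lp = lp_chain[burn_in:]
    acceptance = float(acc.sum()) / n_prop

    best = int(np.argmax(retained_lp))
    mean = retained.mean(axis=0)
    ci = np.percentile(retained, [2.5, 97.5], axis=0)
    names = ("k_fast", "k_slow", "k_passive", "f_fast", "f_slow", "f_passive")
    point = {n: float(retained[best, i]) for i, n in enumerate(names)}
    # the passive rate is poorly constrained by finite series: report its
    # posterior mean instead of the maximum-likelihood draw
    point["k_passive"] = float(mean[2])
    summaries = {
        "point": point,
        "mean": {n: float(mean[i]) for i, n in enumerate(names)},
        "ci": {n: (float(ci[0, i]), float(ci[1, i])) for i, n in enumerate(names)},
        "tau_years_point": {
            p: float(1.0 / (point[f"k_{p}"] * DAYS_PER_YEAR))
            for p in ("fast", "slow", "passive")
        },
    }
    return Posterior(
        chains=retained, log_post=retained_lp, acceptance_rate=acceptance,
        burn_in=burn_in, sigma=sigma, summaries=summaries,
    )


# ---------------------------------------------------------------------------
# temperature normalization
# ---------------------------------------------------------------------------

def default_q10(t_celsius):
    """Empirical temperature-dependent Q10, decreasing with temperature.

    Piecewise linear from 3.0 at 0 degC to 1.8 at 35 degC, clamped outside;
    replace with any callable Q10(T) for alternative sensitivities.
    """
    t = np.asarray(t_celsius, dtype=float)
    return np.interp(t, [0.0, 35.0], [3.0, 1.8])


def normalize_to_reference(tau, t_inc, q10_fn=default_q10, t_ref: float = 15.0):
    """Scale a turnover time from the incubation temperature to ``t_ref``.

    tau_ref = tau * Q10(T_inc) ** ((T_inc - T_ref) / 10)
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    q10 = np.asarray(q10_fn(t_inc), dtype=float)
    if np.any(q10 <= 0):
        raise ValueError("q10_fn returned a non-positive Q10")
    return tau * q10 ** ((np.asarray(t_inc, dtype=float) - t_ref) / 10.0)


def activation_energy_from_q10(q10, t_celsius):
    """Activation energy (J mol^-1) whose Arrhenius rate ratio over the
    centered 10-degree interval [T-5, T+5] equals ``q10``."""
    q10 = np.asarray(q10, dtype=float)
    tk = np.asarray(t_celsius, dtype=float) + KELVIN
    return R_GAS * np.log(q10) / (1.0 / (tk - 5.0) - 1.0 / (tk + 5.0))


def normalize_arrhenius(tau, t_inc, ea, t_ref: float = 15.0):
    """Arrhenius counterpart of :func:`normalize_to_reference`.

    tau_ref = tau * k(T_inc) / k(T_ref) with k(T) ~ exp(-Ea / (R T)).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    tk = np.asarray(t_inc, dtype=float) + KELVIN
    tref_k = t_ref + KELVIN
    return tau * np.exp(np.asarray(ea, dtype=float) / R_GAS * (1.0 / tref_k - 1.0 / tk))
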