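"""Climatologies and delta (change) bias correction of future forcing.

Temperature and NPP are corrected additively, precipitation
multiplicatively:

    T_cor   = T_bas,obs   + (T_fut,mod   - T_bas,mod)
    P_cor   = P_bas,obs   * (P_fut,mod   / P_bas,mod)
    NPP_cor = NPP_bas,obs + (NPP_fut,mod - NPP_bas,mod)

applied at the native timescale of the supplied series (annual in this
package's synthetic experiments).
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import BaselinePair, ScenarioForcing

ADDITIVE_KINDS = {"T", "NPP"}
MULTIPLICATIVE_KINDS = {"P"}


def climatology(series, years, window=(2000, 2014)) -> np.ndarray:
    """Arithmetic mean field over an inclusive year window (mask-aware:
    NaNs propagate per cell)."""
    series = np.asarray(series, dtype=float)
    years = np.asarray(years)
    sel = (years >= window[0]) & (years <= window[1])
    if not sel.any():
        raise ValueError(f"no years within {window}")
    return series[sel].mean(axis=0)


def delta_correct(variable_kind: str, future_mod, baseline: BaselinePair):
    """Bias-correct an ESM future series against observed baselines.

    ``future_mod`` has time on axis 0; the baseline fields broadcast
    against its trailing dimensions.  For precipitation, cells with a zero
    modeled baseline cannot be ratio-corrected and are masked (NaN) with a
    warning.  Corrected NPP is clipped at zero (additive deltas can
    undershoot); the clip count is reported via warning.
    """
    kind = variable_kind.upper()
    fut = np.asarray(future_mod, dtype=float)
    obs, mod = baseline.observed, baseline.modeled
    if kind in ADDITIVE_KINDS:
        out = obs + (fut - mod)
        if kind == "NPP":
            n_neg = int(np.sum(out < 0))
            if n_neg:
                warnings.warn(f"clipped {n_neg} negative corrected NPP values to 0")
                out = np.clip(out, 0.0, None)
        return out
    if kind in MULTIPLICATIVE_KINDS:
        bad = mod == 0
        if np.any(bad):
            warnings.warn(f"masked {int(bad.sum())} cells with zero modeled baseline precipitation")
            mod = np.where(bad, np.nan, mod)
        return obs * (fut / mod)
    raise ValueError(f"unknown variable kind {variable_kind!r}; expected T, P or NPP")


def bias_correct_forcing(
    forcing: ScenarioForcing,
    obs_baseline: dict,
    window=(2000, 2014),
) -> ScenarioForcing:
    """Delta-correct a full ScenarioForcing against observed baselines.

    ``obs_baseline`` maps 'tas', 'pr', 'npp' to observed climatology
    fields; the model baselines are the forcing's own means over
    ``window``.
    """
    tas_b = BaselinePair(obs_baseline["tas"], climatology(forcing.tas, forcing.years, window))
    pr_b = BaselinePair(obs_baseline["pr"], climatology(forcing.pr, forcing.years, window))
    npp_b = BaselinePair(obs_baseline["npp"], climatology(forcing.npp, forcing.years, window))
    return ScenarioForcing(
        years=forcing.years.copy(),
        tas=delta_correct("T", forcing.tas, tas_b),
        pr=delta_correct("P", forcing.pr, pr_b),
        npp=delta_correct("NPP", forcing.npp, npp_b),
        scenario=forcing.scenario,
        model=forcing.model,
    )
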