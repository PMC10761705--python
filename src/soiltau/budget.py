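"""Global aggregation, stock-change accounting and carbon-budget impact.

Cell areas are spherical (computed from cell-edge latitudes), totals are
reported in PgC (1 PgC = 1e15 gC), and the remaining-budget reduction
relies on an ordinary-least-squares fit of global soil carbon change
against global warming across models and scenarios.
"""

from __future__ import annotations

import numpy as np

from .types import BudgetResult, DeltaResult, Trajectory

EARTH_RADIUS_M = 6.371e6
G_PER_PG = 1e15

#: remaining carbon budgets (PgC) for a likely (50%) chance of staying
#: below each warming target, from the start of 2022
DEFAULT_BUDGETS_PGC = {1.5: 68.0, 2.0: 327.0}


def cell_areas(lat, lon) -> np.ndarray:
    """Spherical cell areas (m^2) on a regular grid from edge latitudes."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = lat[1] - lat[0] if len(lat) > 1 else 180.0
    dlon = lon[1] - lon[0] if len(lon) > 1 else 360.0
    edges_lo = np.deg2rad(np.clip(lat - dlat / 2.0, -90.0, 90.0))
    edges_hi = np.deg2rad(np.clip(lat + dlat / 2.0, -90.0, 90.0))
    band = EARTH_RADIUS_M**2 * np.deg2rad(abs(dlon)) * (np.sin(edges_hi) - np.sin(edges_lo))
    return np.repeat(band[:, None], len(lon), axis=1)


def global_total(field, lat, lon, mask=None) -> float:
    """Area-weighted total of a gC m^-2 field, in PgC."""
    field = np.asarray(field, dtype=float)
    areas = cell_areas(lat, lon)
    if mask is not None:
        areas = np.where(np.asarray(mask, dtype=bool), areas, 0.0)
    vals = np.where(np.isfinite(field), field, 0.0)
    return float((vals * areas).sum() / G_PER_PG)


def delta_stock(
    trajectory: Trajectory,
    lat,
    lon,
    period_a=(2005, 2014),
    period_b=(2080, 2099),
    mask=None,
    scenario: str = "",
    model: str = "",
) -> DeltaResult:
    """Per-cell stock change mean(period_b) - mean(period_a); positive
    means the soil gains carbon (sink)."""
    field = trajectory.period_mean_total(*period_b) - trajectory.period_mean_total(*period_a)
    return DeltaResult(
        field=field,
        total_pgc=global_total(field, lat, lon, mask=mask),
        period_a=tuple(period_a), period_b=tuple(period_b),
        scenario=scenario, model=model,
    )


def aggregate(field, lat, lon, scheme="latitude", band_width=0.5, mask=None,
              biomes=None):
    """Area-weighted means per latitude band or biome latitude class.

    scheme='latitude': bands of ``band_width`` degrees (cells assigned by
    center).  scheme='biome_latitude': tropical (23S-23N), temperate
    (23-50 deg), boreal (>50N), southern_high (>50S).  Returns a dict
    mapping band label -> mean value.
    """
    field = np.asarray(field, dtype=float)
    areas = cell_areas(lat, lon)
    if mask is not None:
        areas = np.where(np.asarray(mask, dtype=bool), areas, 0.0)
    areas = np.where(np.isfinite(field), areas, 0.0)
    field = np.where(np.isfinite(field), field, 0.0)
    lat2d = np.repeat(np.asarray(lat, dtype=float)[:, None], len(lon), axis=1)

    if scheme == "latitude":
        idx = np.floor(lat2d / band_width).astype(int)
        labels = np.unique(idx)
        out = {}
        for lab in labels:
            sel = idx == lab
            w = areas[sel].sum()
            if w > 0:
                out[float(lab * band_width + band_width / 2.0)] = float(
                    (field[sel] * areas[sel]).sum() / w
                )
        return out
    if scheme == "biome_latitude":
        classes = {
            "tropical": np.abs(lat2d) < 23.0,
            "temperate": (np.abs(lat2d) >= 23.0) & (np.abs(lat2d) < 50.0),
            "boreal": lat2d >= 50.0,
            "southern_high": lat2d <= -50.0,
        }
        out = {}
        for name, sel in classes.items():
            w = areas[sel].sum()
            if w > 0:
                out[name] = float((field[sel] * areas[sel]).sum() / w)
        return out
    raise ValueError(f"unknown aggregation scheme {scheme!r}")


def _ols(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def budget_reduction(
    delta_t,
    delta_soc_constrained,
    delta_soc_original=None,
    budgets=None,
) -> BudgetResult:
    """Remaining-budget impact of the observational constraint.

    Fits OLS lines of global soil carbon change (PgC, relative to the
    2020 stock) against global warming (degC above the 1850-1900 mean)
    across model x scenario points, for both the constrained and the
    original projections (original defaults to zero change).  At each
    warming target the budget reduction is

        (original - constrained soil carbon change) / remaining budget.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    yc = np.asarray(delta_soc_constrained, dtype=float)
    if delta_t.size < 3:
        raise ValueError("need at least 3 (warming, stock-change) points to fit")
    if delta_soc_original is None:
        yo = np.zeros_like(yc)
    else:
        yo = np.asarray(delta_soc_original, dtype=float)
    budgets = dict(DEFAULT_BUDGETS_PGC if budgets is None else budgets)

    slope_c, icpt_c = _ols(delta_t, yc)
    slope_o, icpt_o = _ols(delta_t, yo)
    soil_c, soil_o, diff, red = {}, {}, {}, {}
    for target, budget in budgets.items():
        cc = slope_c * target + icpt_c
        oo = slope_o * target + icpt_o
        soil_c[target], soil_o[target] = cc, oo
        diff[target] = oo - cc
        red[target] = diff[target] / budget
    return BudgetResult(
        slope_constrained=slope_c, intercept_constrained=icpt_c,
        slope_original=slope_o, intercept_original=icpt_o,
        soil_change_constrained=soil_c, soil_change_original=soil_o,
        difference=diff, reduction_fraction=red, n_points=int(delta_t.size),
    )
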