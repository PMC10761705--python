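"""Shared domain containers for the three-pool soil carbon pipeline.

All gridded quantities live on a regular lat/lon grid (cell-center
coordinates in degrees).  Pool-resolved arrays use axis 0 with the order
``(fast, slow, passive)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

DAYS_PER_YEAR = 365.25
#: order of soil carbon pools on pool-resolved axes
POOLS = ("fast", "slow", "passive")


@dataclass
class PoolParams:
    """Per-pool first-order decay rates and partition fractions.

    Parameters
    ----------
    k : array-like, shape (3,)
        Intrinsic decay rates (d^-1), ordered fast > slow > passive.
    f : array-like, shape (3,)
        Partition coefficients of the initial carbon, summing to one.
    """

    k: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.f = np.asarray(self.f, dtype=float)

    def validate(self) -> None:
        if self.k.shape != (3,) or self.f.shape != (3,):
            raise ValueError("PoolParams requires three pools")
        if not (self.k[0] > self.k[1] > self.k[2] > 0):
            raise ValueError("decay rates must satisfy k_fast > k_slow > k_passive > 0")
        if np.any(self.f < 0) or np.any(self.f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(self.f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def tau_years(self) -> np.ndarray:
        """Turnover times 1/k converted from days to years."""
        return 1.0 / (self.k * DAYS_PER_YEAR)


@dataclass
class IncubationSeries:
    """One site's incubation CO2-flux time series plus metadata.

    Fluxes are in mgC g^-1 dw d^-1, times in days since the start of the
    incubation, ``c_tot`` is the initial carbon content in mgC g^-1 dw.
    """

    site_id: str
    times: np.ndarray
    fluxes: np.ndarray
    c_tot: float | None
    incubation_t: float
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
        if self.fluxes is not None:
            self.fluxes = np.asarray(self.fluxes, dtype=float)

    @property
    def aerobic(self) -> bool:
        return bool(self.metadata.get("aerobic", True))

    @property
    def substrate_added(self) -> bool:
        return bool(self.metadata.get("substrate_added", False))


@dataclass
class Posterior:
    """MCMC output for one incubation series.

    ``chains`` holds one row per retained draw with columns
    (k_fast, k_slow, k_passive, f_fast, f_slow, f_passive); ``log_post``
    the corresponding unnormalized log-posterior values. ``burn_in`` is the
    number of discarded leading sweeps (chains excludes them).
    """

    chains: np.ndarray
    log_post: np.ndarray
    acceptance_rate: float
    burn_in: int
    sigma: float
    summaries: dict

    def point_params(self) -> PoolParams:
        """Point estimate as PoolParams (see summaries['point'])."""
        p = self.summaries["point"]
        f = np.array([p["f_fast"], p["f_slow"], p["f_passive"]])
        return PoolParams(
            k=np.array([p["k_fast"], p["k_slow"], p["k_passive"]]), f=f / f.sum()
        )


@dataclass
class GridField:
    """A 2-D georeferenced field on a regular lat/lon grid."""

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    units: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise ValueError(
                f"field shape {self.values.shape} does not match grid "
                f"({len(self.lat)}, {len(self.lon)})"
            )
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)

    def masked(self) -> np.ndarray:
        return np.where(self.mask, self.values, np.nan)


@dataclass
class PoolState:
    """Per-cell carbon stocks (gC m^-2, 0-1 m column); ``pools[0]`` fast."""

    pools: np.ndarray  # (3, nlat, nlon) or (3,) for a single cell

    def __post_init__(self) -> None:
        self.pools = np.asarray(self.pools, dtype=float)

    def total(self) -> np.ndarray:
        return self.pools.sum(axis=0)

    def copy(self) -> "PoolState":
        return PoolState(self.pools.copy())


@dataclass
class Trajectory:
    """Yearly pool evolution: ``pools[t, p]`` is the state in year ``years[t]``."""

    years: np.ndarray
    pools: np.ndarray  # (nyears, 3, nlat, nlon)

    def total(self) -> np.ndarray:
        """Total stock per year, shape (nyears, nlat, nlon)."""
        return self.pools.sum(axis=1)

    def state_at(self, year: int) -> PoolState:
        idx = int(np.searchsorted(self.years, year))
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in trajectory")
        return PoolState(self.pools[idx])

    def period_mean_total(self, start: int, end: int) -> np.ndarray:
        """Mean total stock over the inclusive year window [start, end]."""
        sel = (self.years >= start) & (self.years <= end)
        if not sel.any():
            raise ValueError(f"trajectory has no years in [{start}, {end}]")
        return self.pools[sel].sum(axis=1).mean(axis=0)


@dataclass
class ScenarioForcing:
    """Per-cell yearly NPP (gC m^-2 yr^-1), air temperature (degC) and
    precipitation (mm yr^-1) for one scenario and one model."""

    years: np.ndarray
    npp: np.ndarray  # (nyears, nlat, nlon)
    tas: np.ndarray
    pr: np.ndarray
    scenario: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        ny = len(self.years)
        for name in ("npp", "tas", "pr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape[0] != ny:
                raise ValueError(f"{name} has {arr.shape[0]} years, expected {ny}")
        if ny > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("forcing years must be contiguous")

    def subset(self, start: int, end: int) -> "ScenarioForcing":
        sel = (self.years >= start) & (self.years <= end)
        return ScenarioForcing(
            self.years[sel], self.npp[sel], self.tas[sel], self.pr[sel],
            scenario=self.scenario, model=self.model,
        )


@dataclass
class EmulatorParams:
    """Reduced-complexity model parameters for one ESM.

    ``tau_i`` are spatially uniform intrinsic turnover times (yr) per pool;
    ``q10``/``t_ref`` define the temperature modifier, ``b`` the
    precipitation exponent and ``p_max`` (mm yr^-1) the normalization.
    """

    tau_i: np.ndarray  # (3,)
    q10: float
    t_ref: float
    r_f: float
    r_s: float
    b: float
    p_max: float

    def __post_init__(self) -> None:
        self.tau_i = np.asarray(self.tau_i, dtype=float)

    def validate(self) -> None:
        if not (0 < self.tau_i[0] < self.tau_i[1] < self.tau_i[2]):
            raise ValueError("tau_i must be ordered fast < slow < passive")
        if not (0 <= self.r_f <= 1 and 0 <= self.r_s <= 1):
            raise ValueError("transfer coefficients must lie in [0, 1]")
        if self.b <= 0:
            raise ValueError("precipitation exponent b must be positive")
        if self.p_max <= 0:
            raise ValueError("p_max must be positive")


@dataclass
class RefinedParams:
    """Observationally constrained model parameters.

    ``tau_i`` is a per-cell (3, nlat, nlon) map of intrinsic turnover
    times at 15 degC; ``q10`` per-pool values obeying the carbon
    quality-temperature ordering Q10_passive >= Q10_slow >= Q10_fast >= 1;
    ``clay`` the per-cell clay fraction driving mineral protection and
    ``r_root_frac`` the NPP fraction respired by roots (priming driver).
    """

    tau_i: np.ndarray
    q10: np.ndarray  # (3,)
    b: float
    r_f: float
    r_s: float
    clay: np.ndarray
    p_max: float
    t_ref: float = 15.0
    r_root_frac: float = 0.07

    def __post_init__(self) -> None:
        self.tau_i = np.asarray(self.tau_i, dtype=float)
        self.q10 = np.asarray(self.q10, dtype=float)
        self.clay = np.asarray(self.clay, dtype=float)

    def validate(self) -> None:
        if not (self.q10[2] >= self.q10[1] >= self.q10[0] >= 1.0):
            raise ValueError("Q10 must satisfy passive >= slow >= fast >= 1")
        if np.any((self.clay < 0) | (self.clay > 1)):
            raise ValueError("clay fraction must lie in [0, 1]")
        if self.b <= 0 or self.p_max <= 0:
            raise ValueError("b and p_max must be positive")


@dataclass
class TauMaps:
    """Gridded turnover-time products from upscaling."""

    tau: np.ndarray        # (3, nlat, nlon), yr at 15 degC
    tau_std: np.ndarray    # (3, nlat, nlon), std across dataset combinations
    fractions: np.ndarray  # (3, nlat, nlon), renormalized to sum 1
    weighted: np.ndarray   # (nlat, nlon), carbon-weighted tau
    lat: np.ndarray = None
    lon: np.ndarray = None


@dataclass
class BaselinePair:
    """Observed and modeled baseline (2000-2014 mean) of one variable."""

    observed: np.ndarray
    modeled: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.modeled = np.asarray(self.modeled, dtype=float)
        if self.observed.shape != self.modeled.shape:
            raise ValueError("baseline fields must share a grid")


@dataclass
class DeltaResult:
    """Per-cell stock change between two period means, plus global total."""

    field: np.ndarray       # gC m^-2
    total_pgc: float
    period_a: tuple
    period_b: tuple
    scenario: str = ""
    model: str = ""


@dataclass
class BudgetResult:
    """Remaining-carbon-budget implications of constrained projections."""

    slope_constrained: float
    intercept_constrained: float
    slope_original: float
    intercept_original: float
    soil_change_constrained: dict   # warming target -> PgC
    soil_change_original: dict
    difference: dict                # original minus constrained, PgC
    reduction_fraction: dict        # difference / budget
    n_points: int


Q10Function = Callable[[np.ndarray], np.ndarray]
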