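# Methods

This note records the models implemented in `soiltau`, the parameter
choices that matter, the numerical scheme, and what the synthetic
experiments can and cannot demonstrate.

## Three-pool decomposition kinetics

An incubated soil sample is modeled as three independently depleting
first-order pools. The total CO₂ efflux is

    R(t) = Σₚ kₚ · C_tot · fₚ · exp(−kₚ t),   p ∈ {fast, slow, passive}

with decay rates kₚ (d⁻¹) ordered k_fast > k_slow > k_passive > 0 and
partition coefficients fₚ ∈ [0, 1], Σfₚ = 1. The time dependence is the
standard deconvolution form: since each pool depletes independently, the
pool-specific flux decays as exp(−kₚt); a time-constant flux could not
fit a declining series, which the screening criteria require.

**Screening.** A record is retained iff it parses, lasted ≥ 180 days, was
aerobic, reports the initial carbon content, received no substrate
addition, and its mean flux over the first 10% of observation times
exceeds that over the last 10%. Rejections are labelled with the first
failing criterion.

**Inversion.** Parameters m = (k, f) are sampled from
p(m|O) ∝ p(O|m) p(m) with uniform priors and a Gaussian likelihood
log p(O|m) = −Σₜ[S(t)−O(t)]²/(2σ²). σ is fixed to the sample standard
deviation of the measured fluxes (an intentionally conservative, tempered
choice; it can be overridden with a known instrument error). The sampler
is a component-wise Gaussian random walk on
(ln k_f, ln k_s, ln k_p, f_f, f_s) with f_p = 1 − f_f − f_s; proposals
violating the rate ordering, the simplex or the prior boxes are rejected,
so every retained draw is valid. Step sizes adapt toward ~30% acceptance
during the burn-in (first 20% of sweeps) and are then frozen, preserving
detailed balance for the retained draws. Default priors (all
overridable): k_fast ∈ [10⁻³, 1], k_slow ∈ [10⁻⁵, 10⁻²],
k_passive ∈ [10⁻⁸, 10⁻⁴] d⁻¹, fₚ ∈ [0, 1]. Point estimates follow the
well/poorly-constrained split: maximum-likelihood draws for k_fast,
k_slow and the fractions, the posterior mean for k_passive; 95% credible
intervals for everything.

**Identifiability.** Multi-exponential deconvolution is ill-conditioned.
For a 2-year weekly series with additive noise at 5% of the initial flux,
the Cramér–Rao bound on the fast and slow rates is ≈ 20% (1σ) *for any
estimator*, across the admissible parameter space — the information
simply is not in the data at that noise level. The recovery tests
therefore assert agreement at the information bound (the recovery
fixture, k = (0.05, 6·10⁻³, 10⁻⁵) d⁻¹, f = (0.10, 0.50, 0.40), was chosen
to maximize Fisher information under that design). At 1% noise the bound
drops to ≈ 4.5% and recovery to a few percent is routine.

**Temperature normalization.** τ values inverted at the incubation
temperature T are scaled to the 15 °C reference by
τ₁₅ = τ_T · Q10(T)^((T−15)/10). The default Q10(T) is piecewise linear,
3.0 at 0 °C to 1.8 at 35 °C (decreasing sensitivity with temperature),
and user-replaceable — there is no single agreed functional form for
this empirical relationship. The Arrhenius alternative uses
k ∝ exp(−Ea/(R T_K)); converting a Q10 at temperature T to Ea uses the
centered definition (rate ratio over [T−5, T+5] °C), which keeps the two
normalizations within a few percent of each other for incubation
temperatures 10–30 °C.

## Upscaling

Site-level log₁₀ τ (and pool fractions) are regressed on ten predictors
(MAT, MAP, NDVI, bulk density, pH, SOC, total N, C:N, silt, sand) with
gradient-boosted regression trees. Hyperparameters are grid-searched
(default grid: 200/400 trees × depth 2/3 × learning rate 0.06) under
ten-fold cross-validation minimizing RMSE; the reported CV R² is the
fold-mean R² of the selected configuration. Records with missing
predictors are dropped (no imputation). Maps are predicted per covariate
source combination (the study design is 2 climate × 2 soil sources);
per-cell means and standard deviations are taken after back-transforming
from log₁₀. Fraction maps are renormalized to sum to one, since
independent regressors do not preserve the simplex. Extrapolation flags
mark cells where any predictor leaves the training [min, max] range.

## Reduced-complexity emulator

Pool dynamics (annual, gC m⁻²):

    dC_f/dt = NPP − k_f C_f
    dC_s/dt = r_f k_f C_f − k_s C_s
    dC_p/dt = r_s k_s C_s − k_p C_p

with k = Q10^((T−T_ref)/10) · (P/P_max)^b / τ_i; P_max is the maximum
annual precipitation over the ESM's own domain and period. The closed
form equilibrium is C_f* = NPP/k_f, C_s* = r_f NPP/k_s,
C_p* = r_f r_s NPP/k_p.

**Time stepping** is annual explicit Euler with automatic sub-stepping
whenever k·dt ≥ 0.5; the discrete steady state coincides exactly with
the continuous one, the scheme preserves non-negativity, and each
(sub)step satisfies the carbon balance
Δ(C_f+C_s+C_p) = NPP·dt − [k_f C_f(1−r_f) + k_s C_s(1−r_s) + k_p C_p]·dt
identically (verified to 10⁻¹⁰ relative).

**Per-cell diagnosis.** (r_f, r_s, b) are fitted per grid cell against an
ESM's pool trajectories: the model is initialized at the mean historical
(2000–2014) stocks and the summed per-pool normalized RMSE over
2016–2100 is minimized. The pool equations are linear in the transfer
coefficients — for a given b, C_f is fully determined, C_s is affine in
r_f and C_p is bilinear in (r_f, r_s) — so the optimal transfer
coefficients have closed-form least-squares profiles and the search
reduces to a 1-D bracketed grid refinement in b per cell (deterministic,
~40 objective evaluations). Degeneracy (e.g., P ≡ P_max making b
unidentifiable, or unresolved transfer coefficients) is detected and
flagged. A generic batched differential-evolution optimizer
(`soiltau.optimize`) is available for objectives without this structure
and serves the refined-model calibration.

## Refined (observationally constrained) model

Decay rates gain two process scalars:

    kₚ = F(T)·F(P)·F(M)·F(RPₚ) / τ_i,p,   T_ref = 15 °C

- F(T) uses pool-specific Q10 obeying the carbon quality–temperature
  ordering Q10_passive ≥ Q10_slow ≥ Q10_fast ≥ 1.
- F(M) (mineral protection) is the empirical clay function
  24.2·clay for clay < 0.033, else −2.1·clay² + 6.2·clay + 0.6.
- F(RP) (rhizosphere priming) = 1/(1 + 2.47·R_root/(13.01 + R_root)) with
  R_root = 0.07·NPP (configurable), applied to the slow and passive pools
  only; it lies in (1/3.47, 1] and decreases with root respiration.

**Calibration.** The scalars (Q10 per pool, b, r_f, r_s) are identified
by differential evolution against gridded observations: per-pool stocks
(gridded SOC × fraction maps) and apparent turnover
τ_a = ΣC / Σ kC under 2000–2014 climatological forcing, using the
closed-form steady state. The objective is the summed per-pool
normalized stock RMSE plus the mean squared error of log τ_a, equally
weighted (the relative weighting of the two constraints is a free choice;
equal weight is the neutral one). One parameter set is fitted per
SOC × NPP data-source combination (four ensemble members); the Q10
ordering is enforced by parameterizing the slow/passive values as
non-negative increments. Calibration is pooled across cells: a per-cell
fit of six parameters to four observations is structurally degenerate
(a two-dimensional flat manifold per cell), whereas the pooled problem is
well identified by cross-cell climate variation. Spatial heterogeneity
enters through the τ_i maps and the clay field.

**Spin-up** cycles the yearly 2000–2014 forcing until the cycle-mean
|NPP − total decomposition| falls below 0.1% of mean NPP in every land
cell, starting (by default) from the closed-form equilibrium under the
cycle-mean forcing. Note that the passive pool equilibrates on
multi-millennial timescales; starting it far from equilibrium would
require thousands of cycles regardless of algorithm, which is why the
equilibrium initialization is the default.

**Projection** runs 2000–2100: observed yearly forcing through 2014, then
each ESM's scenario forcing delta-corrected against the observed
baselines (T and NPP additively, P multiplicatively; corrected NPP is
clipped at zero with a logged count, and cells with zero modeled baseline
precipitation are masked). The correction is applied at the resolution
of the supplied forcing (annual in the synthetic experiments).

## Projections, aggregation and budget

Stock changes are period means, 2080–2099 minus 2005–2014 (positive =
sink). Global totals use exact spherical cell areas from cell-edge
latitudes (1 PgC = 10¹⁵ gC). Aggregation supports latitude bands
(default 0.5°) and the biome-latitude classes tropical (23°S–23°N),
temperate (23–50°), boreal (>50°N). The remaining-budget impact fits OLS
lines of global soil carbon change (relative to the 2020 stock) against
global warming above the 1850–1900 mean across model × scenario points,
for both the original and constrained projections; at each warming target
the budget reduction is (original − constrained)/budget with budgets of
68 PgC (1.5 °C) and 327 PgC (2 °C).

## Synthetic world: what it emulates, and what it does not

`gen_world` builds covariates as smoothed Gaussian random fields plus
latitudinal gradients; the turnover truth is a smooth function of MAT
(positively correlated, the dominant driver), NDVI and SOC with 0.02–0.03
dex of unexplained jitter, centered on (0.3, 6.68, 398) yr at 15 °C.
Stocks are constructed at the refined model's closed-form steady state —
so fractions, apparent turnover and stocks are mutually consistent by
construction — with truth constants Q10 = (2.0, 2.8, 3.2), b = 0.5,
r_f = 0.45, r_s = 0.05, chosen to give observation-scale stocks
(global total ≈ 7×10³ PgC on a world whose cold cells behave like
permafrost, with maxima near 10² kgC m⁻²). Site records carry 0.1 dex of
lognormal turnover noise and incubation temperatures of 10–30 °C.

The ESM ensemble is generated by the reduced-complexity model itself,
with spatially uniform τ_i equal to the world's carbon-weighted means
times a bias factor (default 1.3, i.e. a 30% overestimate), per-member
scalar Q10 ∈ {1.7 … 2.1}, and scenario ramps by 2100 of
+1.8/+3.2/+5.2 °C and +15/+29/+50% NPP (CO₂ fertilization) for the
low/middle/high scenarios — magnitudes typical of CMIP6-class models,
set so the ensemble projects a net soil carbon sink as such models do.
Because each stage's input is generated by the very model that stage
fits, calibrations have exact recovery targets.

What passing tests on this world do **not** show: skill on real archives
(heterogeneous measurement protocols, covariate colinearity and data
gaps), the behavior of ESMs whose soil modules are not three-pool
CENTURY descendants, deep/permafrost carbon dynamics, carbon–nitrogen
coupling or the priming–nutrient feedback (all outside the model), or
monthly-scale bias-correction effects. A structural caveat worth noting:
with the priming scalar in its empirical Michaelis–Menten form (decreasing in root respiration,
hence decay *slows* as NPP rises), a constrained model can only lose
carbon while fertilization-driven ESMs gain if its slow/passive Q10
substantially exceed the ESM values; in this synthetic regime the Q10
contrast is therefore the dominant lever in the sensitivity experiments,
whereas a spatially structured turnover bias could dominate on real data.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.default_rng` seeds; fixed
  seeds give bit-identical series, worlds, chains and trajectories.
- Stability guard: sub-step count per year is ceil(k_max·dt / 0.5).
- Masked (ocean) cells carry NaN and are excluded from every aggregate;
  cells with zero SOC are masked out of calibration.
- Desk-scale problem sizes: 20×20 world (340 land cells), 300 sites,
  3 ESMs × 3 scenarios; the full pipeline runs in about a minute and the
  whole test suite in a few minutes on one CPU. Larger grids are a
  parameter, not a code change.
- The batched DE optimizer uses DE/rand/1/bin with reflection at the
  bounds, population 20–40, and flags flat-objective degeneracy.
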