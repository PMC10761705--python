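# soiltau

Observational constraints on the soil carbon–climate feedback, built
around three-pool soil carbon decomposition kinetics.

Soils hold more organic carbon than vegetation and atmosphere combined,
and Earth system models (ESMs) disagree even on the *sign* of the soil
carbon response to warming. A major reason is the intrinsic turnover
time τ_i of the soil carbon pools: most ESMs prescribe it as a handful of
spatially uniform constants, while incubation experiments show it varies
strongly across biomes. `soiltau` implements the full chain of an
observational-constraint analysis of this problem:

1. **Incubation deconvolution** — screen laboratory soil-incubation CO₂
   flux records and fit the three-pool model
   `R(t) = Σₚ kₚ · C_tot · fₚ · exp(−kₚ t)` (pools p ∈ {fast, slow,
   passive}, rates ordered k_fast > k_slow > k_passive, fractions fₚ
   summing to one) by a constrained Metropolis–Hastings sampler, then
   normalize τₚ = 1/kₚ to 15 °C with a temperature-dependent Q10 (or an
   Arrhenius alternative).
2. **Upscaling** — learn covariate → log₁₀ τ mappings (boosted regression
   trees, grid-searched under ten-fold CV) from site inversions and
   produce gridded τ and pool-fraction maps, with uncertainty from
   combinations of covariate data sources, plus the carbon-weighted
   turnover τ_w = Σₚ τₚ fₚ.
3. **ESM emulation** — a reduced-complexity three-pool model
   (dC_f/dt = NPP − k_f C_f, etc., with
   k = Q10^((T−T_ref)/10) · (P/P_max)^b / τ_i) whose transfer
   coefficients (r_f, r_s) and moisture exponent b are diagnosed per grid
   cell against each ESM's own pool trajectories.
4. **Refined, observationally constrained model** — decay rates
   k = F(T)·F(P)·F(M)·F(RP)/τ_i with pool-specific Q10 (carbon
   quality–temperature ordering), a clay-dependent mineral-protection
   scalar F(M) and a Michaelis–Menten rhizosphere-priming scalar F(RP)
   driven by root respiration (7% of NPP). Calibrated against gridded
   pool stocks and radiocarbon-style apparent turnover times, spun up to
   steady state, and run to 2100 under delta-bias-corrected ESM forcing.
5. **Projections and budget** — ΔSOC between 2005–2014 and 2080–2099,
   latitudinal/biome aggregation, and the implied reduction of the
   remaining carbon budget for the 1.5 °C (68 PgC) and 2 °C (327 PgC)
   warming targets via an OLS fit of global ΔSOC against warming.

Because the real inputs are large external archives, the package ships a
first-class synthetic-data generator (`soiltau.synthetic`) that creates a
gridded world with known ground truth — smooth covariate fields, a
learnable covariate→τ mapping, steady-state stocks, and an ESM-like
ensemble whose τ_i are spatially uniform and deliberately ~30% too long —
so every stage of the pipeline is testable end to end with exact
recovery targets.

## Worked example

```python
import numpy as np
from soiltau import PoolParams, gen_incubation_series, mh_sample

truth = PoolParams(k=np.array([0.05, 6e-3, 1e-5]), f=np.array([0.10, 0.50, 0.40]))
noiseless = gen_incubation_series(truth, c_tot=20.0, temperature=20.0,
                                  duration=730.0, noise_sd=0.0)
series = gen_incubation_series(truth, 20.0, 20.0, 730.0,
                               noise_sd=0.05 * noiseless.fluxes[0], seed=2)
post = mh_sample(series, n_iter=30000, seed=2)
pt = post.summaries["point"]
print(f"k_fast {pt['k_fast']:.4f} d-1  k_slow {pt['k_slow']:.5f} d-1  "
      f"f_fast {pt['f_fast']:.3f}  acceptance {post.acceptance_rate:.2f}")
```

prints

```
k_fast 0.0517 d-1  k_slow 0.00587 d-1  f_fast 0.093  acceptance 0.28
```

i.e. the sampler recovers the generating fast and slow decay rates (0.05
and 0.006 d⁻¹) to within a few percent for this noise realization, and
the fast pool fraction to ~0.01. The end-to-end analysis is one call:

```python
from soiltau.pipeline import run_pipeline, reversal_statistics

result = run_pipeline(seed=1)          # 20x20 world, 3 ESMs, 3 scenarios
print(result.summary["delta_soc_pgc"]["ssp585"])
print(reversal_statistics(result, "ssp585"))
```

```
{'original': 50.35, 'constrained': -46.70}
{'scenario': 'ssp585', 'fraction_cells_constrained_below_original': 1.0,
 'original_total_pgc': 50.35, 'constrained_total_pgc': -46.70}
```

The synthetic ESM ensemble projects a global soil carbon **sink** of
~50 PgC by 2080–2099 under the high-emission scenario, while the
observationally constrained model — shorter turnover times, pool-specific
temperature sensitivity, mineral protection and priming — turns it into a
**source** of ~47 PgC, in every land cell.

A thin CLI mirrors the stages: `soiltau simulate`, `soiltau invert`,
`soiltau upscale`, `soiltau bias-correct`, `soiltau pipeline`,
`soiltau budget`, `soiltau sensitivity`.

## Layout

```
src/soiltau/
  types.py       shared containers (PoolParams, Posterior, Trajectory, ...)
  kinetics.py    forward flux model, screening, MH inversion, Q10 normalization
  upscaling.py   boosted-tree upscaling, tau/fraction maps, extrapolation flags
  emulator.py    reduced-complexity three-pool model + per-cell diagnosis
  refined.py     constrained model: modifiers, calibration, spin-up, projection
  forcing.py     climatologies and delta bias correction
  budget.py      spherical area accounting, stock changes, budget reductions
  synthetic.py   ground-truth world, incubation series and ESM ensemble
  pipeline.py    end-to-end orchestration and sensitivity experiments
  optimize.py    batched differential evolution
  io.py, cli.py  CSV/NetCDF/JSON round-trips and the click CLI
```

See `docs/methods.md` for the model equations, parameter choices,
numerical scheme and the limits of what the synthetic experiments can
show.
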