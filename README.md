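# firefreq

Fire-interval survival analysis for savanna landscapes.

Protected areas in fire-prone biomes such as the Brazilian Cerrado burn on
intervals of a few years. Managers need quantitative answers to questions
like *how often does each vegetation type burn*, *how does the chance of
burning change with fuel age*, and *does a parametric interval model
actually fit the censored record a satellite time series provides*.
`firefreq` implements the full statistical pipeline for answering them from
a multi-year stack of annual burned-area maps plus a land-cover map:

1. **Point-grid interval sampling** (`firefreq.censoring`) — a regular
   point grid (default 500 m) converts each point's fire-year sequence into
   complete fire intervals and single-censored boundary intervals
   (left-censored at the record start, right-censored at the record end).
2. **Discrete lognormal interval model** (`firefreq.model`) — the fire
   interval T (whole years between consecutive fires) has

   ```
   f(t) = Φ((ln t − µ)/σ) − Φ((ln(t−1) − µ)/σ)      interval distribution
   A(t) = 1 − Φ((ln t − µ)/σ)                        survival distribution
   λ(t) = f(t) / A(t−1)                              hazard of burning
   ```

   with Φ the standard normal CDF. (µ, σ) are estimated by maximum
   likelihood from the censored sample; the fit also reports the median
   interval (smallest integer ≥ e^µ), the mode (smallest integer >
   e^(µ−σ²)), and the hazard turning point (the fuel age where λ peaks).
3. **Goodness of fit** (`firefreq.gof`) — a Hollander–Proschan style
   censored-data statistic comparing the fitted survival function against
   the Kaplan–Meier estimate, standardized (parametric bootstrap under the
   fitted null) to an asymptotically standard-normal scale with two-sided
   p-values.
4. **Fire rotation statistics** (`firefreq.rotation`) — fire rotation
   period FRP = N·S/ΣA (years to burn an area equal to the burnable study
   area) and annual percent area burned APAB = 100/FRP, overall and per
   land-cover class.
5. **Renewal-process landscape simulator** (`firefreq.simulate`) — each
   cell burns with probability λ(fuel age) and resets its age on burning;
   used to validate the whole chain by parameter recovery on synthetic
   12-year records with realistic start/end censoring.

The package ships the published per-class parameter estimates for Jalapão
State Park (Tocantins, Brazil; 1997–2008 Landsat record) in
`firefreq.datasets` as verification anchors and realistic simulation
regimes.

## Worked example

Simulate a shrub-savanna landscape (µ=0.82, σ=0.66), sample it on the
point grid, and refit:

```python
import numpy as np
from firefreq import (ClassSpec, DiscreteLognormalParams, SimulationConfig,
                      extract_intervals, fit_mle, hp_test, simulate_history)

params = DiscreteLognormalParams(mu=0.82, sigma=0.66)
cfg = SimulationConfig(classes=[ClassSpec("SS", params, 1.0)],
                       shape=(45, 45), cell_size=500.0, burn_in=50, seed=101)
grid = simulate_history(cfg)                  # 12-year burn-mask stack
sample = extract_intervals(grid, spacing_m=500.0)
fit = fit_mle(sample, record_years=grid.n_years)
gof = hp_test(sample, fit.params, seed=1, record_years=grid.n_years)
print(f"mu={fit.params.mu:.3f} sigma={fit.params.sigma:.3f} "
      f"median={fit.median} mode={fit.mode} turning_point={fit.turning_point}")
print(f"GOF z={gof.statistic_std:.2f} p={gof.p_value:.2f}")
```

prints

```
mu=0.831 sigma=0.664 median=3 mode=2 turning_point=4
GOF z=-0.76 p=0.45
```

— the generating parameters are recovered to within ~0.01 from a single
2,025-point censored 12-year record, the derived descriptors say the median
interval is 3 years with the hazard of burning peaking at fuel age 4, and
the goodness-of-fit test (correctly) does not reject the model that
generated the data.

The `firefreq` command line chains the same steps over raster stacks:

```
firefreq simulate --out land/            # or bring your own burn rasters
firefreq extract land/ --out obs.csv
firefreq fit obs.csv --out fits.json
firefreq report land/ --out report/      # per-class summary table + curves
```

The numbered drivers under `analysis/` run the full study narrative:
published-parameter descriptors and curves (01), a seven-class synthetic
landscape (02), per-class fitting with parameter-recovery errors (03), null
calibration of the goodness-of-fit test (04), and rotation statistics with
the renewal-theory consistency check (05). Each writes its tables under
`results/`.

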