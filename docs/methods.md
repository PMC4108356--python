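# Methods

## The interval model

Fire frequency at a point is described by the distribution of the fire
interval T, the number of whole years between consecutive fires. `firefreq`
models T with a discrete lognormal: the lognormal distribution binned at
integer cut-points, so that

- f(t) = Φ((ln t − µ)/σ) − Φ((ln(t−1) − µ)/σ) for t = 1, 2, … (the t = 1
  term uses Φ(−∞) = 0 for the lower cut-point),
- A(t) = 1 − Φ((ln t − µ)/σ) is the probability of staying unburned for
  more than t years (A(0) = 1),
- λ(t) = f(t)/A(t−1) is the hazard of burning: the conditional probability
  of burning in the t-th year of fuel age given survival to the start of
  that year. The denominator is A(t−1) = P(T ≥ t), not A(t); only this
  convention makes λ a proper discrete hazard with
  Π_{u≤t}(1 − λ(u)) = A(t).

These satisfy the exact telescoping identity Σ_{t≤T} f(t) + A(T) = 1 for
every T, which the test suite checks to 10⁻¹² and which makes the model a
genuine probability distribution on the positive integers regardless of
(µ, σ).

Derived descriptors: the median interval is the smallest integer ≥ e^µ, the
mode the smallest integer > e^(µ−σ²), and the turning point the fuel age at
which λ attains its maximum (searched over 1..t_max, default 100 years,
ties to the smallest age). A turning point of 1 means the hazard only
decreases with fuel age. The lognormal hazard rises and then falls, which
matches the empirical behaviour of savanna fuels: flammability builds for
the first few years after a burn and long-unburned patches are rare.

## Sampling censored intervals from a burned-area stack

A regular point grid (default spacing 500 m, at least one cell) is laid
over the landscape; points on unburnable cover (sand, water) are dropped.
For a point with fire years y₁ < … < y_k inside the record [Y₀, Y₁]:

- complete intervals y_{j+1} − y_j (consecutive calendar-year fires give
  interval 1; sub-annual repeat burns are collapsed to one burn year);
- one left-censored observation of open length y₁ − Y₀ + 1 — the previous
  fire predates the record;
- one right-censored observation of length Y₁ − y_k — the next fire was
  not observed. Points that never burned yield a single right-censored
  observation spanning the whole record.

Censored lengths of 0 (fire in the last record year) and left-censored
lengths of 1 (fire in the first record year) carry no information and
contribute exactly 0 to the likelihood; they are retained in the output
(a flag drops them) so observation counts remain k + 1 per burned point.

## Likelihood, and why the boundary terms need care

The conventional censored-data log-likelihood is

  Σ_complete ln f(tᵢ) + Σ_right ln A(cᵢ) + Σ_left ln A(ℓᵢ − 1),

and `log_likelihood` computes exactly this by default. For the last
(right-censored) interval at a burned point this is correct: its censoring
time Y₁ − y_k is fixed once the interval starts, independent of the
interval's own length. The left boundary is different. The interval in
progress at the record start is a length-biased draw of T (the inspection
paradox: long intervals are more likely to straddle any fixed time point),
and what is actually observed is the forward recurrence time V = y₁ − Y₀ + 1,
whose distribution under a stationary renewal process is
P(V = v) = A(v−1)/E[T]. Using ln A(ℓ−1) alone — i.e. dropping the
−ln E[T] term — systematically favours parameter values with longer
intervals. On a 3,600-point synthetic shrub-savanna record the plain
likelihood estimates µ ≈ 0.95 when the generating value is 0.82; with the
renewal term the estimate is 0.82.

`fit_mle` therefore maximizes the stationarity-corrected likelihood by
default (`stationary=True`): left-censored observations contribute
ln A(ℓ−1) − ln E[T], and — when the record length N is supplied via
`record_years` — never-burned points (right-censored at length N, whose
"interval" straddles the whole window) contribute the exact
ln P(V > N) = ln Σ_{a≥N} A(a) − ln E[T] instead of ln A(N). The
never-burned term matters for slow-burning classes: for the dense-woodland
regime (E[T] ≈ 10 years against a 12-year record) it moves µ̂ from 1.93 to
1.82 for a generating value of 1.78. E[T] is computed as the survival tail
sum Σ_{a≥0} A(a), with a continuous-lognormal fallback for extreme
parameter values visited transiently by the optimizer.

Optimization is L-BFGS-B on (µ, ln σ) — the log parameterization keeps
σ > 0 without an active boundary — started from the mean and standard
deviation of the log complete intervals (σ₀ floored at 0.1). Samples with
fewer than 2 complete intervals are rejected as non-identifiable;
zero-variance samples converge to the σ lower bound (10⁻³) and are flagged
degenerate rather than failing.

## Goodness of fit for censored discrete data

The test statistic is C = Σ A₀(tᵢ)·ΔF̂(tᵢ), the jump-weighted average of
the fitted null survival function A₀ over the Kaplan–Meier estimate F̂
computed from complete and right-censored observations. Under the null C
estimates E₀[A₀(T)]. Two departures from the classical continuous-data
treatment are needed:

1. **Discrete null center.** For continuous T, E[S₀(T)] = 1/2; on integer
   support it is Σ_t f₀(t)·A₀(t) (≈ 0.42 for the shrub-savanna
   parameters), so the continuous centering constant would be wrong.
2. **Censoring-horizon truncation.** When censoring cannot exceed the
   record length, the Kaplan–Meier assigns no mass beyond the largest
   observable time and C is shifted below E₀[A₀(T)] by the truncated tail
   term. The statistic is therefore centered and scaled by the mean and
   standard deviation of C over a parametric bootstrap under the fitted
   null (default 1,000 seeded replicates), which reproduces both the
   discrete center and the truncation shift. The censoring distribution for
   the bootstrap is estimated from the sample by reverse Kaplan–Meier and
   paired with independent null interval draws. The uncensored analytic
   center is still reported for reference.

The standardized statistic is asymptotically standard normal under the
null; p-values are two-sided. Under simulation from the null (n = 300
window-censored observations, 1,000 replicates) the empirical type-I error
at α = 0.05 is 0.039 and the Kolmogorov distance of the statistic to
N(0, 1) is 0.02 — both recomputed by `analysis/04_gof_calibration.py` and
the acceptance suite.

Two classes of observations are excluded from the statistic (but not from
fitting): left-censored observations, which the standard Kaplan–Meier
cannot use, and never-burned points, whose fuel age at the record start is
unknown — entering them as age-0 censored observations dilutes the
young-age risk sets and produces spurious rejections (a standardized
statistic of −31 on a dense-woodland landscape where the model is true,
against 0.08 with the exclusion).

## Fire rotation

FRP = N·S/ΣA with N record years, S the burnable area (sand and water
excluded) and ΣA the cumulative burned area; APAB = 100/FRP, so
FRP·APAB = 100 identically. For a stationary renewal landscape the
long-run burned fraction per year is 1/E[T], so FRP converges to the mean
fire interval as the record lengthens — the package's rotation and
interval views of fire frequency are mutually consistent, and the test
suite checks convergence at 50/200/500-year records.

## The landscape simulator

Each cell holds a fuel age; each year a cell of age a burns with
probability λ(a+1) of its land-cover class and resets to age 0, else ages
one year. Initial ages are drawn from the equilibrium age distribution
(mass ∝ A(a), the stationary distribution of the age process) and a
50-year burn-in is discarded, so the emitted window is a stationary cut of
a long-running regime — exactly the situation the censoring conventions
and the stationarity-corrected likelihood assume. Identical seeds give
bit-identical burn masks.

Default study conditions mirror the emulated record: a 12-year window
(1997–2008), seven land-cover classes in their published area shares with
their published (µ, σ), 500 m sampling. Validation runs use 45×45 grids of
500 m cells (~2,000 sample points per class), chosen to match the order of
points per class the 500 m grid yields over the park.

What the simulator does *not* emulate: fire spread (cells are independent
by default; an optional majority-filter pass adds visually contiguous burn
scars without materially changing per-point marginals), ignition patterns,
weather and fuel-load dynamics, classification error in the burned-area
maps, and spatial autocorrelation of land cover. Passing recovery tests
therefore demonstrate the correctness of the statistical chain under the
model's own assumptions, not robustness to mapping error or spatial
dependence in real imagery.

Ages beyond the hazard lookup horizon t_max (default 100 years) burn with
the last defined hazard value and a warning is emitted; beyond the
numerical support of the interval distribution (survival underflow) the
last defined hazard is carried forward, a state unreachable without
burning.

## Numerical conventions

- All printed-value comparisons in tests round to two decimals, the
  precision of the published tables; intermediate files carry full
  precision and rounding happens only in the report layer.
- The turning-point search and curve exports use t_max = 100 years.
- Bootstrap and simulation seeds are explicit arguments and are recorded
  in run logs; the GOF bootstrap processes replicates in memory-bounded
  batches.
- Hazard evaluation raises beyond the support horizon (survival underflow)
  instead of returning 0/0.

## Known limitations

- The forward-recurrence likelihood terms assume the fire regime is
  stationary over (and before) the record; a trending regime would bias
  boundary terms.
- Intervals pooled across points of one class are treated as independent;
  spatially coherent burning would reduce the effective sample size and
  widen true confidence bands (not currently reported).
- The goodness-of-fit bootstrap conditions on an estimated censoring
  distribution and does not refit parameters per replicate; with estimated
  parameters the test is mildly conservative.
- Sub-annual fire recurrence is out of scope: multiple burns within one
  dry season collapse to a single burn year.
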