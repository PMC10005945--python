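# Methods

`rootzone` diagnoses the rooting-zone water-storage capacity S₀ of
vegetation — the total water plants can draw from below ground — from daily
time series of evapotranspiration (ET), precipitation, radiation and
(optionally) sun-induced fluorescence (SIF). This note records the model,
the numerical choices, and what the synthetic validation does and does not
demonstrate.

## The cumulative water deficit

The cumulative water deficit (CWD) is a running sum of daily ET minus
liquid-water infiltration P_in (rain plus snow melt), initiated on the
first day of net water loss (ET − P_in > 0) and terminated when rain
returns the sum to zero. Each initiation-to-termination span is an
*event*. While CWD > 0, all infiltration is assumed to reduce the deficit
(no run-off below saturation). Deficits that fail to reset within five
years ("runaway" accumulations — lateral inflows, irrigation, or data
bias) are flagged and excluded from every downstream statistic.

Snow is handled by a degree-day model: precipitation falls as snow below
0 °C (partition threshold), the pack melts above 1 °C at
1 mm d⁻¹ °C⁻¹, capped by the snow available. ET provided as a latent-heat
flux (W m⁻²) is converted to mm d⁻¹ with a pluggable latent-heat-of-
vaporization function; the default is the standard temperature-linear
λ(T) = (2.501 − 0.002361 T)·10⁶ J kg⁻¹.

Within each event, days after the deficit peak are masked for the
sensitivity analysis once rain has reduced the CWD below 90 % of the event
maximum: partial topsoil rewetting relieves stress before the accumulated
deficit is compensated, so those days would otherwise contaminate the
activity–CWD relation. The rule is applied retrospectively against the
event's final maximum; transient dips on the rising limb are retained
(they carry valid information — storage and deficit still mirror each
other exactly there).

## Diagnosing S₀ from vegetation activity

Under a single-store linear stress model, activity X is proportional to
relative storage, X = X₀·S/S₀. With CWD = S₀ − S this gives a straight
line in deficit space,

    X′(CWD) = a + b·CWD,   S₀ = −a/b,

where X′ is activity normalized by its radiative driver: the evaporative
fraction EF = ET/R_n, or SIF divided by incident short-wave radiation.
Normalization removes the seasonal energy cycle so the intercept is
stationary.

Per location the pipeline pools the unmasked days of the single largest
CWD event of each year (assigned to the year containing its deficit
maximum) and reduces them to the 90 % quantile of X′ in 50 evenly spaced
CWD bins (minimum 3 points per bin; the upper quantile suppresses activity
reductions not caused by water stress). A day's activity reflects its
start-of-day storage, so it is paired with the deficit accumulated
*before* that day; pairing with the end-of-day deficit would inject a
PET-dependent one-day lag into the slope.

Three candidate models are fitted to the binned profile: a straight line
and segmented (continuous broken-line) models with one or two change
points. Segmented fits use exhaustive grid search over bin-center break
candidates with at least five bins per segment — exact and deterministic
at ≤ 50 bins. Model choice is by BIC, counting each breakpoint as a
parameter.

A winning segmented model is only believed if its change point passes two
complementary tests at α = 0.05:

* a *parametric* t test of the slope-change (hinge) coefficients at the
  fitted break, Bonferroni-corrected for the number of break candidates
  searched (a conservative Davies-type bound on the selection effect);
* a *two-stage cluster bootstrap* (default 499 resamples): years are
  resampled with replacement, then days within each drawn year, the
  profile is rebuilt and the hinge coefficients re-estimated at the fixed
  break. The percentile interval must exclude zero. Resampling years
  captures event-composition uncertainty (each year contributes one
  event); resampling days captures the estimation noise of sparse
  high-CWD bins fed by a single deep event.

The two tests fail in different ways — the parametric test is blind to the
dependence structure, the bootstrap re-centers on quantile outliers — so
both must agree. In addition the change must be practically meaningful:
the largest slope change must amount to ≥ 20 % of the first-segment slope.
With very clean data, microscopic profile wiggles are otherwise
"significant" without constituting a distinct hydrological regime.

Classification follows the change-point verdict:

* **estimate** — no credible change point and a significantly negative
  linear slope (one-sided t, α = 0.05): S₀ = −a/b from the linear fit;
* **flattening** — credible change point whose post-break slope is
  significantly *less negative* than the first segment's (one-sided
  bootstrap quantile at α): part of the canopy draws on a distinct,
  larger store; no single S₀ describes the site;
* **rejected** — everything else.

Bins are unweighted in all fits (weighting by bin count was evaluated and
emphasizes exactly the dense low-CWD bins whose mixture composition is
least reliable).

## Extremes, depth conversion, return periods

Annual maximum CWD values (per 365-day year, over non-discarded days) are
fitted with a Gumbel distribution by maximum likelihood
(`scipy.stats.gumbel_r`); an L-moment estimator is available as a switch.
Standard errors come from the closed-form Gumbel Fisher information,
var(β̂) = 6β²/(π²n) and var(μ̂) = β²(1 + 6(1−γ)²/π²)/n. The T-year return
level is the closed form

    S_CWDXT = μ − β·ln(−ln(1 − 1/T)),   T > 1,

strictly increasing in T; the headline choice is T = 80 yr.

S_CWDXT converts to an apparent rooting depth z_CWDXT through a two-layer
plant-available water-holding-capacity (WHC) profile: a topsoil of fixed
thickness (default 300 mm) over a uniform subsoil extending indefinitely —
the inverse of a piecewise-linear cumulative storage curve, exact in
closed form. The pedotransfer function mapping texture to WHC is
pluggable; the default is the Saxton–Rawls regression for volumetric water
content at −33 kPa minus −1500 kPa, clipped into (0, 0.35) mm mm⁻¹.

The return period that reconciles activity-based and extreme-value-based
estimates is screened per coarse block (1° cells pooling up to 400
members; members without an S₀ estimate are excluded) over the discrete
grid 10–100 yr in steps of 10 and 150–500 yr in steps of 50. Per member,
bias = ln(S_CWDXT / S_activity); the best T minimizes |median bias|, ties
toward smaller T. The median bias is strictly increasing in T, so halving
the activity estimates moves the best T *down*. Single blocks scatter by
about one grid step under realistic noise; the modal value across blocks
is the estimator.

## Biome-level evaluation

Point observations of maximum rooting depth are aggregated to sites by
coordinates (statistic: maximum, matching the "maximum rooting depth"
semantics; mean available as a switch). Where a water-table depth is
known, both observed and predicted depths are capped by it (idempotent,
never increases a depth). Per biome (minimum three sites) the 10 % and
90 % empirical quantiles (linear interpolation of order statistics) of
observed and predicted depth are computed and correlated across biomes
(Pearson, with p-value); with fewer than two biomes the correlation is
reported as undefined.

## The synthetic validation world

All validation runs on a stochastic bucket water balance with prescribed
S₀, so every stage can be checked by parameter recovery:

* precipitation occurrence is a two-state Markov chain; wet-day depths are
  exponential with a seasonally modulated mean;
* PET and temperature are sinusoidal climatologies (365-day years, no
  leap days);
* the bucket updates explicitly: ET = PET·S/S₀ at start-of-day storage,
  S ← min(S₀, S + P_in − ET), excess is run-off. ET/PET = S/S₀ holds
  exactly, and the net-radiation and short-wave proxies are set equal to
  PET so that EF and SIF normalization are exercised literally;
* the SIF *yield* proxy is sif_slope·S/S₀ plus Gaussian noise
  (σ = 0.05, a realistic noise level for daily downscaled satellite
  fluorescence), truncated at zero; the stored SIF column is the yield
  times the short-wave proxy, because observed fluorescence scales with
  incident radiation — dividing by short-wave radiation in the pipeline
  recovers exactly the yield;
* five spin-up years are simulated and discarded so records start from
  the store's climatic equilibrium (a full store at t = 0 in a dry
  climate would register as one artificial runaway deficit);
* the two-store variant lets a fraction (default 0.3) of the surface draw
  on a store five times deeper; column ET is the area-weighted sum. This
  produces the flattening signature once the shallow store is exhausted.

Three hydroclimates are bundled, all with cool-season rain concentration
so that the wet season recharges the store between drydowns — the regime
in which the estimator's central assumption (events start from a full
store, so the intercept is the unstressed activity) holds:

| preset   | annual rain | annual PET | character                          |
|----------|------------:|-----------:|------------------------------------|
| ARID     | ~560 mm     | ~1,640 mm  | winter-wet steppe, long dry season |
| SEASONAL | ~1,100 mm   | ~1,280 mm  | Mediterranean, deep summer drydown |
| HUMID    | ~1,480 mm   | ~1,100 mm  | rain > PET, short dry spells       |

Validation scales: 30-year records, S₀ ∈ {50, 100, 200, 400} mm, 20 seeds
per cell for recovery; 50 seeds for flattening detection. Median recovery
error is ~6 % wherever the largest drydown probes ≥ 80 % of the store.
The residual positive bias (~5–6 %) is intrinsic to the upper-quantile
profile: the 90 % quantile of noise inflates the intercept but not the
slope, so −a/b overestimates by about z₀.₉·σ_noise relative to the
activity scale. In humid climates with large stores the deficit never
approaches S₀ and the estimate is a censored extrapolation; it then always
exceeds the largest observed CWD but need not approach the prescribed
capacity.

What the synthetic world does *not* emulate: spatially correlated forcing,
ET retrieval bias during drought, phenology and CO₂ effects on the
activity proxies, irrigation or lateral inflows, and real calendars with
leap days. Passing recovery here shows the inference machinery is
consistent with its own generative assumptions — not that those
assumptions hold for any particular satellite product.

## Degenerate inputs and tie-breaks

* Series shorter than 2 days, negative ET, or mismatched lengths raise
  errors; empty event sets yield an empty pooled table, distinct from an
  error.
* Annual maxima with zero spread raise a degenerate-fit error; fewer than
  5 usable years a sample-size error.
* Segmented ties break toward smaller RSS, then the leftmost break.
* Return-period ties break toward the smaller T (parsimony).
* Quantile convention everywhere: linear interpolation of order
  statistics (`np.quantile` default).
* Bootstrap resamples whose support leaves fewer than four bins on either
  side of a break are discarded (the hinge is ill-conditioned there); a
  verdict requires at least 20 valid resamples, otherwise the change
  point is not credited.

## Known limitations

* The flattening classification inherits the ambiguity of any
  change-point test: in regimes where annual events start from widely
  varying storage (semi-arid climates with large stores that never
  refill), the pooled upper-quantile profile bends for compositional
  reasons, and no test can fully distinguish that from a genuine second
  store. The bundled climates avoid this regime; real-world flattening
  calls in such climates deserve scepticism.
* The q90-induced intercept bias (+z₀.₉·σ) is not corrected; with the
  bundled noise level it is well inside the validation tolerance.
* MLE standard errors are asymptotic; for records much shorter than ~20
  years the L-moment switch is the more robust choice.
* The two-layer WHC profile has no bedrock cutoff; depths beyond a few
  metres should be read as "apparent" depth of the exploited store, not
  as a literal rooting depth.
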