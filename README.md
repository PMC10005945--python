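# rootzone

How much water can vegetation draw from the ground before it shuts down?
`rootzone` estimates the **rooting-zone water-storage capacity S₀** of an
ecosystem from daily hydrological time series, and converts it into the
apparent rooting depth that capacity implies. It is a library for
ecohydrologists working with flux-, reanalysis- or satellite-derived daily
series (ET, precipitation, radiation, SIF), with a thin command-line
wrapper for file-based pipelines.

## The method

1. **Cumulative water deficit (CWD).** A running sum of daily
   ET − P_in (P_in = rain + snow melt from a degree-day snow model),
   started on the first day of net water loss and reset when rain returns
   the sum to zero. Each span is a *CWD event*; accumulations that never
   reset within five years are discarded as "runaway".

2. **S₀ from the activity–CWD decline.** If activity X is proportional to
   the remaining store, normalized activity declines linearly with the
   deficit:

   X′(CWD) = a + b·CWD,  **S₀ = −a/b** —

   the deficit at which activity extrapolates to zero. Per location the
   unmasked days of each year's largest event are pooled, reduced to the
   90 % quantile of X′ in 50 CWD bins, and fitted with linear and
   segmented models (BIC selection). A robust change point with a flatter
   second segment is classified as **flattening**: part of the vegetation
   taps a distinct, larger store (groundwater, weathered bedrock) and no
   single S₀ applies.

3. **Extreme-value view.** A Gumbel fit to annual maximum CWD gives the
   deficit with return period T, S_CWDXT = μ − β·ln(−ln(1 − 1/T)), which a
   two-layer water-holding-capacity profile converts to an apparent
   rooting depth z_CWDXT.

4. **Return-period screening.** Pooling both estimates in coarse blocks
   and minimizing the median log bias over a discrete T grid reveals the
   drought rarity that rooting systems are apparently dimensioned for.

5. **Validation by construction.** A bucket water-balance simulator with
   *prescribed* S₀ (three bundled hydroclimates, optional two-store
   variant) closes the loop: the full pipeline recovers prescribed
   capacities to ~6 % median error and detects two-store worlds as
   flattening.

## Worked example

```python
import rootzone as rz
from rootzone.pipeline import PipelineConfig

cfg = rz.SimConfig(s0_true=200.0, years=30, seed=3, **rz.SEASONAL)
forcing = rz.generate_forcing(cfg)           # daily table incl. SIF proxy
record = rz.run_location(forcing, PipelineConfig(activity="sif"))
print(record["classification"], record["s0_estimate"])
```

prints

```
estimate 213.2...
```

i.e. the pipeline classifies the site as a clean single-store decline and
recovers the prescribed 200 mm capacity within ~7 % (the small positive
bias is the upper-quantile profile of noisy activity data; see
`docs/methods.md`). The same site with 30 % of its surface drawing on a
5× deeper store classifies as `flattening` and returns no estimate —
run `python examples/02_estimate_s0.py` to see both, and the other
`examples/*.py` scripts for the extremes, return-period and biome-
evaluation stages, each printing a few annotated numbers.

The CLI mirrors the library:

```bash
rootzone simulate --s0 150 --years 30 --climate seasonal --out forcing.csv
rootzone cwd forcing.csv --out cwd.csv --events-out events.csv
rootzone fit-sensitivity forcing.csv --activity sif
```

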