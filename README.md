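# bcellfate

Population-dynamics modelling of follicular mature (FM) and germinal center
(GC) B cells from busulfan-chimera fate-mapping experiments.

## The problem

In busulfan chimeras, the host's hematopoietic stem cells are replaced by
congenically marked donor cells without disturbing peripheral lymphocyte
compartments. Donor-derived B cells then percolate through development —
transitional stages T1/T2 in the spleen, then the mature compartments — and
the *rate* at which each downstream compartment approaches the chimerism of
its precursor reveals how fast that compartment turns over, while Ki67 (a
marker that persists for days after division, and is therefore inherited
across developmental stages) separates self-renewal from the influx of
recently divided precursors.

`bcellfate` implements this analysis as a reusable package for
quantitative immunologists:

* **Ki67-structured ODE models** of a compartment fed by an empirical
  precursor time course. Per subset and lineage ℓ ∈ {host, donor}:

  ```
  dK_hi/dt = a φ(t) S(t) χ_ℓ(t) κ_S + ρ (K_hi + 2 K_lo) − (β + δ(t)) K_hi
  dK_lo/dt = a φ(t) S(t) χ_ℓ(t) (1−κ_S) + β K_hi − (ρ + δ(t)) K_lo
  ```

  with per-capita recruitment φ, precursor size S and donor fraction χ,
  precursor Ki67-high fraction κ_S, division rate ρ, loss rate δ and
  Ki67-high→low transit rate β (transit time 1/β). Model families allow a
  single rate (δ, ρ or φ) to vary exponentially with host age, a two-subset
  kinetically heterogeneous pool, or a never-replaced "incumbent" host
  population.
* **Joint Bayesian inference** (MAP and affine-invariant ensemble MCMC) on
  total counts, normalized chimerism and host/donor Ki67 fractions, with
  model comparison by PSIS-LOO information criterion and pseudo-BMA weights.
* **Derived summaries**: residence time 1/δ, inter-division time 1/ρ,
  clonal lifespan 1/(δ−ρ) — the persistence timescale of self-renewing
  lineages and the timescale of donor replacement — influx rates, doubling
  times, with 95% credible intervals.
* **Age-structured extension** mapping cell age to Rag2-GFP fluorescence to
  discriminate rising recruitment from excess early-life death in young mice.
* **Ki67-reporter (YFP) label-dilution model** converting observed label
  decay into a lognormal prior on GC net loss rates.
* **Synthetic-data generators** reproducing the full statistical structure
  of the experiments (destructive sampling, three age-at-transplant groups,
  lognormal count noise, logit-normal fraction noise).

## Worked example

Simulate a 41-mouse FM cohort at the reference adult parameter values and
refit it:

```python
import numpy as np
from bcellfate import presets, simulate_cohort, fit_map, summarize_kinetics
from bcellfate.priors import default_priors

config, params, source = presets.fm_reference()
cohort = simulate_cohort(presets.fm_fig_design(seed=1), config, params, source)
fit = fit_map(cohort, config, source, default_priors(config, "FM"),
              presets.DEFAULT_NOISE, n_starts=4, seed=0)
s = summarize_kinetics(fit, config, source, t_ref=75.0)
print(f"residence time at 75 d: {s['residence_time_d']:.1f} d")
print(f"clonal lifespan at 75 d: {s['clonal_lifespan_d']:.1f} d")
print(f"daily influx: {s['influx_cells_per_day'] / 1e6:.2f}e6 cells/day")
print(f"Ki67 transit time: {s['ki67_transit_d']:.1f} d")
```

prints

```
residence time at 75 d: 35.1 d
clonal lifespan at 75 d: 38.1 d
daily influx: 0.85e6 cells/day
Ki67 transit time: 6.0 d
```

— recovering the generating values (residence 35 d, influx 0.87×10⁶/day,
transit 5.8 d) to within a few percent from 41 noisy mice. The same
machinery is available from the shell:

```bash
bcellfate simulate --subset FM --seed 1 --out cohort.csv
bcellfate fit --cohort-file cohort.csv --subset FM --families time_turnover
bcellfate summarize --subset GC_spleen
```

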