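# Methods

This note documents the models, the numerical and statistical choices, and
what the synthetic-data experiments do and do not establish.

## Compartment models

A peripheral B cell compartment (FM, splenic GC, or LN GC) is fed by a
precursor population whose size `S(t)`, donor chimerism `χ(t)` and
Ki67-high fraction `κ_S` are empirical functions of host age, fitted
independently and frozen before the main inference (two-stage estimation;
the precursor data are far more informative about the precursor than the
downstream fit could ever be, and freezing avoids feedback).

Within the compartment, cells are classified by lineage (host/donor) and
Ki67 status. Division places both daughters in the Ki67-high pool; Ki67
decays below the detection gate at rate `β` (transit time `1/β`); new
immigrants arrive Ki67-high with the precursor's fraction `κ_S`. Loss `δ`
pools death and onward differentiation. Summing Ki67 states gives the
unstructured dynamics `dN/dt = a φ S χ + (ρ − δ) N` per subset-lineage.

Six structural families are supported: homogeneous; time-dependent
turnover / division / recruitment, where exactly one of `δ`, `ρ`, `φ`
varies exponentially with *host age* (`x(t) = x0 · e^{r_x (t − 75 d)}`,
anchored at 75 days so base rates are quoted at a common reference age);
kinetic heterogeneity (two subsets with independent `δ`, `ρ`, sharing `β`
and the influx, split `α : 1−α`); and an incumbent variant with a constant
host-only pool that is never replaced. Host age, not time since transplant,
drives the modifiers because cohorts transplanted at different ages are
fitted jointly. The exponential form is implied by the constancy of the
published rate-doubling times.

**Initial condition.** Chimera compartments are unperturbed by the
conditioning, so at the transplant age the host pool starts at the model's
quasi-steady state under the source evaluated there (`N* = a φ S/(δ − ρ)`,
Ki67 split at its equilibrium fraction `k* = ((δ−ρ)κ_S + 2ρ)/(β+δ+ρ)`);
donor compartments start empty. Parameters with `δ ≤ ρ` at the transplant
age admit no pre-transplant steady state and are rejected (−∞ likelihood).
The incumbent pool is treated as Ki67-low (a long-established resting
population); its size only enters the chimerism plateau.

## Numerics

Every subset-lineage reduces to a cascade of two *scalar linear* forced
ODEs (first `N`, then `K_hi` given `N`). The default integrator advances
each with its exact constant-coefficient propagator per step (coefficients
and forcing at the step midpoint, step 0.5 d), accumulated in a log-sum-exp
form that cannot overflow however stiff the rates (GC loss rates approach
2/day, so naive integrating factors overflow over 600-day spans). The
scheme is unconditionally stable, strictly non-negative, and *exact*
whenever rates and forcing are constant — which is what the closed-form
oracle tests exercise at 1e−6. For time-varying rates the error is second
order in the step times the coefficient variation (slow: weeks to months);
cross-checks against LSODA (`backend="lsoda"`, rtol 1e−8) agree to ~1e−4
relative. The exponential stepper is roughly 40× faster than LSODA, which
is what makes multistart MAP, MCMC and the replicate studies tractable.
Output ages are inserted into the internal grid, so no interpolation error
is added. The degenerate case `δ = ρ` is handled by the `expm1`-based step
weights, not by dividing by a vanishing rate.

## Observation model and likelihood

Each mouse is destructively sampled once and contributes up to four
independent components: log total counts (Gaussian, sd 0.3), logit
normalized chimerism (sd 0.3), and logit Ki67-high fractions of host and
donor cells (sd 0.2). These scales respect positivity and the [0, 1] range
and are the package's stand-in for the study's unpublished likelihood; the
sds were chosen once to match the visual scatter of the published cohort
figures. Fractions are clipped to [1e−4, 1−1e−4] before the logit — model
predictions of exactly 0 or 1 are thereby guarded, and donor Ki67 is
reported missing (never zero) while the donor pool is below a 1e−3
normalized-chimerism detection floor. Within-mouse correlation between
components is ignored, matching the granularity of the description the
analysis is based on.

## Priors

Rates carry lognormal priors specified on the log scale, proportions
logit-normal, signed rate modifiers normal(0, 0.01/day). Loss and division
priors are centred by compartment class: median residence ~1 month for
naive-like pools, ~1 day for germinal centers (GC B cells are known rapid
cyclers); both have sdlog 1.5, weak enough that the data dominate wherever
they are informative. The Ki67 transit prior (lognormal, median 4 d, sdlog
0.5) encodes the reported ~3–4 day persistence of Ki67 after mitosis; for
FM fits the donor–host Ki67 transient identifies `β` from data, while for
GC fits (both lineages saturated near `k* ≈ 0.95`) the prior carries most
of the weight. The YFP dilution experiment provides an optional extra
lognormal factor on the net loss rate `δ − ρ` (influx-weighted mean for
two-subset models), mirroring the study's use of the reporter to tighten
GC posteriors; its scale has a floor of 0.3 log units so the simple
exponential-dilution model behind it is never over-trusted.

## Estimation and model comparison

MAP: multistart (default 16 starts drawn from the prior; infeasible draws
are resampled) Nelder-Mead followed by an L-BFGS-B polish; the observed
information at the optimum furnishes a Laplace covariance used for
intervals when no MCMC is run. Label switching in the two-subset model is
broken by canonical relabelling (`δ₁ > δ₂`: subset 1 transient, subset 2
persistent). Sampling: emcee's affine-invariant ensemble, walkers
initialised near the MAP; convergence is summarised by split-R̂ across
walkers and the mean acceptance fraction, and non-converged results are
flagged, never silently returned. Pointwise log-likelihoods (one entry per
observation component) over thinned posterior draws feed arviz's PSIS-LOO;
models are ranked by LOO-IC with pseudo-BMA weights `∝ exp(−ΔLOOIC/2)`.
WAIC is the flagged fallback when PSIS fails outright. Laplace draws are
*not* used for LOO: the Gaussian approximation is biased against the
weakly identified two-subset model.

Credible intervals on derived quantities are percentile intervals of the
functional over draws; for influx-%-of-pool the pool size per draw rescales
the MAP pool by the draw's quasi-steady-state pool to avoid one ODE solve
per draw (the time-dependence correction factor is nearly
parameter-invariant over the posterior's support). A clonal lifespan with
`δ ≤ ρ` is reported as infinite, never as a negative number.

## Reference parameter sets

`presets` encodes published adult-mouse estimates: FM (time-dependent
turnover from T1; residence 35 d at 75 d rising to 42 d at 300 d,
inter-division 400 d, transit 5.8 d, influx 0.87×10⁶/day), splenic GC
(time-dependent recruitment from T2; residence 0.55 d, clonal lifespan
29 d, influx doubling every 230 d), and LN GC (two subsets from FM;
residence 0.51/0.73 d, lifespans 21/140 d, persistent share 0.77 at 75 d).
Published posterior medians of nonlinear functionals do not compose
exactly; where they conflict, residence times and clonal lifespans are
taken as primary and division rates derived (splenic GC inter-division
becomes 0.561 d vs the printed 0.56 d), and the LN GC influx shares are set
so both subsets sit at quasi-steady state with the printed pool shares.
Precursor sizes use representative values (T1 ≈ 10⁷, T2 ≈ 5×10⁶,
FM ≈ 3.3×10⁷ cells) so absolute influxes match the published cells/day.
A consequence worth knowing: at quasi-steady state the splenic GC influx
is (δ−ρ) + r_φ ≈ 3.5 %/day of the pool, below the printed 5 %/day, which
is not QSS-consistent with the same row's residence and lifespan.

## Synthetic data

The cohort generator emulates: three age-at-transplant groups (windows
<8, 8–12, >12 weeks; transplant ages rounded to whole weeks like batched
experimental cohorts), destructive sampling at ages up to 600 days,
lognormal count noise and clamped logit-normal fraction noise, saturating
precursor chimerism (~95 % of its stable value within 4 weeks for
bone-marrow-proximal precursors; rate 1/38 d for FM acting as the LN GC
source, inheriting FM's own slow replacement), and high precursor Ki67
(0.8 for T1, 0.7 for T2, 0.13 for FM). One integer seed expands into
independent substreams per mouse. What it deliberately does not emulate:
between-mouse kinetic variability (all mice share one parameter set),
within-mouse correlation across observables, lymph-node-to-lymph-node
chimerism variation, and cohort batch effects. Passing recovery tests
therefore demonstrates identifiability and correctness of the estimation
machinery under the stated noise — not robustness to biological
heterogeneity absent from the generator.

The Rag2-GFP generator maps cell age (time since FM entry; upstream decay
is absorbed into the entry fluorescence `g0`) through
`g(a) = g0 e^{−γ a}`. Defaults — `g0 = 1000` a.u., decay `γ = 0.05`/day,
positive gate 550 (cells younger than ~12 d), influx ramp logistic with
midpoint 30 d and width 15 d, excess early death `0.15 e^{−0.03 t}`/day —
were calibrated once so the fixture reproduces the documented qualitative
behaviour quantitatively: GFP⁺ MFI varying <10 % over host ages 20–100 d
under rising influx while total MFI falls >30 %, and a ~3-fold overshoot
of young FM counts when adult kinetics are extrapolated from age 10 d.
MFI noise defaults to 5 % (lognormal): population-mean fluorescence is far
more reproducible than cell counts, and at materially larger noise the two
young-mouse variants (whose held-out GFP⁺ predictions differ by ~4 % rms)
would be indistinguishable by any method. The boundary cohort at the
10-day tracking start carries a steady-state exponential age profile;
its influence decays within ~3 residence times.

The YFP generator labels a fraction `f0` instantaneously at the end of
tamoxifen induction (induction-window dynamics out of scope) and scores a
binomial sample of cells per mouse; the labeled fraction decays at the net
loss rate because division conserves the label — the identity that makes
the reporter measure clonal, not cellular, lifespan, and which is verified
against an explicit birth-death-influx simulation in the tests.

## Problem sizes

Replicate studies use compact cohorts (one transplant date per group) so
each likelihood needs three ODE solves: interval-coverage uses 20
replicates of 15 mice with 12-walker, 250-step chains; model-selection
recovery uses 10 replicates of 60 mice with 16-walker, 260-step chains.
These sizes give stable Monte-Carlo behaviour for the properties checked
(coverage counts, selection frequencies) and are the package's test-scale
defaults; the recovery experiments mirroring the published cohorts use the
published sizes (41 / 24 / 23 mice) with multistart MAP.

## Known limitations

* The empirical source forms, the observation-noise likelihood and the
  priors are the package's own reconstructions of unpublished choices; all
  are config-replaceable.
* Laplace intervals (used when MCMC is skipped) understate skew for weakly
  identified parameters such as the FM inter-division time.
* The "T1+T2" precursor option pools the two transitional stages into a
  single empirical curve rather than modelling them separately.
* Fitting assumes one observation per mouse; longitudinal (repeated)
  sampling would require a correlated observation model.
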