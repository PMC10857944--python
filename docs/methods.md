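# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Data model

A survey is a deployments table (one row per station: active interval,
land-cover class) and a detections table (station, species, timestamp).
Deployment intervals are closed-open `[start, end)` so effort accounting is
unambiguous: a detection stamped exactly at `end` is a reject. Timestamps
are timezone-naïve local civil time; the analysis uses only differences and
time-of-day within one site and season, so no DST handling is attempted.
Land cover is a six-class factor (clearfell, coniferous plantation,
grassland, heathland & shrubland, wetland, woodland). Species labels are
case-folded to snake_case on load; `human` is an ordinary label. Detections
outside their station's window are collected into a rejects report rather
than silently dropped; structural problems (unknown station or land cover,
unparseable timestamp, duplicated deployment rows) are hard errors.

## Independence filtering

Two readings of the 30-minute rule exist in practice and the package
implements both behind `independence_mode`:

* `rolling` (default): the gap is measured from the immediately preceding
  detection of that species at that station. A burst of images stays one
  contact for as long as no inter-image gap exceeds the window, which is
  how photo "sequences" behave in tagging software.
* `from_contact`: the gap is measured from the opening image of the current
  contact, chopping unbroken sequences every 30 minutes.

"Greater than 30 min" is read strictly: a gap of exactly 30:00 merges.
The filter cannot distinguish individual animals; two different individuals
of one species inside the window count as one contact. That is a known
divergence from workflows where taggers can identify individuals.

Naïve occupancy uses stations with non-zero effort as its denominator.
`days_per_contact` is total trap-days over total contacts and is reported
as absent for species never contacted.

## Detection-rate models

Per species, station counts are fitted by maximum likelihood to an NB2
negative binomial with log link,

```
count_i ~ NB(mu_i, theta),   log mu_i = x_i' beta + log duration_i,
```

where `x_i` holds an intercept, five land-cover indicators against the
reference (`clearfell` by default) and the station's human detection rate.
The engine is `statsmodels` discrete NB with `alpha = 1/theta` estimated
jointly; Wald SEs and two-sided normal p-values follow. Overdispersion is
diagnosed on the matching Poisson GLM as Pearson χ² / residual d.f., with
verdict threshold 1.4 (configurable) — a conventional cut-off above which
Poisson variance is untenable on ecological count data.

Pseudo-R² is Nagelkerke (Cragg–Uhler), computed against an
intercept-plus-offset null refitted with the same NB engine. Which variant
a given table-formatting package prints is often unstated; the metric name
is therefore always printed alongside the value.

Estimated marginal means condition the covariate at its across-station
arithmetic mean (the standard least-squares-means convention) and fix the
offset at one trap-day so response-scale EMMs read as contacts/day.
Pairwise contrasts are EMM differences; the covariate term cancels, so the
contrast of a level against the reference is exactly that level's
coefficient. P-values are unadjusted by default, with a Tukey HSD option
via the studentized-range distribution at large d.f. (matching the
asymptotic z reference); the adjustment used is recorded in the output.

Degenerate designs are surfaced, not repaired: a land-cover level with no
events drifts to a large negative estimate with an enormous SE and is
flagged (`separation`, default threshold SE > 10 on the log scale); a
predictor column with no variation at all is excluded from the optimisation
and reported as NaN with the flag set. Fit tolerances: statsmodels Newton
with BFGS fallback, max 200/500 iterations; if no Wald covariance exists at
a degenerate optimum (dispersion on its boundary), SEs are reported NaN
rather than invented.

Offset correctness: doubling every duration and count leaves rate
coefficients unchanged exactly under a Poisson likelihood; under NB2 with
jointly re-estimated dispersion the invariance is approximate (empirically
within ~0.01 log units at n = 150), which is what the test suite asserts.

## Time-interval randomization test

For a directed pair, each follower contact contributes the waiting time to
the most recent *preceding* leader contact at the same station (ties in
time do not count as preceding); follower contacts with no prior leader at
their station contribute nothing. Intervals are pooled across stations and
summarised by their median. A `first_after_leader` pairing mode (each
leader's first subsequent follower) is available as a sensitivity switch,
as is a `max_lag_hours` cap; neither is default because the base definition
makes no such restriction.

The null re-timestamps each follower contact with a calendar date uniform
over its station's deployed dates and a time of day drawn from the
follower's diel activity pattern — by default the empirical distribution of
its observed contact clock-times pooled across stations, which is
assumption-free; a von Mises kernel-smoothed option exists. Draws landing
outside the effort window (possible on partial first/last days) are
rejected and redrawn. Randomized contacts are *not* re-passed through the
independence filter: the null permutes filtered contacts as-is, conserving
per-station follower counts by construction. Leader and third-species
contacts are untouched.

With 1000 replicates (default), Q is the proportion of valid null medians
strictly above the observed median, replicates with no intervals being
excluded and counted (a result is marked unreliable above 20% invalid).
Null medians exactly equal to the observed median add 0.5 to Q — an
unbiased two-sided treatment of ties, which are possible at minute
resolution. Then `p = min(Q, 1-Q) × 2`, capped at 1; a p of exactly 0 is
displayed as `< 1/reps` because the Monte-Carlo resolution cannot support
a smaller claim. The percent difference `100 × (null median − observed) /
null median` is positive for attraction. Multiple testing across the 12
ordered pairs is deliberately not corrected; the output says so.

Reproducibility: each pair runs on a deterministic RNG substream derived
from the master seed and the pair's index, so per-pair results are
independent of execution order.

Pooling across stations before taking the median (rather than summarising
per-station medians) is the package's reading of per-camera interval
calculation feeding a single median per pair.

## Synthetic surveys

The generator emits contact-level events directly with the structure the
analysis assumes: per station × species counts from
`NB(duration × rate × exp(land-cover offset), theta)`, event times placed
independently given the count (uniform date + diel clock-time), humans from
their own diurnal profile independent of animals, and optional directed
attraction that moves a fraction π of follower events to an
`Exponential(τ)` lag after a uniformly chosen same-station leader event —
counts conserved, only timestamps move. Diel profiles are mixtures of
wrapped von Mises bumps so crepuscular peaks wrap correctly at midnight.
A burst expander (each contact → 1–5 images within 2 min, on by default)
gives the independence filter real work; burst images are clipped at the
deployment end.

`preset_paper_like()` is the reference regime: 39 stations split
2/8/8/6/5/10 across the six classes, 28-day deployments, four species with
site-mean rates 0.60 / 0.12 / 0.04 / 0.11 contacts per day, land-cover
fold-changes shaped like the fitted coefficients of the study system
(including the degenerate wild-boar wetland cell), NB θ = 1, crepuscular
deer, more nocturnal boar, diurnal humans at 0.30 contacts/day, and one
attraction rule (roe deer → sika deer, π = 0.5, τ = 1 h). All stations
share one start date; staggered deployment starts are inert for the
analysis (only per-station windows and differences matter) and are not
emulated. `preset_parameter_recovery()` is a balanced 200-station,
single-species regime (known effects +1.0/−0.5/+0.3/+0.8/−1.0, θ = 2,
uniform diel) used for confidence-interval coverage checks.

What the generator does **not** emulate: spatial autocorrelation between
stations, animal movement and home ranges, seasonal trends, detectability
differences between stations or species, group-size variation, camera
failure part-way through deployment. Passing tests therefore show the
pipeline recovers the truth *under the model's own assumptions*; they say
nothing about robustness to spatial structure or detectability bias in
real surveys.

## Validation sizes and results policy

The test suite and acceptance script validate at these problem sizes,
chosen to give tight Monte-Carlo error at desk scale: type-I error of the
interval test over 300 attraction-free surveys at 200 replicates each
(accept 0.02–0.08 at α = 0.05); power over 100 seeds of the preset regime
(expect ≥ 80%, with no uninvolved pair flagged in > 15% of seeds);
coverage of 95% Wald CIs over 200 × 200-station surveys (accept
0.95 ± 0.04); brute-force oracle equivalence of the filter and the
interval pairing on random streams of ≤ 30 events. Every number in the
README's worked example is actual package output at the stated seeds.

## Known limitations

* The NB engine can sit at the `alpha → 0` boundary on equidispersed data;
  estimates remain valid, Wald SEs may be absent (reported NaN).
* The empirical activity resampler cannot produce clock-times never
  observed; for very sparse followers the kernel option is preferable.
* The interval test conditions on observed leader times; it does not model
  leader-side randomness.
* Contacts are counts of events, not individuals; group size is out of
  scope throughout.
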