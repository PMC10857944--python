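# ctstia — camera-trap spatiotemporal interaction analysis

`ctstia` analyses multi-species camera-trap surveys of the kind used to
study land-cover preferences and interspecific interactions in ungulate
communities (sika deer, roe deer, red deer, wild boar and similar systems).
It is aimed at ecologists who have a table of time-stamped species
detections and a table of camera deployments and want three things:

1. **Independent contacts.** Raw detections are collapsed with the standard
   30-minute independence rule: consecutive records of the same species at
   the same station separated by more than 30 min open a new "contact".
   Per-species summaries (naïve occupancy, total contacts, mean ± SD
   detection rate, trap-days per contact) follow.

2. **Land-cover preference models.** Per species, station contact counts
   are modelled with a negative binomial GLM

   &nbsp;&nbsp;&nbsp;&nbsp;`count_i ~ NB(mu_i, theta)`, `log mu_i = beta0 +
   beta_landcover(i) + beta_h * human_rate_i + log(duration_i)`

   so coefficients are log differences in *detection rate* (contacts per
   trap-day) against a reference land cover, with human disturbance as a
   covariate and effort as an offset. A Pearson dispersion diagnostic
   against the matching Poisson fit, Nagelkerke pseudo-R², estimated
   marginal means per land-cover class, and all pairwise contrasts (raw or
   Tukey-adjusted) are provided. Empty design cells (complete separation)
   are flagged, never hidden or regularised.

3. **Spatiotemporal interaction tests.** For each directed species pair the
   statistic is the pooled median waiting time from each follower contact
   back to the most recent preceding leader contact at the same station.
   A null distribution is built by re-timestamping follower contacts with a
   random deployment date and a time of day resampled from the follower's
   own diel activity pattern, 1000 times; with Q the proportion of null
   medians above the observed one, `p = min(Q, 1-Q) × 2`. A positive
   percent difference (observed median shorter than null) indicates
   attraction, negative indicates avoidance.

A synthetic survey generator with known ground truth (land-cover effects,
overdispersion, diel profiles, optional injected attraction) makes every
stage testable end to end without any field data.

## Worked example

```python
import ctstia as ct

# simulate a 39-station, 28-day survey with an injected roe -> sika attraction
dataset, truth = ct.simulate_survey(ct.preset_paper_like(), seed=7)

contacts = ct.filter_independent(dataset)            # 30-min rule
print(ct.summarize_species(contacts, dataset, "sika_deer"))

hr = ct.human_detection_rates(contacts, dataset)
fit = ct.DetectionRateModel.from_survey(contacts, dataset, "sika_deer", hr).fit()
print(fit.summary())

res = ct.TimeIntervalTest(contacts, dataset, ("roe_deer", "sika_deer")).fit(
    reps=1000, seed=3)
print(res.summary())
```

prints (abbreviated):

```
SpeciesSummary(species='sika_deer', naive_occupancy_pct=82.05...,
               total_contacts=472, mean_detection_rate=0.432...,
               days_per_contact=2.31...)

Negative binomial detection-rate model — sika_deer
  stations: 39   reference land cover: clearfell
  theta (NB size): 1.063   log-likelihood: -129.66
  pseudo-R2 (Nagelkerke): 0.30
  Poisson dispersion ratio: 10.51 (overdispersed)

  predictor                 estimate   std err       p  rate ratio
  intercept                    -3.69      1.28   0.004        0.02
  coniferous_plantation         3.16      1.29   0.014       23.50
  grassland                     3.32      1.27   0.009       27.69
  ...

Interval test roe_deer -> sika_deer (most_recent, reps=1000)
  observed median: 16.37 h over 191 intervals
  null median: 52.76 h (95% band 42.57 - 63.47)
  pct difference: +69.0% (attraction direction)
  Q = 1.000   p = < 0.001
```

The species summary reads as one Table-style row: the species was seen at
82% of stations, every 2.3 trap-days on average. The GLM says sika
detection rates are ~28× higher in grassland than clearfell
(`exp(3.32)`), counts are overdispersed (Pearson ratio 10.5 ≫ 1), and the
interval test recovers the injected attraction: sika arrive after roe far
sooner (16.4 h) than the null expects (52.8 h), p below the Monte-Carlo
resolution.

The same pipeline runs from the shell on any pair of CSVs:

```bash
ctstia simulate --seed 7 --out survey/
ctstia run-all --detections survey/detections.csv \
               --deployments survey/deployments.csv \
               --reps 1000 --seed 3 --out results/
```

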