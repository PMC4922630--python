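# nettrans

Estimation of one-year **net transition probabilities** between ordered
body-mass-index categories — normal weight, overweight, obese — from
repeated **cross-sectional** survey data.

## The problem

Longitudinal cohorts spanning early childhood to late adulthood rarely
exist, yet public-health planning needs to know *at which ages* populations
move between weight categories. When the age-specific transition regime is
approximately stable over the period covered by a few survey cycles, the
*net* flow between adjacent categories is identified from cross-sections
alone: if the prevalence of normal weight falls from p₁(a) to p₁(a+1)
between consecutive ages, a net p₁(a) − p₁(a+1) of the population crossed
the normal/overweight boundary upward. Individual (gross) transition rates
remain unidentified — only the excess of one direction over the other is.

## The estimator

For each sex-by-group stratum, three steps:

1. **Prevalence smoothing.** A survey-weighted multinomial logit with the
   log-odds of each category (vs normal weight) modeled as a penalized
   B-spline (P-spline) in age over 2–80 years, smoothing parameter chosen
   by AIC, and a PSU-clustered sandwich covariance for the coefficients.
2. **Transport.** Between every pair of consecutive-age prevalence vectors
   p(a), p(a+1), the one-year flows x_ij minimize Σ c_ij x_ij subject to
   the marginal constraints, with "economy of movement" costs
   c_ij = (0, 6, 17) for zero-, one- and two-step moves (staying is
   cheapest; two one-step moves undercut one jump). The optimal plan's net
   boundary flows have a closed form — boundary k's net flow is
   F_p(k) − F_q(k) — and dividing by the origin category's prevalence gives
   the net transition probability; the disfavored direction is reported
   as 0.
3. **Uncertainty.** Parametric bootstrap: spline coefficients are resampled
   from their asymptotic normal distribution, the surface rebuilt, nets
   recomputed, and percentile 95% intervals taken per age and boundary.

Supporting analyses: cost-constant calibration against longitudinal
trajectories (the nets are provably cost-invariant across valid constants,
and the calibration profile documents that), cross-cycle stability
validation by forward-projecting an earlier cycle onto later ones, and
extrapolation of probabilities to net numbers of persons using census
population counts.

## Worked example

The package's own defining example: in a one-year cohort of 100
normal-weight 18-year-olds, 10 move up to overweight while 3 overweight
participants move down — a net of 7 people, i.e. a 7% net transition
probability:

```python
>>> from nettrans.experiments import worked_example
>>> worked_example()
{'empirical_net_prob': 0.069999..., 'transport_net_prob': 0.069999..., 'n_normal': 100}
```

Both routes — counting the longitudinal moves directly, and solving the
transportation problem on the implied marginal prevalences — give 7%.

## Analysis walkthrough

The `analysis/` scripts run the whole study on a synthetic population with
known truth (no downloads needed); each prints what it found and writes its
tables under `results/`. Running them in order produces, for example:

```
$ python analysis/01_simulate_cohort.py
true overweight->obese net at age 2: 12.1% (peak of the regime)
true normal->overweight net peaks at age 24: 5.5%
$ python analysis/02_classify.py
exclusions by reason: {'pregnancy': 216, 'amputation': 37, 'missing_bmi': 121}
agreement with generating category: 100.00%
$ python analysis/05_calibrate_validate.py
calibration grid [(1, 3), (6, 17), (10, 25), (6, 11)]: best (0.0, 1.0, 3.0)
valid-candidate MSE spread: 0.00e+00 (ties, as expected)
```

The simulated regime peaks exactly where the estimator should find it (the
overweight-to-obesity net at age two), every valid cost triple yields
identical nets, and cycles drawn from the same regime pass the stability
check while a +50% drifted cycle is flagged.

A command-line interface mirrors the stages
(`nettrans simulate|classify|prevalence|nets|bootstrap|calibrate|validate|extrapolate|run`).

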