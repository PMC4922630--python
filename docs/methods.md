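# Methods

This note documents the statistical model behind `nettrans`, the knobs that
matter, the synthetic data the tests rely on, and the numerical choices
made where the design was open.

## Model and identifying assumption

Weight status is a three-state ordered variable: normal weight
(adult BMI < 25 kg/m², child BMI-for-age < 85th percentile), overweight
(25–29.99; 85th–95th), obese (≥ 30; > 95th). Underweight (BMI < 18.5) is
folded into normal weight — the model has no underweight state and the
category is rare in the populations of interest — with the folded count
logged.

The population is assumed to evolve by an age-specific one-year transition
regime that is *stationary over the period spanned by the survey cycles*.
Under stationarity, consecutive ages in one cross-section stand in for
consecutive years of one cohort, so the change in category prevalence
between age a and a+1 identifies the **net** flow across each adjacent
category boundary. Gross flows are not identified; the disfavored
direction of each boundary is reported as zero by convention.

## Prevalence smoothing

Per sex-by-group stratum, category prevalence over age 2–80 is estimated
by a weighted multinomial logit: the log-odds of overweight and obese
versus normal weight are cubic B-splines in age. The basis uses equally
spaced knots extended beyond [2, 80] (20 interior knots by default) with a
second-order difference penalty on adjacent coefficients — the canonical
P-spline pair, whose infinite-penalty limit is a straight log-odds line.
One smooth spans the child/adult classification switch at age 20; no break
is modeled there.

* **Weights** are survey weights, normalized to sum to the sample size, so
  all output is invariant to weight rescaling. Pooling cycles divides each
  cycle's weights by the number of cycles.
* **Smoothing parameter** λ is chosen by AIC (−2·loglik + 2·edf, with
  edf = tr(A⁻¹ A_unpen)) over a log-spaced grid 10⁻²–10⁴, warm-starting
  Newton at each step. The fit maximizes the penalized weighted
  log-likelihood by Newton-Raphson with step halving; convergence is
  declared on the Newton decrement (scale-invariant, robust to the extreme
  Hessian conditioning that very large penalties induce).
* **Covariance.** Coefficient uncertainty is a cluster-robust sandwich
  A⁻¹(B + λS)A⁻¹, clustered on PSU-within-stratum (record-level when no
  design columns are present). The λS term — the penalty curvature added
  back into the meat — is the robust analogue of the Bayesian P-spline
  covariance; without it, intervals for penalized smooths systematically
  ignore smoothing bias and undercover. With it, simulated across-the-
  function coverage of the downstream net-transition intervals is ≈ 95–97%
  at nominal 95%.
* Degenerate strata (a single category present) return a deterministic
  0/1 surface with a warning; absent categories get structural-zero
  probabilities.

## Transportation step

Between p(a) and p(a+1) the flow matrix minimizes Σ c_ij x_ij subject to
row sums p(a) and column sums p(a+1), x ≥ 0. Costs depend only on the step
distance |i−j|, with constants (0, 6, 17) by default: staying is cheapest
and the two-step cost strictly exceeds two one-step costs ("economy of
movement", constants calibrated externally against longitudinal weight
trajectories). Validity (strict convexity in step distance) is enforced at
construction.

For any valid cost matrix the optimal plan's net flow across boundary k is
F_p(k) − F_q(k) — a closed form used both as an independent oracle in tests
and as the fast path inside the bootstrap. The LP itself is solved by
HiGHS; when the optimum is degenerate the monotone (north-west-corner,
non-crossing) plan is reported after verifying its cost matches the LP
optimum, making plans reproducible without affecting nets.

Net probabilities divide the favored direction's net flow by the origin
category's prevalence (normal for upward crossings of the first boundary;
overweight for the downward first-boundary and upward second-boundary
crossings; obese for downward second-boundary crossings). A flow can
exceed its origin category's own mass when upstream mass cascades through
within the year; the reported probability is capped at 1. Marginal-sum
mismatches up to 10⁻⁶ are renormalized; anything larger is an error, since
upstream surfaces are normalized exactly.

## Bootstrap

Coefficients are resampled from N(β̂, V̂) — sampling in coefficient space,
so every replicate surface is automatically a proper probability surface —
and nets recomputed per replicate; intervals are percentile-based, 1,000
replicates by default (a warning below 100). V̂ is symmetrized and
eigenvalue-clipped at zero before factorization; a materially negative
eigenvalue triggers a nearest-PSD warning. Identical seeds give bit-
identical intervals. Percentile intervals were chosen over BCa for
simplicity and because the sampled statistic is a smooth functional of an
asymptotically normal quantity.

## Calibration and stability validation

* **Empirical nets** from longitudinal records count one-year boundary
  crossings among individuals observed at both ages (a two-step move
  crosses both boundaries), netting up against down and dividing by the
  origin-category count.
* **Calibration** scores each candidate (c₁, c₂) with c₀ = 0 by the mean
  squared difference between LP nets (from cross-sectional prevalence) and
  empirical longitudinal nets. Because nets are cost-invariant across
  valid candidates, the profile ties to numerical precision; the search
  documents that insensitivity, rejects invalid candidates (2c₁ ≥ c₂ or
  c₀ ≥ c₁), and breaks ties by grid order. The discrepancy metric is our
  choice; so is the tie-break.
* **Stability** projects the earlier cycle's prevalence forward
  (default horizon two years, matching the spacing of biennial survey
  cycles) using its own nets and compares with later cycles' independently
  fitted curves. A cell (age, category) is discrepant when
  |predicted − observed| > 3 × the combined bootstrap SE; a cycle is
  flagged unstable when more than 10% of cells are discrepant. The 3-SE
  cell rule and 10% fraction are our operationalization of a qualitative
  judgment; at these defaults the simulated false-alarm rate under a
  stable regime is ≈ 0 and a +50% upward-drift regime is flagged
  essentially always (both measured at 200 simulations of paired
  7,000-record cycles).

## Extrapolation

Net persons transitioning per year of age = net probability × origin
category prevalence × population count at that age, from a user-supplied
single-year-of-age census table; rounded persons are reported alongside
the exact product. Signed boundary counts therefore equal the population
times the prevalence change attributable to that boundary.

## Synthetic data

The generator emulates the features of the target surveys that the
estimator actually touches, with known truth for recovery tests:

* **Regime.** Age-varying 3×3 transition matrices with dominant diagonals
  and direct normal↔obese jumps capped at 1% per year. The `early_peak`
  preset reproduces the qualitative life-course pattern: overweight→obese
  nets peak at age two (~12%) and decline; normal→overweight nets peak in
  the mid-20s (~5.5%); downward transitions become favored in the 50s–60s.
  Initial age-2 distribution (0.70, 0.15, 0.15).
* **Design.** 14 strata × 2 PSUs, mean-zero PSU logit effects (scale
  0.05), lognormal weight variation (stratum-level σ = 0.3, individual
  σ = 0.5) independent of weight category — so weighted estimates stay
  unbiased — and 7,000 records per cycle by default, giving a pooled
  three-cycle sample of the same order as the motivating studies.
* **Anthropometry.** Adults get BMI uniform within their category's range;
  children get a percentile within their category's band, inverted through
  a bundled *synthetic* LMS growth reference (toy table with the
  qualitative shape of a real BMI-for-age reference), so classification
  round-trips exactly. Small category-independent rates of pregnancy
  flags, amputation flags and missing anthropometry exercise the
  exclusion stage.

What the generator does **not** emulate: continuous BMI dynamics
(tracking, growth spurts), informative nonresponse, within-person
measurement error, and real growth-reference curvature. Passing recovery
tests therefore demonstrates correctness of the estimation machinery under
the model's own assumptions, not robustness to their violation in field
data.

## Problem sizes for the computational checks

Truth recovery runs one stratum of 50,000 records through the full
classification path (mean absolute error vs truth ≈ 0.2 percentage
points). Interval calibration uses 200 replicate datasets of 20,000
classified records with 400 bootstrap draws each; the stability operating
characteristics use 200 paired 7,000-record cycles with 200-draw SEs.
These sizes give Monte-Carlo error comfortably below the decision margins
they feed.

## Known limitations

* Design-based variance is PSU-cluster-robust only; full linearization
  against pseudo-strata, BRR or jackknife replication is out of scope.
* The stationarity assumption is testable only jointly with the smoothing
  model; the stability check inherits the spline's bias at sharp features.
* Net transitions say nothing about gross flows; equal-and-opposite churn
  is invisible by construction.
* The closed-form oracle is specific to K = 3; `solve_transport` accepts
  general K with banded convex costs as a documented extension.
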