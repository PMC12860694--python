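# Methods

## Design and estimand

The package analyses a quasi-experimental repeated cross-sectional design:
two survey waves (t0 before, t1 after a cannabis-legalisation reform) in an
intervention country and a control country where policy did not change. The
difference-in-differences (DiD) estimand is the time-by-country interaction
in a logistic model,

    logit P(y=1) = b0 + b1*time + b2*country + b3*(time x country) + g'x,

so exp(b3) is the ratio of the intervention country's odds trend to the
control country's. Identification rests on the parallel-trends assumption
on the log-odds scale; the package does not test that assumption (it would
need external pre-period data) but supports negative-control outcomes, for
which the same machinery should produce a null interaction.

Two outcomes use this model: past-year cannabis use in the full sample
(weighted, the population question) and past-year DUIC — driving a motor
vehicle within two hours of cannabis use — among at-least-monthly users
without a medical prescription (unweighted, the behavioural question;
population weights are not designed for user subgroups). Covariates enter
as treatment-coded dummies with the reference levels t0, control country,
male, no licence, ages 18–24, low education. Candidate covariates are
screened by Pearson chi-square against the outcome in the pooled baseline
wave and retained at p < 0.10.

## Estimation and inference

`LogisticIRLS` maximises the (case-weighted) Bernoulli likelihood by
Newton–Raphson with step-halving (the step is shortened until the
likelihood does not decrease, so transient overshoot is never mistaken for
separation). Numerical contract:

- convergence: largest coefficient update < 1e-10, at most 50 iterations;
- separation: any |coefficient| > 15 after a damped step raises an error;
- aliasing: rank deficiency detected by pivoted QR of the weighted design,
  reported with the offending column names;
- covariance: inverse of the final observed information (Wald).

Wald 95% intervals and two-sided p-values are used throughout because the
published tables report OR-with-CI and they are deterministic; profile
likelihood is not implemented. Post-stratification weights are treated as
frequency-style case weights in the likelihood. This is a documented
simplification: the resulting intervals are model-based, not
survey-linearised (no Taylor/replicate-weight variance). With weights
renormalised to mean one per country-wave the effective n equals the sample
size, so the approximation is mild at this design's weight range but it is
an approximation.

Goodness-of-fit diagnostics: Nagelkerke R² (Cox–Snell rescaled by its
maximum; the weighted n is the weight sum) and generalised variance
inflation factors computed as Fox–Monette determinant ratios on the
correlation matrix of the non-intercept design columns, grouped by model
term. The interaction term's GVIF necessarily exceeds 1 — interactions are
correlated with their main effects — and is reported, not flagged as a
defect.

## Post-stratification and design-corrected tests

Weights are computed independently per (country, wave) and renormalised to
mean 1 there, so weighted totals equal sample sizes. Two modes:

- **cell**: weight = target share / sample share on the joint
  age x gender x education x region grid; exact calibration, but raises a
  degenerate-cell error (recommending raking) when a positive-share cell is
  empty in the sample — common with fine grids;
- **raking**: iterative proportional fitting over the four one-way margins,
  tolerance 1e-8 on the largest margin residual, at most 100 sweeps.

Diagnostics are the Kish quantities ESS = (Σw)²/Σw² and design effect
n·Σw²/(Σw)². Chi-square tests on weighted contingency tables use a
first-order Rao–Scott correction: the Pearson statistic on the weighted
table rescaled to the actual n, divided by the Kish design effect, referred
to χ² with (r−1)(c−1) df. The full linearised (second-order) correction is
out of scope; first-order is the standard choice for post-stratified quota
samples and is exactly testable (unit weights reduce it to Pearson).

## Power and minimum detectable effect

Power for the interaction test is estimated by Monte Carlo: outcomes are
binomial per arm, with the effect placed entirely on the intervention-t1
arm on the logit scale, logit(p11) = logit(p10) + [logit(p01) − logit(p00)]
+ log(OR). For the saturated model the IRLS fit has a closed form in the
2x2x2 counts — the interaction estimate is the empirical log ratio of odds
ratios and its Wald SE is sqrt of the summed reciprocal success/failure
cells — which a dedicated test verifies against the IRLS path and which
makes thousands of simulated datasets per evaluation cheap. Datasets with
an empty cell cannot be fitted and count conservatively as non-rejections.

The minimum detectable effect bisects the log odds ratio until the bracket
is narrower than 0.01 (each midpoint re-estimated with `nsim` datasets),
and reports alongside it the analytic Wald approximation
MDE = exp[(z_{1−α/2} + z_{power}) · SE] with SE² = Σ_arms 1/(n·p·(1−p)) at
the null-anchored prevalences. At the two study designs bundled as
`sample1_power_design()` (arms 6670/9692/2132/2102, anchors 12.1/9.4/9.6%)
and `sample2_power_design()` (393/589/86/92, 28.5/12.8/16.3%) the analytic
values are 1.38 and 3.54; simulation sits slightly above the second because
the estimated small-sample SE is noisier in arms of under a hundred users.

## Episode burden

Categorical 30-day DUIC episode counts are midpoint-coded: once → 1,
2–3 → 2.5, 4–9 → 6.5, 10–15 → 12.5, and an exact entered value above 15.
The midpoints 6.5 and 12.5 follow the same interval-midpoint rule as the
stated 2–3 → 2.5 case. Each respondent's count is split proportionally
between DUIC(−) (cannabis only) and DUIC(+) (cannabis plus alcohol or other
drugs) by their verbal co-use category; the primary scheme assigns
100/75/25/0 percent to DUIC(−) for cannabis-only/occasionally/mostly/
always, and alternative schemes are supported for sensitivity analysis.
Fractional episodes are retained — the allocation is proportional, not a
per-episode assignment. Group shares divide each frequency group's episode
sum by the overall sum, separately for DUIC(−) and DUIC(+); population
shares use all past-year users excluding medical-only-with-prescription as
the denominator, not only DUIC reporters. Percentile 95% CIs come from a
nonparametric bootstrap (default B = 2000) resampling respondents with
replacement, pooled across countries by default with within-country
stratification available; the user table is resampled independently for the
population-share intervals. Resamples with a zero episode denominator are
skipped and counted, with a warning above 1%.

## The synthetic generator

The generator's defaults are the study conditions the pipeline emulates:
cell sizes 6670/9692 (intervention t0/t1) and 2132/2102 (control), use
prevalence anchors 12.1/9.4/9.6% with an injected DiD odds ratio of 1.194
(the value implied by a 14.4% intervention-t1 prevalence), use frequency
(41.3/20.3/18.4/20.0% for less-than-monthly/monthly/weekly/daily among
users), and a DUIC process whose baseline per-frequency rates
(4/9/13/17%) and country/time/DiD odds multipliers (2.72/1.33/0.69)
reproduce user-level DUIC prevalences near 28.5/26.8% (intervention) and
12.8/16.3% (control). Quantities the study does not publish were fixed once
at realistic values: the co-use distribution (55/27/12/6%, implying an
expected DUIC(−) fraction of 0.78), the episode-category distribution
(30/32/23/8/7%) with a truncated-geometric tail above 15 of mean 25
(sample maxima around 60), P(30-day DUIC | 12-month DUIC) = 0.45, a 20%
medical-only-prescription share among users, and artifact rates of
2/1/1/0.5% for speeders/straightliners/control failures/duplicates.

Item routing mirrors the waves' filtering rules: at t0 only at-least-
monthly users receive the DUIC module, at t1 all past-year users; co-use
and episode counts exist at t1 only. Covariates are drawn independently
from their margins (only marginal quotas are published), and shift outcome
odds through configurable log-odds effects. Because the odds ratio is
non-collapsible, naively adding covariate effects would shift marginal cell
prevalences away from their targets; the generator therefore recalibrates
each design cell's intercept by root-finding so the realized mean outcome
probability equals the target exactly, keeping the marginal saturated-model
interaction equal to the injected log odds ratio. Unflagged records are
kept above the quality cutoffs, so preprocessing removes exactly the
planted truth ledger — by construction, which is what makes the filter
round-trip exactly testable.

What the generator does **not** emulate: panel recruitment and incentive
effects, attrition, joint quota grids, item nonresponse beyond the routing
pattern, recall error, or socially desirable underreporting as a response
process (the NQ− score shifts true DUIC odds rather than reported ones).
Passing tests therefore demonstrate the estimators' statistical properties
under the assumed data-generating process, not robustness to those
real-world features.

## Problem sizes in the test suite

The statistical guarantees are exercised at sizes chosen to keep Monte
Carlo error well inside the asserted tolerances while the whole suite stays
desk-scale: 500 generated surveys at the full design for the type-I-error
(0.05 ± 0.02) and log-OR recovery (|bias| < 2 MC SE) checks, 3000 simulated
datasets per bisection step for the two MDE benchmarks (±0.05 and ±0.25),
200 replicates of B = 2000 bootstraps for CI coverage (95 ± 3 points), and
100 random tables or fixtures for the exact-equivalence and conservation
properties (1e-8 and 1e-6).

## Known limitations

- Weighted-fit intervals are model-based (case-weight likelihood), not
  design-based; no BRR/jackknife replicate weights.
- No multiple-imputation machinery; the t0 less-than-monthly DUIC
  imputation is a single deterministic (largest-remainder) or Bernoulli
  fill-in from the t1 rate and should be read as a sensitivity analysis.
- Power analysis covers the saturated model only, not covariate-adjusted
  designs.
- Cell weighting fails on grids fine enough to leave empty cells; raking
  calibrates one-way margins only.
- The ratio-of-odds-ratios Wald test is slightly conservative-to-liberal in
  very small arms (empty-cell datasets are dropped as non-rejections),
  which nudges the simulated MDE above the analytic approximation at the
  user-level design.
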