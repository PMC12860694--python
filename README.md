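# duicdid

Difference-in-differences (DiD) evaluation of cannabis legalisation effects
on cannabis use and on driving under the influence of cannabis (DUIC), for
epidemiologists and policy analysts working with repeated cross-sectional
survey data.

The package implements the complete analysis chain for a two-country,
two-wave quasi-experiment — an intervention country that legalised cannabis
between waves and a control country that did not — driven by a seeded
synthetic survey-microdata generator, so every stage is testable without
access to restricted respondent-level data.

## The model

Let $y_{i} \in \{0,1\}$ be a binary outcome (past-year cannabis use in the
general population, or past-year DUIC among at-least-monthly users),
$t_i \in \{0,1\}$ the survey wave and $g_i \in \{0,1\}$ the country
(1 = intervention). The DiD model is the logistic regression

$$\operatorname{logit} P(y_i = 1) = \beta_0 + \beta_1 t_i + \beta_2 g_i
  + \beta_3 (t_i \times g_i) + \gamma' x_i,$$

fitted by iteratively reweighted least squares (IRLS), optionally with
post-stratification weights entering the Bernoulli likelihood as case
weights. $e^{\beta_3}$ is the DiD odds ratio: under parallel trends on the
log-odds scale, it isolates the change attributable to legalisation from
the secular trend shared with the control country. Wald 95% intervals and
two-sided p-values are reported, alongside Nagelkerke $R^2$, the model
likelihood-ratio $\chi^2$, and generalised variance inflation factors.

Around this core the package provides:

- **synthetic microdata** (`generate_survey` / `inject_artifacts`): quota
  covariates, past-year use with a configurable injected DiD odds ratio,
  use frequency, the DUIC item routing of each wave, co-use and 30-day
  episode counts, and planted response-quality failures with a truth ledger;
- **preprocessing** (`apply_quality_filters`, `derive_samples`): ordered
  duplicate/speeder/straightliner/control-check exclusions and the three
  analytic samples (all respondents; at-least-monthly non-medical users;
  past-30-day DUIC reporters with complete episode items);
- **weighting** (`poststratify`, `rao_scott_chisq`): cell weighting or
  raking to population margins over age x gender x education x region, with
  Kish diagnostics and first-order Rao-Scott corrected chi-square tests;
- **power** (`minimum_detectable_effect`): Monte-Carlo power and the
  minimum detectable DiD effect, with a closed-form Wald cross-check;
- **episode burden** (`burden_decomposition`, `bootstrap_burden`): the
  DUIC(−)/DUIC(+) allocation — splitting each respondent's midpoint-coded
  episode count by their co-use category (100/75/25/0% cannabis-only for
  cannabis-only/occasionally/mostly/always) — decomposed by use frequency
  with percentile bootstrap intervals.

## Worked example

```python
from duicdid import (GeneratorConfig, generate_survey, inject_artifacts,
                     apply_quality_filters, recode_covariates, derive_samples,
                     margins_from_config, poststratify, ModelSpec, did_effect,
                     sample1_power_design, minimum_detectable_effect,
                     past_year_users, bootstrap_burden, PRIMARY_SCHEME)

cfg = GeneratorConfig(seed=42)          # study-condition defaults
table, truth = inject_artifacts(generate_survey(cfg), cfg)
clean, log = apply_quality_filters(table)
clean = recode_covariates(clean, seed=42)
s1, s2, s3 = derive_samples(clean)

design = poststratify(clean, margins_from_config(cfg), mode="raking")
res = did_effect(design.rows, ModelSpec("cannabis_12m", weighted=True))
mde = minimum_detectable_effect(sample1_power_design(seed=42, nsim=2000))
bt = bootstrap_burden(s3.rows, PRIMARY_SCHEME, B=2000, seed=42,
                      users=past_year_users(clean))
```

which prints (seed 42):

```
clean n = 19571, sample2 n = 1170, sample3 n = 118
H1 weighted DiD: OR = 1.25 (95% CI 0.99-1.57), p = 0.056, Nagelkerke R2 = 0.006
minimum detectable DiD effect: OR = 1.38 (analytic approximation 1.38)
528 DUIC episodes from 118 respondents; DUIC(+) share = 20.8% (95% CI 13.6-28.5)
                   pop_share_pct  minus_share_pct  plus_share_pct
less_than_monthly           41.5             35.2            31.2
monthly                     19.4             12.4            10.5
weekly                      19.7             19.6            15.2
daily                       19.4             32.8            43.1
```

Reading the output: after quality exclusions, the weighted DiD odds ratio
of 1.25 says the odds of past-year use grew 25% faster in the intervention
country than in the control — here a draw from a generator whose injected
effect is OR 1.19, and not significant at this design's power (the smallest
effect detectable with 80% power is OR 1.38). Of the 528 thirty-day DUIC
episodes reported by sample 3, 20.8% involved alcohol or other drugs in
addition to cannabis; daily users account for the largest DUIC(+) share in
this draw while making up a fifth of the user population.

A command-line interface runs the same chain end to end:

```sh
duicdid all -c run.yaml          # or: duicdid generate / preprocess / ...
duicdid make-fixture paper-scale --seed 1 --outdir fixtures
```

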