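# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the design decisions behind `efhs-surveys`.
It states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Protocol model

The analysed protocol deploys 22 surveys per participant over one year:
nine at baseline (sociodemographic, smoking, medications/risk factors,
CVD history, non-CVD history, physical activity, alcohol, health, CES-D),
the physical-activity survey at every quarterly wave, medical-history
update / CES-D / health at 6 and 12 months, and medications–risk-factors /
smoking / alcohol again at 12 months. Returns are anchored to registration
by whole elapsed days (floored seconds/86 400) and assigned to inclusive
day-index windows 0–89, 90–179, 180–269, 270–359, 360–449. Day boundaries
are integer day indices, deliberately avoiding calendar-month and timezone
arithmetic; returns after day 449 stay in the raw tables but are excluded
from wave analyses.

Eligibility applies two exclusions in a fixed, idempotent order:
(1) follow-up shorter than `min_followup_days` (default 365); (2) among
participants who returned anything, a first return on day ≥ 90 (no baseline
anchor). "On day ≥ 90" rather than "> 90" keeps the rule the exact
complement of the baseline window. Non-returners survive both rules and
count in adherence denominators.

## Adherence and timing

A survey instance is complete when answered items / instrument items ≥ 0.75
(threshold configurable; the item total comes from the instrument
definition, not from the response rows present). Per wave, `p_any` counts
eligible participants with at least one completed instance and `p_all`
those completing every scheduled survey type; both share the single
post-exclusion denominator. When a participant returns the same survey type
twice in one wave, completion counts if *any* instance passes, and scoring
uses the earliest return — the most favourable reading of "completed at
least one survey".

Timing metrics per survey type × wave: return time (deployment → return,
days), touch time (start → return, minutes), step time (successive step
timestamps, seconds) and per-question time (step time rescaled by questions
per step). Summaries are median and IQR with type-7 (linear-interpolation)
quantiles throughout the package; IQR endpoints depend on the quantile
convention, so it is fixed and stated. Instances violating
deployment ≤ start ≤ return are dropped from timing with a log entry.

Percentages intended for tables are rounded half-up to 2 decimals
(`56.935 → 56.94`); raw proportions are always emitted alongside. All
scores are carried at full floating precision and rounded only at report
time.

## Scoring rules

* **PAI** — weighted hour sum, weights 1 (sleep), 1.1 (sedentary),
  1.5 (slight), 2.4 (moderate), 5 (heavy); range 24–120 since hours sum to
  24. Exactly one missing hour is imputed as `max(0, 24 − Σ others)` and
  flagged; two or more missing yield a missing score. If the four present
  hours exceed 24 beyond 10⁻⁶ the imputation would be negative — a data
  error (hours are physical quantities), logged and left missing.
* **CES-D** — 20 items in 0–3; items at 0-based positions {3, 7, 11, 15}
  (the instrument's standard reverse-scored items) are mapped v → 3 − v
  before summing. The reverse set is configurable and may be emptied if the
  collection software already stores reversed values. 1–5 missing items:
  mean of answered × 20; > 5 missing: missing. Binary depressive-symptoms
  flag = score ≥ 16, derived from the continuous score (including rescaled
  ones).
* **Drinks/week** — drinks per drinking day × drinking days per week;
  0 days gives 0 regardless of the drinks item; days outside 0–7 is a data
  error.

## Agreement

Clinic measurements are the gold standard `x`; baseline app scores are `y`;
pairing is complete-case with a logged count of dropped pairs.

* **CCC** uses 1/n (biased) moment estimators, Lin's original definition;
  the n−1 alternative differs by O(1/n) and is immaterial at the sample
  sizes involved. The confidence interval transforms ẑ = atanh(ĉ) with the
  corrected asymptotic variance
  `SE_z² = (1/(n−2))·[(1−r²)ĉ²/((1−ĉ²)r²) + 2ĉ³(1−ĉ)u²/(r(1−ĉ²)²) −
  ĉ⁴u⁴/(2r²(1−ĉ²)²)]`, where r is the Pearson correlation and
  u = (x̄−ȳ)/√(sₓs_y), then back-transforms. Empirical coverage of this
  interval is verified by simulation in the test suite (500 replicates at
  n = 200, coverage required in [0.90, 0.99]).
* **κ** is unweighted (the depression flag is binary, so weighting is
  moot), with the standard asymptotic SE √(p_o(1−p_o)/(n(1−p_e)²)). Both
  raters constant and identical makes p_e = 1; κ is then reported as
  degenerate/missing rather than raised.
* **Bland–Altman** reports bias = mean(y − x), sd of differences with the
  n−1 denominator, limits bias ± 1.96·sd, and the per-pair (mean, diff)
  scatter for plotting. The pipeline emits plotted quantities, not styled
  figures.

## Cohort comparisons

Continuous variables use the pooled-variance Student t test (Welch is
available via `scipy` directly but the pooled test is the package default);
categorical variables use the Pearson chi-square on the full contingency
table without continuity correction. Summaries follow table conventions:
mean (SD), median (IQR), or n (%) with per-variable non-missing
denominators.

The returner model is a complete-case maximum-likelihood logistic
regression of returning any survey on age, sex, current smoking, and
education, with Wald 95% CIs on the odds-ratio scale. Education enters as
indicator terms against the lowest category; since the lowest category can
be nearly empty (and then often contains no non-returners, quasi-separating
the fit), the pipeline first merges levels with fewer than 25 participants
into the neighbouring level and uses the lowest retained level as
reference. Education is treated as categorical, not ordinal. Zero-variance
covariates are dropped with a warning; non-convergence or runaway
coefficients raise an explicit separation error.

## Longitudinal trends

Trend analysis is restricted to participants observed at every wave at
which a measure is scheduled (complete-case balanced panel), mirroring
"returned at all time points" subgroups. On a balanced panel the
random-intercept model has an exact closed form: wave effects are wave-mean
differences from baseline; σ̂² is the interaction mean square of the
two-way (participant × wave) ANOVA and τ̂² = (MS_subject − σ̂²)/k, clamped
at zero when the moment estimate is negative — identical to REML on
balanced data (cross-checked against `statsmodels` MixedLM in the tests).
A general unbalanced mixed-model solver is deliberately out of scope. Wave
effects get Wald tests with SE = √(2σ̂²/n); at panel sizes in the hundreds,
small-sample corrections are immaterial. Time is categorical (contrasts
against baseline), not a continuous slope. Alcohol, observed at baseline
and 12 months only, uses the classical paired t test; zero-variance
differences are reported as p = 1 (zero mean) or the p → 0 limit (nonzero
mean) with no division by zero.

## Synthetic cohort generator

The generator emulates the data-production process the pipeline assumes,
with one master seed driving independent named substreams (participants,
traits, returns, responses, timing, clinic), so adding a table never
perturbs existing draws and every run is byte-reproducible.

**Participants.** Default 1948 enrolled plus 1566 non-enrolled comparison
participants. Covariates (age, sex, smoking, 5-level education, marital and
employment status, BMI) are drawn from distributions matching a middle-aged
community cohort, with the non-enrolled group older, less often female,
more often smoking, and less educated — the volunteer-bias structure an
enrolled/declined comparison is meant to detect. Registrations are spread
over a calendar year; timestamps are whole seconds since epoch with all day
arithmetic downstream.

**Returns.** A two-layer model: a participant-level *ever-returner*
indicator, Bernoulli on the logit scale with centred covariate effects
(defaults: log 1.58 for female, log 0.53 for current smoking) and an
optional extra random intercept; then, conditional on ever returning,
independent wave-level Bernoullis at `wave_return_prob / ever_return_prob`,
and per-survey-type Bernoullis given a wave return. Defaults: wave
probabilities 0.89/0.58/0.52/0.41/0.40, ever-return 0.906, survey-type
probability 0.97 except 0.04 for the long medical-history update. This
yields marginal wave return rates equal to the configured probabilities
(exactly when ever ≥ max wave probability), a realistic ~9% never-returner
group for the logistic model, and a small late-first-return exclusion set.
Covariates are centred so the configured wave probability is the marginal
rate; the residual Jensen deviation is second-order. **Limitation:** wave
returns are conditionally independent given returner status, so all-wave
complete-case panels are smaller than in a real cohort, where return
behaviour is strongly autocorrelated; setting `return_intercept_sd > 0`
adds that correlation at the cost of shifting marginal rates below the
configured values.

**Traits and agreement structure.** Each enrolled participant has one
latent trait per measure: PAI hours from a Dirichlet over the five activity
classes scaled to 24 h (default concentration 14, giving a trait SD near 4
points around a mean of ~31); CES-D from a truncated normal on [0, 60]
(default mean 7, SD 5); drinks/week from a normal clipped at 0 (default
mean 3.5, SD 4). The clinic value is trait + N(0, σ_c²); app item
responses are constructed so the *scored* app value equals
trait + δ + wave effect + N(0, σ_a²):

* PAI: hours are shifted between activity classes until the weighted sum
  hits the target score — this preserves the sum-to-24 constraint the
  scorer assumes and reaches any target in [24, 120];
* CES-D: the integer target sum is spread across 20 items in 0–3 (then the
  reverse-coded items are inverted for storage, so scoring round-trips);
* alcohol: drinking days are chosen and drinks/day set so the product
  equals the target.

This makes the population concordance available in closed form,
`CCC = 2τ²/(2τ² + σ_c² + σ_a² + δ²)` (`expected_ccc`), which the tests use
as an oracle: empirical CCC from a generated cohort must match it within
0.02 at n = 5000, with τ² estimated from the clinic-side variance. Range
clipping (PAI at 24, CES-D at 0, drinks at 0) makes the additive-Gaussian
model approximate near the boundaries; the oracle tests therefore use trait
settings well inside each range, and under the realistic defaults the
empirical CCC can sit slightly above the nominal closed form. Default
agreement parameters (δ = 2.27/0.03/0.54; σ_c = σ_a = 3.2/2.4/1.5 for
PAI/CES-D/drinks) produce moderate PAI agreement and high CES-D and alcohol
agreement, the pattern reported for these instruments. Default wave effects
raise CES-D by 1.01 at 6 months and 0.84 at 12 months; PAI and alcohol are
flat.

**Items, missingness, timing.** Non-analysed instruments get generic 0–3
items. Every response is independently missing with probability 0.02
(missingness is MCAR; the CES-D rescale rule is unbiased under it, which a
real informative-missingness process would not guarantee). Start lag after
deployment and touch duration are lognormal (defaults: median 1.7 days,
log-SD 1.0; median 3 minutes, log-SD 0.6 — surveys returned within days but
touched for minutes), with the lag capped so every return lands inside its
wave window; per-step timestamps partition the touch interval.

**What passing tests do not show.** The generator's covariate effects,
missingness, and timing are simplified (no informative missingness, no
learning/fatigue effects within surveys, no notification-driven return
clustering, no seasonal effects). Tests against it validate the pipeline's
arithmetic and statistical behaviour under its stated assumptions, not the
substantive conclusions one would draw from any real cohort.

## Problem sizes

The bundled suite simulates at the scale each check needs: estimator
oracles at n = 5000, CI coverage at 500 replicates of n = 200, logistic
recovery at 200 replicates of n = 2000, variance-component recovery at 200
replicates of n = 2000 × 5 waves, panel recovery at the subgroup scale
n = 644, and pipeline runs at 200–4000 participants. `scripts/acceptance.py`
runs the full default cohort (1948 + 1566) once; the whole suite and the
script each complete in well under a minute on one CPU.
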