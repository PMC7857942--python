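# efhs-surveys

Analysis pipeline for smartphone-app **eCohort surveys**: longitudinal
studies that collect health questionnaires through a mobile app instead of
(or alongside) in-person research-center visits. The package is aimed at
epidemiologists and biostatisticians who need to quantify, for an app-based
survey protocol with a baseline deployment and quarterly follow-ups over one
year:

* **adherence** — what fraction of participants return and complete surveys
  in each protocol time window, under a 75%-of-questions completion rule;
* **agreement** — how well app-scored measures (Physical Activity Index,
  CES-D depressive symptoms, weekly alcohol consumption) agree with
  gold-standard research-center measurements;
* **participation structure** — which participant characteristics predict
  returning surveys;
* **trends** — whether repeated app measures drift across waves.

Because participant-level data from such studies are typically not
shareable, the package ships a **synthetic eCohort generator** that emulates
the full data-production process (registration timestamps, wave-level
return behaviour with covariate effects, item-level responses with
missingness, survey timing, and paired clinic measurements with a known
agreement structure), so every stage of the pipeline is testable end to end.

## The statistics at the core

**Time windows.** A returned survey is assigned to a wave by whole days
since registration: baseline 0–89, 3 months 90–179, 6 months 180–269,
9 months 270–359, 12 months 360–449; later returns are excluded from wave
analyses. Participants with under a year of follow-up, or whose first
return falls on day 90 or later (no baseline anchor), are excluded;
non-returners are kept in adherence denominators.

**Adherence.** A survey is *complete* when at least 75% of its questions
are answered. Per wave, `p_any` is the proportion of eligible participants
with ≥ 1 completed survey and `p_all` the proportion completing every
scheduled survey type, both over the fixed post-exclusion denominator.

**Scoring.** PAI = Σ wᵢhᵢ with weights 1/1.1/1.5/2.4/5 over daily hours of
sleep/sedentary/slight/moderate/heavy activity (hours sum to 24; a single
missing entry is imputed as 24 − Σ others). CES-D = sum of 20 items scored
0–3 (four reverse-coded); with 1–5 items missing the mean of answered items
× 20, with > 5 missing the score is missing; the depression flag is
CES-D ≥ 16. Drinks/week = drinks per drinking day × drinking days per week.

**Agreement.** Lin's concordance correlation coefficient

```
CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)
```

with 1/n moment estimators and a Fisher-z confidence interval using the
corrected asymptotic variance; Cohen's unweighted κ with the asymptotic
Wald interval for the binary depression flag; Bland–Altman bias and
95% limits of agreement `bias ± 1.96·sd(diff)` with clinic as gold standard.

**Trends.** For measures observed at all waves by a complete-case subgroup,
a random-intercept model `y_it = μ + β_wave + b_i + e_it` fitted by the
balanced-panel closed form (wave effects = wave-mean differences from
baseline; variance components from the within/between mean squares,
identical to REML on balanced data). Alcohol, observed twice, uses a paired
t test.

## Worked example

```python
from efhs.pipeline import RunConfig, run_pipeline
from efhs.synthetic import CohortConfig

cfg = RunConfig(out_dir="demo_run", cohort=CohortConfig(seed=0))
bundle = run_pipeline(cfg)
print(bundle.tables["adherence"][["wave", "n_any", "n_all", "denominator",
                                  "pct_any", "pct_all"]].to_string(index=False))
```

```
    wave  n_any  n_all  denominator  pct_any  pct_all
baseline   1720   1239         1911    90.01    64.84
      m3   1077   1077         1911    56.36    56.36
      m6    978     44         1911    51.18     2.30
      m9    768    768         1911    40.19    40.19
     m12    745     26         1911    38.98     1.36
```

Of 1948 enrolled synthetic participants, 1911 remain after exclusions
(the denominator for every wave). Adherence is highest at baseline (90%)
and declines to ~39% by 12 months; `pct_all` collapses at 6 and 12 months
because the long medical-history update survey is rarely returned, while at
3 and 9 months a single scheduled survey makes both metrics coincide.

```python
print(bundle.tables["agreement"].head(4).to_string(index=False))
```

```
measure statistic  estimate   ci_low  ci_high  n_pairs
    pai       ccc  0.542659 0.511071 0.572783     1669
    pai      bias  2.277802      NaN      NaN     1669
    pai loa_lower -6.323238      NaN      NaN     1669
    pai loa_upper 10.878841      NaN      NaN     1669
```

App-based PAI agrees moderately with the clinic measurement (CCC 0.54,
95% CI 0.51–0.57 on 1669 complete pairs) and reads about 2.3 points higher
on average — exactly the agreement structure the generator was configured
with (bias δ = 2.27, moderate noise). The same run yields high agreement
for CES-D (CCC 0.75) and drinks/week (CCC 0.83), κ = 0.52 for the binary
depression flag, and a returner model with aOR 1.57 (95% CI 1.16–2.12) for
female sex and 0.48 (0.28–0.83) for current smoking — recovering the
generating log-odds of log(1.58) and log(0.53).

The same pipeline runs from the command line:

```bash
efhs-pipeline run --out demo_run --seed 0          # full pipeline
efhs-pipeline simulate --out cohort_dir --seed 0   # tables only
efhs-pipeline validate --in cohort_dir             # schema/consistency checks
```

Stage-level subcommands (`adherence`, `agree`, `compare`, `trend`) operate
on previously written CSV tables. Exit code 2 signals validation failure.

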