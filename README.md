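# mesodose

Incidental soil ingestion is a poorly characterised exposure pathway for
agricultural workers, who spend long outdoor hours in direct contact with
soil. `mesodose` estimates average daily doses (ADDs) of a hypothetical
soil contaminant for fruit and vegetable growers from season-specific
*meso-activity* questionnaire data — how many days and hours a grower
spends on site, and on each of six tasks (bed preparation, planting seeds,
transplanting, irrigation, weeding, harvesting) — for exposure scientists
and risk assessors who want task-resolved alternatives to a flat daily
ingestion-rate default.

## The model

All three dose methods evaluate the standard intake equation

```
ADD = (C · IR · EF · ED) / (BW · AT)        [mg / kgBW / day]
```

with contaminant concentration C (400 mg/kg by default), body weight BW,
exposure duration ED = 1 month, and:

1. **Daily rates** — IR = 378 mg/day (high-contact 95th-percentile
   soil + dust estimate) on days worked; EF = (days/week) × 4.35
   days/month; AT = 30.5 days.
2. **Hourly rates** — outdoor work hours at IR = 362/8 = 45.25 mg/h, the
   complementary indoor hours (730.8 − outdoor) at 22/16 = 1.375 mg/h;
   AT = 730.8 h; hourly doses × 24 to express per day.
3. **Hourly task-specific rates** — each task's hours/month at the
   baseline 45.25 mg/h scaled by its mean soil-contact fraction
   (≥ 60 % contact → ×2 = 90.5 mg/h; 40–60 % → ×1; < 40 % → ×0.5 =
   22.625 mg/h, printed 22.63); remaining hours are indoors at 1.375 mg/h.

Each method also has a Monte Carlo variant: body weights drawn from a
population-weighted empirical table, exposure factors bootstrapped from
per-season questionnaire pools, and task rates perturbed by a
Uniform(scale ± 0.2) multiplier. A synthetic cohort generator
(`mesodose.synthetic_data`) reproduces the study conditions so the whole
pipeline runs with no external data.

## Worked example

```python
from mesodose import (CohortSpec, build_rate_set, cohort_contact_means,
                      estimate_cohort, generate_bodyweight_table, generate_cohort)

cohort = generate_cohort(CohortSpec(n_growers=500, seed=2024))
means = cohort_contact_means(cohort)
rates = build_rate_set(contact_means=means)
print({a.value: round(r, 3) for a, r in rates.task_rates.items()})

table = generate_bodyweight_table("median_lookup")
doses = estimate_cohort(cohort, table, method=3, rate_set=rates)
import numpy as np
print(round(float(np.mean([d.add_total for d in doses])), 6))
```

prints

```
{'bed_preparation': 45.25, 'planting_seeds': 45.25, 'transplanting': 90.5,
 'irrigation': 22.625, 'weeding': 90.5, 'harvesting': 22.625}
0.000948
```

i.e. the cohort's recovered contact fractions assign the doubled
90.5 mg/h rate to transplanting and weeding, keep the 45.25 mg/h baseline
for planting seeds and bed preparation, and halve it to 22.625 mg/h for
harvesting and irrigation; the mean task-specific ADD across all
grower-seasons is ≈ 9.5 × 10⁻⁴ mg/kgBW/day.

The same pipeline is available from the shell:

```
mesodose synth --n 38 --seed 1 --out cohort/
mesodose rates --cohort cohort/
mesodose estimate --cohort cohort/ --method 3 --seed 1 --out adds.csv
mesodose simulate --cohort cohort/ --method 3 --season summer \
    --n 5000 --seed 1 --out-draws draws.csv --out-summary summary.json
```

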