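# Methods

## Dose model

All three methods are deterministic evaluations of the intake equation
`ADD = C · IR · EF · ED / (BW · AT)` for a hypothetical soil contaminant.
The mg→kg conversion of ingested soil mass (×10⁻⁶) is applied exactly
once, inside the dose formulas, never in rate derivation. Defaults, with
units:

| symbol | meaning | default |
|---|---|---|
| C | contaminant concentration in soil | 400 mg/kg |
| IR (method 1) | daily soil + dust ingestion | 378 mg/day |
| IR outdoor | hourly soil ingestion while working outdoors | 362/8 = 45.25 mg/h |
| IR indoor | hourly dust ingestion while indoors | 22/16 = 1.375 mg/h |
| ED | exposure duration | 1 month |
| AT (method 1) | averaging time | 30.5 days |
| AT (methods 2–3) | averaging time | 4.35 × 7 × 24 = 730.8 h |
| weeks/month | frequency conversion | 4.35 |

Two internal inconsistencies in these source defaults are carried
verbatim, never reconciled: the daily-model default (378 mg/day) is not
the sum of the hourly-model components (362 + 22 = 384 mg/day), and the
daily averaging time is stated as 30.5 days although 4.35 × 7 = 30.45.
One practical consequence: at a full 8-h, 7-day working month the hourly
model can slightly exceed the daily model (384 > 378), so the usual
ordering method 1 ≥ method 2 ≥ method 3 holds for cohort means at ≤ 8-h
workdays, not pointwise at the boundary.

Hourly doses are multiplied by 24 to express them per day. In method 2
the indoor exposure frequency is defined as the exact complement
730.8 − outdoor hours; outdoor hours above 730.8 are rejected rather than
clamped, because clamping would silently break the complement. In
method 3, hours not attributed to the six tasks are assumed indoors; when
reported task hours exceed 730.8 (possible under concurrent tasks) the
indoor term is clamped to zero and the result flagged
`indoor_hours_clamped`, preserving non-negativity.

Full precision is kept throughout (22.625, 1.375); the printed-style
two-decimal values (22.63, 1.38) are display rounding only, implemented
as round-half-away-from-zero (`format_rate`), which matters because
binary-float `"%.2f"` rounds 22.625 down.

## Contact-fraction scaling

The task-specific rates scale the 45.25 mg/h baseline by each task's mean
reported fraction of time with hands in soil, computed over engaged
growers only (days/month > 0) and pooled across seasons (a per-season
variant is available via the `season` argument). The band cut-points —
≥ 0.60 → ×2.0, 0.40–0.60 → ×1.0, < 0.40 → ×0.5 — are a judgment call
made configurable; the defaults reproduce the published assignment for
all six tasks (0.87, 0.72 → 2.0; 0.49, 0.41 → 1.0; 0.35, 0.08 → 0.5).
Glove use, handwashing and ergonomic position are recorded in the data
model but deliberately never modify dose: no defensible quantitative
adjustment exists for them.

## Body weight

Empirical estimates use a sex × age-bracket median lookup (a grower's own
reported weight overrides it). The shipped lookup table is **synthetic** —
plausible adult medians tiling ages [18, 100) — because the actual
handbook medians are not part of this package's inputs; users reproducing
a real cohort should substitute their own table. Simulation uses a
weighted empirical sample drawn with probability proportional to each
datum's population weight, with no kernel smoothing.

## Monte Carlo design

Each simulated grower draws a body weight, then the method's exposure
factor(s) with replacement from per-season empirical pools (an empirical
bootstrap), then — for method 3 — one rate multiplier per task from
Uniform(scale − 0.2, scale + 0.2). Zero pool values (non-engagement) are
included by default so the simulated population reflects engagement
prevalence. Per-task pools are sampled independently across tasks, which
discards within-grower correlation between tasks; `row_bootstrap=True`
samples an entire grower-season row instead. Sampling is vectorised from
a single seeded `numpy` generator with a fixed draw order (body weight,
exposure factors in activity order, then rate multipliers), so identical
config + seed reproduces draws bit-for-bit; this is the package's
reproducibility mechanism in place of per-draw substreams, which buy
nothing extra for a single-threaded vectorised run. The default
population is 5000 growers per season × method; summaries report mean,
median and the 5th/95th percentiles, all recomputable from stored draws.

## Synthetic cohort generator

The generator emulates the *summary* structure of the study cohort, not
individual responses:

* On-site time: days/week ~ Binomial(7, p) (min 1) and hours/day ~
  lognormal (σ_log = 0.35, clipped to [0.25, 23.5]), with season
  parameters chosen so mean hours/month ≈ 204.6 (summer) and 76.8
  (winter) — the published anchors — and spring/fall interpolated
  (≈ 159 and 111) to preserve the summer > spring > fall > winter rank.
* Engagement: per-activity, per-season Bernoulli; all six tasks common in
  spring/summer, rarer in winter.
* Task time: total task hours are a *coverage* fraction of on-site hours,
  split across engaged tasks by a Dirichlet draw whose base weights give
  irrigation and bed preparation the largest time shares. Coverage is
  1 − unaccounted fraction (default mean 0.35) for most grower-seasons
  and 1.02–1.45 (task time exceeding on-site time, i.e. concurrency) for
  a default 29 % — matching the published 71 % share of positive
  reliability differences. With both knobs at zero, coverage is exactly 1
  and the reliability difference is identically zero, a constructed test
  identity. Task hours are decomposed into integer days/month (binomial,
  irrigation on many more days) and hours/day = hours ÷ days, so records
  always satisfy the type bounds.
* Contact fractions: Beta(μκ, (1 − μ)κ) with κ = 12 and per-task means μ
  defaulting to the published 0.87/0.72/0.49/0.41/0.35/0.08, so a cohort
  of a few hundred growers recovers the means within ±0.03 and reproduces
  the published scaling assignment.
* Demographics: 52/48 male/female, ages uniform on 26–69, 5 % smokers,
  employment 71/8/21 % full/part/other, lognormal farm sizes in hectares.

What the generator does **not** emulate: within-grower consistency across
seasons (each season is drawn independently), real distribution shapes
(the study found no season's doses normal or lognormal; families here are
modelling conveniences), item non-response, and any correlation between
demographics and activity. Tests passing on synthetic cohorts therefore
validate the pipeline's arithmetic and contracts, not distributional
claims about real growers.

Distribution families and all anchor values are exposed on `CohortSpec`
rather than hard-coded.

## Numerical and design notes

* 4.35 × 7 × 24 equals the 730.8 literal exactly in binary floating
  point, and `h + (730.8 − h) == 730.8` held for every value exercised,
  so the complement-conservation contract is exact, not approximate.
* Quantiles use linear interpolation between closest order statistics
  (numpy default); box-plot-style summaries exclude zeros by default, per
  the reporting convention the package mirrors.
* Statistical comparisons (Kruskal-Wallis, Shapiro-Wilk, Pearson,
  Kendall's tau) delegate to `scipy.stats`; the package contributes the
  report shape and degenerate-input handling only. Identical groups and
  constant samples are reported explicitly rather than passed to routines
  that warn. No multiple-testing correction is applied.
* Annual aggregation over four seasons reports both the seasonal sum
  (labelled a cumulative annual index, not a dose rate) and the
  time-weighted mean, since a single annualisation formula is not
  canonical.
* CSV percent columns round-trip through decimal strings so a written
  cohort re-reads bit-identically; missing task rows are read as
  non-engagement, never imputed as activity.
* Problem sizes used by the default test run: synthetic cohorts of
  40–500 growers and simulations of 10³–10⁵ draws, which bound Monte
  Carlo error well below the contract tolerances (3 standard errors)
  while keeping the suite fast.

## Known limitations

* Exposure pathways other than incidental ingestion (dermal, inhalation)
  and any risk characterisation beyond dose are out of scope.
* The six-task vocabulary is fixed; real growers report time on tasks
  outside it, which the task-specific method implicitly treats as indoor
  non-exposure — a known downward bias it inherits from its design.
* The questionnaire's days/week (on-site) vs days/month (per task) duality
  is kept as reported; no reconciliation for unequal-length weeks is
  attempted.
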