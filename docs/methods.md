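# Methods

This note documents the models, conventions and design choices behind
`trajclust`, in the order the pipeline runs.

## Time convention

Day 0 is the first day of coaching. Program week *w* (1-based) covers day
indices `[7(w−1), 7w−1]`, so week 1 = days 0–6 and a 16-week program spans
days 0–111. The week after the program (days 112–118) only serves as the
fallback window for the final weight.

## Eligibility cascade (`cohort`)

Stages run in a fixed order; the first failing stage claims the user, so
exclusion reasons are mutually exclusive and the flow counts are exactly
conserved (`n_in = n_excluded + n_out` at every stage).

| stage | rule | default |
|---|---|---|
| has_weight_logs | ≥ 1 weight record | — |
| height_in_range | 125 cm ≤ height ≤ 230 cm | inclusive bounds |
| target_weight_plausible | target ≤ initial weight | off unless a target is present |
| adult_age | age present and ≥ 18 y | 18 |
| initial_weight_available | a log in the initial window | window [−14, +7] days |
| initial_bmi_overweight | initial BMI ≥ 25 kg/m² | 25 |
| final_weight_available | last log of week 16, else of week 17 | — |
| consistent_weights | no BMI jump ≥ 3.5 kg/m² within 30 d or ≥ 7.0 within 60 d between consecutive logs | months read as 30/60 days |
| minimal_adherence | ≥ 1 meal log in every program week | configurable, on |

The *initial* weight is the earliest log in the initial window — not a
self-reported signup weight. The lower bound of −14 days is a choice: the
defining rule ("before coaching through one week after") has no natural
lower bound, and two weeks of pre-coaching records is a conservative
reading; the window is a config field. Likewise "adult" = 18 years (US
convention) and the month-based consistency rule is fixed at 30/60
calendar days so it is exactly testable.

## Preprocessing (`preprocess`)

`regularize → moving_average → z_normalize`, with duplicates on the same
day averaged first.

* **Grid length 30.** The centered moving average of width 15 in valid
  mode outputs `L − 14` points; 30 is the unique pre-smoothing length that
  yields exactly 16. This is the single most consequential inferred
  parameter in the package and is configurable. Short series (< 30
  observations) are linearly interpolated up to the grid; long series are
  resampled by evaluating the same piecewise-linear interpolant at 30
  equally spaced times — one operation covers both regimes and handles
  irregular sampling.
* **Observation window of the output.** The 16 smoothed points summarize
  windows whose centers span grid positions 8–23 of 30, i.e. roughly
  weeks 4–12 of a full-span series; endpoints still contribute through the
  window tails. Archetype design (below) accounts for this.
* **z-normalization** uses the population SD (ddof 0), the convention of
  the shape-based time-series clustering literature. A flat series (SD
  < 1e−12) maps to all zeros with a `degenerate` provenance flag instead
  of dividing by zero.
* Exponential/Holt-Winters smoothing is deliberately not offered: recency-
  weighted smoothers are built for forecasting trends, not for symmetric
  noise suppression over a short fixed horizon.

Consequences asserted in tests: output length always 16, mean 0 and SD 1
within 1e−9; invariance to positive affine transforms of the weights
(only shape survives); smoothing never increases variance.

## DTW, DBA and k-means (`cluster`)

* **DTW.** Local cost `(x−y)²`, step set {(1,0),(0,1),(1,1)}, endpoints
  matched, no window constraint by default (an optional Sakoe-Chiba band
  exists for speed). `dtw_distance` returns the square root; inertia uses
  the squared form — the objective Lloyd iterations minimize. Both the sum
  of squared and of unsquared distances are reported on fitted models
  (`inertia`, `inertia_root`), since "total sum of distances" is read both
  ways in practice.
* **DBA.** Each member is aligned to the current barycenter along its
  optimal warping path (ties prefer the diagonal, a fixed deterministic
  rule); each barycenter coordinate becomes the mean of the member values
  aligned to it; iterate until the barycenter moves < tol (1e−6) or
  max_iter. A step that would increase the total squared-DTW cost is
  rejected, so the cost is non-increasing. DBA is a local method: from a
  symmetric initialization it can sit at a non-global fixed point, which
  is why k-means uses several seeded restarts.
* **k-means.** k-means++-style seeding under squared DTW; assignment ties
  break to the lowest cluster index; empty clusters are reseeded at the
  point farthest from its centroid; best of `n_init` restarts (default 5)
  by inertia; assignment-step inertia is recorded per iteration and is
  non-increasing. After fitting, clusters are renumbered 1..k by
  descending size so "cluster 1" is always the largest.
* **Elbow.** k is scanned over 2..10. The suggestion is the knee of the
  **log** inertia curve: both axes rescaled to [0, 1], knee = point
  farthest below the endpoint chord. The raw second-difference rule was
  tried first and discarded: with clusters at heterogeneous separations
  (here, the stable/oscillating shapes are far from the declining family
  while the declining shapes are mutually close) the inertia curve drops
  over orders of magnitude and the raw rule always elects the first
  interior k. A knee depth < 0.3 (normalized units) is flagged
  low-confidence — single-cluster data produces depths well below this,
  clusterable data well above. The full curve is always reported; the
  final k remains a human call, which is how it is settled in practice.

## Outcomes (`outcomes`)

Percent change `100·(final−initial)/initial`; classes partition the line
with boundaries belonging to the larger-loss side (−5% → loss_5_10, −2% →
loss_2_5, +2% → stable). The prose ranges these classes come from overlap
at shared endpoints, so a fixed convention is required; this one is
asserted by an exhaustive boundary sweep. Adherence rates always divide by
the 16 program weeks (a program-level rate; unlogged weeks count), while
steps divide by days that have a step record (a passive stream).

## Statistics (`stats`)

A one-sample KS test against a normal with the sample's own estimated
mean/SD routes each continuous comparison: ANOVA if p ≥ .05, otherwise
Kruskal-Wallis. (Parameter estimation makes this KS anti-conservative —
a Lilliefors correction would be stricter — but it is used only as a
router and the routing is reported with each result.) η² is always
computed from the ANOVA sum-of-squares decomposition so effect sizes stay
comparable across routes. Categorical comparisons use Pearson chi-square
without continuity correction; Cramér V = √(χ²/(N·min(r−1, c−1))), and
2×2 tables get the signed φ. Pairwise weekly tests are pooled-variance t
tests, matching Cohen d's pooled SD. No multiple-testing correction is
applied; the guard is the dual criterion: significant ⇔ p < .05 AND
effect > small (η² 0.01, V 0.01, |d| 0.20 — the V threshold is
unconventionally low but is kept as given and is configurable).
Degenerate inputs (zero pooled SD, zero total SS) yield NaN effects
flagged non-significant rather than errors; a week with an empty group is
flagged in that week's result, not fatal.

## Synthetic cohorts (`synth`)

No generative model for this kind of data is published; every curve here
is a stand-in chosen for qualitative plausibility, and the defaults below
are the package's frozen study conditions.

**Trajectories.** Fractional weight change vs. continuous week t:

* sharp_decrease — near-linear exponential decline to −10% at week 16;
* moderate_decrease — fast drop reaching −4.5% by week 5, then plateau;
* yo_yo — decline to a −5% nadir at week 8 (configurable), then linear
  rebound to −0.5%;
* stable_increase — +2% linear gain;
* other — a ~1.6-cycle sinusoid (±2%), non-converging by design.

Shapes were chosen to remain mutually distinguishable *after* the
smoothing pipeline (whose output summarizes roughly weeks 4–12): an
earlier single-period sinusoid for "other" is monotone over that window
and collapses onto the sharp decline. Weight = baseline × (1 + curve) +
N(0, 0.5 kg) self-weighing noise; baseline weight comes from BMI ~
N(33.6, 5.9) (clipped ≥ 25.5) and height ~ N(166.4, 7.4) cm; sex is 92%
female, age ~ N(43.9, 10.9) clipped to ≥ 18 — marginals echo the kind of
cohort the pipeline targets and are fully configurable.

**Sampling.** Weekly log counts are Poisson at per-archetype weekly rates
with uniform day placement (irregular, heterogeneous-length series).
Every user weighs in on day 0 and has a final-program-week log; the
exclusion-worthy conditions are injected separately (`inject_violations`)
at configured rates — implausible height, no weight logs, no final-window
weight, and a weight spike sized to a 5 kg/m² BMI jump one week after an
existing log (margin over the 3.5 threshold so ordinary weekly trajectory
movement cannot mask it).

**Adherence.** Meal and weight-log rates share a common envelope (≈17
meals/week in week 1, peaking ≈18 at week 3, fading to ≈13.5) plus an
archetype offset times a gap profile h(w): h(1) = 0, rising to 1 at the
peak-gap week (default 4), then decaying to a floor of 0.2. Hence
archetypes are indistinguishable in week 1 and diverge most at week 4 —
the structure the weekly effect-size analysis is designed to detect. The
moderate-vs-yo-yo meal gap at its peak is ≈2.5 logs/week ≈ 0.6 Poisson
pooled SDs. Between-user heterogeneity: a mean-1 lognormal multiplier
(σ = 0.2) on each user's logging rates, a separate σ = 0.5 multiplier on
message rates (messaging habits vary far more between users than between
archetypes, which is what makes message effects negligible), and a
personal daily-step level ~ N(archetype mean, 2000). Without this
heterogeneity, per-user averaging over 16 weeks shrinks within-group
variance so much that trivial rate differences produce huge spurious
effect sizes.

**What passing tests do and do not show.** The generator reproduces the
*structure* the analysis assumes — latent shape clusters, early-peaking
adherence divergence, irregular sampling, protocol violations — not the
messiness of real lifelogs (no correlated missingness, no measurement
drift, no behavioral feedback between weight and logging, no seasonal
effects). Perfect ARI on the benchmark says the pipeline recovers planted
structure at realistic noise; it is not a claim about separability of
real cohorts.

## Problem sizes

The recovery benchmark uses n = 500 users (weight noise 0.1 kg), the
weekly-divergence analysis n = 900 across the two compared archetypes,
and the elbow scan k = 2..10 with 4 restarts per k — sizes at which every
reported quantity is stable across seeds while the whole suite runs in
about a minute.

## Known limitations

* DBA and k-means find local optima; restarts mitigate but do not
  eliminate this.
* The KS router is anti-conservative (estimated parameters); with large
  n it routes almost everything to Kruskal-Wallis.
* The elbow knee depth threshold (0.3) is a heuristic; the scan always
  returns the full curve for human inspection.
* The 30-point pre-smoothing grid is inferred from the 15→16 window
  arithmetic, not independently validated.
* Whether week-17 fallback weights should ever override a week-16 log on
  the boundary day is a convention (they do not, here); both windows are
  config-driven.
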