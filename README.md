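# trajclust

Weight-loss **traj**ectory **clust**ering for 16-week mobile
weight-management programs.

Mobile weight-loss apps log what users do (weigh-ins, meal records,
coach messages, steps) at irregular times. Judging success only by "lost
≥5% of initial weight" hides *how* people got there: some lose steadily,
some lose fast then plateau, some lose and regain (the "yo-yo" pattern).
`trajclust` re-implements, as a tested reusable pipeline, the analysis
that phenotypes these trajectories and relates them to in-app behavior:

1. **cohort** — screen lifelogs through an eligibility cascade (has weight
   records; height in [125, 230] cm; adult; initial BMI ≥ 25 kg/m²; final
   weight in program week 16, or week 17 as fallback; no BMI jumps ≥ 3.5
   kg/m² within a month or ≥ 7.0 within two; ≥ 1 meal log per week), with
   stage-by-stage flow accounting.
2. **preprocess** — turn each user's irregular weight series *lᵢ* (length
   *Tᵢ*) into a length-16 trajectory: linear interpolation/resampling on a
   30-point grid, centered moving average of width 15 (30 − 15 + 1 = 16),
   then z-normalization (mean 0, SD 1, population convention) so only the
   *shape* of the trajectory matters.
3. **cluster** — k-means under dynamic time warping (DTW) with
   DTW-barycenter-averaging (DBA) centroids, written from scratch:
   `dtw(x, y)² = min over warping paths Σ (xᵢ − yⱼ)²`, inertia
   `Σ dtw(x, c(x))²`, k-means++-style seeding, restart selection, and
   elbow-based selection of k over 2..10.
4. **outcomes** — percent weight change binned into six classes (gain >2%,
   stable, loss 2–5%, 5–10%, 10–15%, >15%) and per-user app-use rates.
5. **stats** — KS-routed ANOVA / Kruskal-Wallis, chi-square, and t tests,
   each paired with its effect size (η², Cramér V, φ, Cohen d); a result is
   significant only if p < .05 **and** the effect exceeds "small"
   (η² ≈ 0.01, V ≈ 0.01, |d| ≈ 0.20). Week-by-week effect-size curves show
   *when* clusters diverge in adherence.
6. **synth** — a first-class synthetic-lifelog generator with five latent
   trajectory archetypes, adherence that peaks in weeks 2–4 then diverges
   by archetype, realistic between-user heterogeneity, and injectable
   protocol violations — so the entire pipeline is testable without any
   proprietary data.

## Worked example

```sh
python examples/03_cluster_trajectories.py
```

```
k: [2, 3, 4, 5, 6, 7, 8, 9, 10]
inertia: [740.4  510.58 118.5    8.9    5.79   4.24   3.86   3.31   3.11]
suggested k = 5
fitted inertia 8.90 in 2 iterations; cluster sizes {1: 132, 2: 62, 3: 46, 4: 36, 5: 24}
adjusted Rand index vs ground truth: 1.000
```

A 300-user synthetic cohort is generated from five archetypes, screened,
standardized and clustered. The inertia (total within-cluster squared DTW
distance) collapses until k = 5 and flattens after; the knee detector
suggests 5, and the fitted partition matches the generating archetypes
exactly (ARI 1.0). Clusters are renumbered by descending size, so
"cluster 1" is always the largest.

The other examples cover simulation + screening (`01`), preprocessing
(`02`), outcome classes and effect sizes (`04`), and the published
reference association (`05`). The same pipeline is scriptable from the
shell:

```sh
trajclust run --synth 500 --seed 7 --out-dir my_run   # full pipeline
trajclust reproduce-reference-v                       # published Cramér V
```

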