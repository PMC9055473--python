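"""Outcome classes and effect-size comparisons on a clustered cohort.

Runs the whole pipeline on a synthetic cohort, then shows the weight-class
x cluster contingency table, the cross-sectional effect sizes, and the
weekly Cohen d curve that locates when adherence between the moderate and
yo-yo trajectories diverges.
"""

import numpy as np

from trajclust import apply_eligibility, kmeans_dtw
from trajclust.outcomes import (classify_weight_change, contingency_table,
                                percent_change, summarize_usage, usage_frame)
from trajclust.preprocess import preprocess_cohort
from trajclust.stats import compare_clusters_cross_sectional, weekly_effect_trajectory
from trajclust.synth import SynthConfig, generate_cohort

cohort, _ = generate_cohort(SynthConfig(n_users=400, seed=9))
included, records, _ = apply_eligibility(cohort)
matrix, _ = preprocess_cohort(included)
model = kmeans_dtw(matrix, 5, seed=9)

rec = {r.user_id: r for r in records}
classes = {
    u.user_id: classify_weight_change(
        percent_change(rec[u.user_id].initial_weight_kg, rec[u.user_id].final_weight_kg))
    for u in included
}
print(contingency_table(model.assignments, classes))

summaries = [summarize_usage(u) for u in included]
usage = usage_frame(summaries)
results, _ = compare_clusters_cross_sectional(usage, classes, model.assignments)
print("\ncross-sectional comparisons (effect > small AND p < .05 => significant):")
for r in results:
    print(f"  {r.variable:<28s} {r.test_name:<15s} p={r.p_value:.2e} "
          f"{r.effect_type}={r.effect_value:.3f} significant={r.significant}")

trajs = weekly_effect_trajectory(summaries, model.assignments)
meal = next(t for t in trajs
            if t.variable == "meal_records" and t.comparison == "t_cluster2_vs_3")
print("\nweekly Cohen d, meal records, cluster 2 vs 3:")
print(np.round(meal.effect_curve, 2))
print(f"peak |d| at week {meal.peak_week}. Clusters are numbered by size, so which")
print("archetypes sit in clusters 2 and 3 depends on the draw; the curve shows")
print("when meal-logging between those two clusters diverges most. Meal and")
print("weight adherence carry the significant cross-sectional effects;")
print("messages and steps do not.")
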