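"""Standardize one user's irregular weight logs into a length-16 trajectory.

Shows the three preprocessing steps (piecewise-linear regularization to a
30-point grid, centered moving average of width 15, z-normalization) and
the contracts the output satisfies.
"""

import numpy as np

from trajclust.preprocess import WeightSeries, preprocess_pipeline
from trajclust.synth import SynthConfig, generate_cohort

cohort, labels = generate_cohort(
    SynthConfig(n_users=1, archetype_weights=(0, 0, 1, 0, 0), seed=3)
)
user = cohort[0]
series = WeightSeries.from_lifelog(user)
print(f"user {user.user_id} ({labels[0]}): {series.days.size} raw weight logs "
      f"over days {series.days[0]:.0f}-{series.days[-1]:.0f}")

out = preprocess_pipeline(series)
print("\nstandardized trajectory (16 points):")
print(np.round(out.values, 3))
print(f"mean = {out.values.mean():.2e}, SD = {out.values.std(ddof=0):.9f}")
print(f"provenance: {out.provenance}")
print("\nThe curve dips and rebounds: the yo-yo archetype's nadir near week 8")
print("survives smoothing. Mean 0 / SD 1 means clustering sees only shape,")
print("never the user's absolute weight.")
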