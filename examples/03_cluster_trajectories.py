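"""Cluster standardized trajectories with DTW k-means and pick k by elbow.

Generates the 5-archetype benchmark cohort, scans k = 2..10, fits the
final model, and scores recovery of the known labels.
"""

import numpy as np

from trajclust import apply_eligibility, elbow_scan, kmeans_dtw
from trajclust.preprocess import preprocess_cohort
from trajclust.synth import SynthConfig, generate_cohort

cohort, labels = generate_cohort(SynthConfig(n_users=300, weight_noise_sd=0.1, seed=7))
truth = {u.user_id: lab for u, lab in zip(cohort, labels)}
included, _, _ = apply_eligibility(cohort)
matrix, _ = preprocess_cohort(included)

scan = elbow_scan(matrix, range(2, 11), seed=7)
print("k:", scan.k_values)
print("inertia:", np.round(scan.inertias, 2))
print(f"suggested k = {scan.suggested_k}"
      + (" (low confidence)" if scan.low_confidence else ""))

model = kmeans_dtw(matrix, scan.suggested_k, seed=7)
sizes = {c: int((model.labels == c).sum()) for c in range(1, model.k + 1)}
print(f"fitted inertia {model.inertia:.2f} in {model.n_iter} iterations; "
      f"cluster sizes {sizes}")

try:
    from sklearn.metrics import adjusted_rand_score

    y = [truth[u] for u in matrix.index]
    print(f"adjusted Rand index vs ground truth: {adjusted_rand_score(y, model.labels):.3f}")
    print("ARI 1.0 = the five archetypes are recovered exactly; the elbow of")
    print("the (log) inertia curve lands at the true cluster count.")
except ImportError:
    pass
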