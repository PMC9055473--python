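import numpy as np
import pytest

from trajclust import cohort as ch
from trajclust import preprocess as pp
from trajclust import synth as sy


def make_lifelog(user_id="u0", weights=(), meals=(), height=166.4, age=40.0, **kw):
    """Small hand-built lifelog; weights is a list of (day, kg)."""
    return ch.Lifelog(
        user_id=user_id,
        height_cm=height,
        age=age,
        weight_logs=[(int(d), float(kg)) for d, kg in weights],
        meal_logs=[(int(d), str(m)) for d, m in meals],
        **kw,
    ).sort_streams()


@pytest.fixture(scope="session")
def benchmark_cohort():
    """The 5-archetype recovery benchmark: n=500, weight noise 0.1 kg, seed 7."""
    cfg = sy.SynthConfig(n_users=500, weight_noise_sd=0.1, seed=7)
    cohort, labels = sy.generate_cohort(cfg)
    truth = {u.user_id: lab for u, lab in zip(cohort, labels)}
    return cohort, truth


@pytest.fixture(scope="session")
def benchmark_matrix(benchmark_cohort):
    cohort, truth = benchmark_cohort
    included, _, _ = ch.apply_eligibility(cohort)
    matrix, _ = pp.preprocess_cohort(included)
    y_true = np.array([truth[u] for u in matrix.index])
    return matrix, y_true
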