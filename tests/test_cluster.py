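import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h
from sklearn.metrics import adjusted_rand_score

from trajclust import cluster as cl
from trajclust import cohort as ch
from dtw_oracle import dtw_bruteforce

series = st_h.lists(st_h.floats(-5, 5), min_size=1, max_size=8).map(np.array)


class TestDtwDistance:
    def test_identity(self):
        x = np.array([0.3, -1.2, 4.0])
        assert cl.dtw_distance(x, x) == 0.0

    def test_enumerated_pair(self):
        # all three warping paths of ([0,0],[1,1]) cost 2 -> sqrt(2)
        assert cl.dtw_distance([0, 0], [1, 1]) == pytest.approx(np.sqrt(2))

    def test_zero_cost_alignment(self):
        assert cl.dtw_distance([0, 1], [0, 0, 1]) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ch.DomainError):
            cl.dtw_distance([], [1.0])

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = rng.normal(size=rng.integers(1, 5))
            b = rng.normal(size=rng.integers(1, 5))
            assert cl.dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b), abs=1e-12)

    @given(a=series, b=series)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_nonnegativity(self, a, b):
        d = cl.dtw_distance(a, b)
        assert d >= 0.0
        assert d == pytest.approx(cl.dtw_distance(b, a), abs=1e-12)

    @given(a=series)
    @settings(max_examples=50, deadline=None)
    def test_identity_of_indiscernibles_equal_length(self, a):
        assert cl.dtw_distance(a, a) == 0.0

    @given(data=st_h.data())
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_euclidean_equal_length(self, data):
        n = data.draw(st_h.integers(1, 8))
        a = np.array(data.draw(st_h.lists(st_h.floats(-5, 5), min_size=n, max_size=n)))
        b = np.array(data.draw(st_h.lists(st_h.floats(-5, 5), min_size=n, max_size=n)))
        assert cl.dtw_distance(a, b) <= np.linalg.norm(a - b) + 1e-12

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 16))
        c = rng.normal(size=16)
        batch = cl._batch_sq_dtw(X, c)
        for i in range(20):
            assert batch[i] == pytest.approx(cl.dtw_distance(X[i], c, squared=True), abs=1e-10)


class TestDba:
    def test_identical_series_fixed_point(self):
        x = np.array([0.0, 1.0, -1.0, 2.0])
        bar = cl.dba_barycenter(np.tile(x, (5, 1)))
        assert bar == pytest.approx(x)

    def test_length_one_arithmetic_mean(self):
        assert cl.dba_barycenter([[0.0], [2.0]]) == pytest.approx([1.0])

    def test_no_worse_than_euclidean_mean(self):
        # the converged barycenter's total squared-DTW cost never exceeds
        # that of the plain Euclidean mean of the set (its starting point)
        S = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        bar = cl.dba_barycenter(S, init=np.array([0.0, 0.5, 1.0]))
        cost = cl._batch_sq_dtw(S, bar).sum()
        assert cost <= cl._batch_sq_dtw(S, S.mean(axis=0)).sum() + 1e-12
        # and on a less symmetric set DBA strictly improves on the mean,
        # approaching the best candidate on a 0.1-value grid
        S2 = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 1.0], [0.0, 0.2, 0.9]])
        bar2 = cl.dba_barycenter(S2)
        cost2 = cl._batch_sq_dtw(S2, bar2).sum()
        mean_cost = cl._batch_sq_dtw(S2, S2.mean(axis=0)).sum()
        assert cost2 <= mean_cost + 1e-12
        grid_best = min(
            cl._batch_sq_dtw(S2, np.array(cand)).sum()
            for cand in itertools.product(np.arange(0.0, 1.01, 0.1), repeat=3)
        )
        assert cost2 <= grid_best + 0.05  # local optimum close to grid optimum

    def test_empty_set_errors(self):
        with pytest.raises(ch.DomainError):
            cl.dba_barycenter(np.empty((0, 4)))

    def test_cost_non_increasing(self):
        rng = np.random.default_rng(5)
        S = rng.normal(size=(10, 16))
        bar = S[0].copy()
        prev = cl._batch_sq_dtw(S, bar).sum()
        for _ in range(5):
            bar, _ = cl._dba_step(S, bar)
            cost = cl._batch_sq_dtw(S, bar).sum()
            assert cost <= prev + 1e-9
            prev = cost


class TestKmeans:
    def test_k1_is_global_barycenter(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 16))
        m = cl.kmeans_dtw(X, 1, seed=0, n_init=1)
        assert set(m.labels) == {1}
        assert m.k == 1

    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 16))
        m = cl.kmeans_dtw(X, 6, seed=0, n_init=3)
        assert m.inertia == pytest.approx(0.0, abs=1e-12)
        assert sorted(m.labels) == [1, 2, 3, 4, 5, 6]

    def test_n_less_than_k_errors(self):
        with pytest.raises(ch.DomainError):
            cl.kmeans_dtw(np.zeros((3, 16)), 4)

    def test_labels_ordered_by_size(self, benchmark_matrix):
        mat, _ = benchmark_matrix
        m = cl.kmeans_dtw(mat, 5, seed=7)
        sizes = [int((m.labels == c).sum()) for c in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_inertia_history_non_increasing(self, benchmark_matrix):
        mat, _ = benchmark_matrix
        m = cl.kmeans_dtw(mat, 4, seed=1, n_init=2)
        hist = np.array(m.inertia_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 16))
        a = cl.kmeans_dtw(X, 3, seed=5)
        b = cl.kmeans_dtw(X, 3, seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_three_archetype_recovery(self):
        from trajclust import preprocess as pp
        from trajclust import synth as sy

        cfg = sy.SynthConfig(n_users=150, weight_noise_sd=0.05, seed=21,
                             archetype_weights=(1 / 3, 1 / 3, 1 / 3, 0, 0))
        cohort, labels = sy.generate_cohort(cfg)
        mat, _ = pp.preprocess_cohort(cohort)
        truth = {u.user_id: l for u, l in zip(cohort, labels)}
        m = cl.kmeans_dtw(mat, 3, seed=21)
        ari = adjusted_rand_score([truth[u] for u in mat.index], m.labels)
        assert ari >= 0.95


class TestElbow:
    def test_degenerate_range_flagged(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 16))
        scan = cl.elbow_scan(X, k_range=[4], seed=0, n_init=1)
        assert scan.suggested_k == 4 and scan.low_confidence

    def test_single_archetype_low_confidence(self):
        from trajclust import preprocess as pp
        from trajclust import synth as sy

        cfg = sy.SynthConfig(n_users=120, weight_noise_sd=0.1, seed=12,
                             archetype_weights=(1, 0, 0, 0, 0))
        cohort, _ = sy.generate_cohort(cfg)
        mat, _ = pp.preprocess_cohort(cohort)
        scan = cl.elbow_scan(mat, range(2, 11), seed=12, n_init=2)
        assert scan.low_confidence

    def test_inertia_decreases_with_k(self, benchmark_matrix):
        mat, _ = benchmark_matrix
        scan = cl.elbow_scan(mat.iloc[:120], range(2, 7), seed=3, n_init=2)
        inert = np.array(scan.inertias)
        # non-increasing up to stochastic-restart tolerance
        assert np.all(np.diff(inert) <= 0.05 * inert[:-1] + 1e-9)

    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 16))
        m = cl.kmeans_dtw(X, 2, seed=0, n_init=1)
        p = tmp_path / "model.json"
        m.write_json(p)
        import json

        d = json.loads(p.read_text())
        assert d["k"] == 2 and len(d["centroids"]) == 2
        assert d["assignments"] == m.assignments
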