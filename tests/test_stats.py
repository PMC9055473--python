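import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from trajclust import cohort as ch
from trajclust import outcomes as oc
from trajclust import stats as st
from trajclust import synth as sy


class TestKsNormality:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        assert st.ks_normality(rng.normal(size=10_000)) > 0.05

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(1)
        assert st.ks_normality(rng.exponential(size=10_000)) < 1e-6

    def test_constant_sample_degenerate(self):
        assert st.ks_normality([3.0, 3.0, 3.0, 3.0]) == 0.0

    def test_tiny_sample_errors(self):
        with pytest.raises(ch.DomainError):
            st.ks_normality([1.0, 2.0])


class TestCohenD:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0]
        assert st.cohen_d(x, x) == 0.0

    def test_hand_computed(self):
        assert st.cohen_d([0, 1], [1, 2]) == pytest.approx(-np.sqrt(2))

    def test_zero_pooled_sd_flagged(self):
        assert np.isnan(st.cohen_d([1.0, 1.0], [2.0, 2.0]))

    @pytest.mark.parametrize("true_d", [0.2, 0.5, 0.8])
    def test_simulation_recovery(self, true_d):
        rng = np.random.default_rng(int(true_d * 10))
        x = rng.normal(true_d, 1.0, size=10_000)
        y = rng.normal(0.0, 1.0, size=10_000)
        assert st.cohen_d(x, y) == pytest.approx(true_d, abs=0.05)


class TestEtaSquared:
    def test_identical_groups_zero(self):
        g = [1.0, 2.0, 3.0]
        assert st.eta_squared([g, g]) == pytest.approx(0.0)

    def test_no_within_variance_is_one(self):
        assert st.eta_squared([[1, 1], [2, 2]]) == pytest.approx(1.0)

    def test_hand_ss_decomposition(self):
        # SS_total = 12, SS_between = 6 for these shifted triplets
        assert st.eta_squared([[1, 2, 3], [2, 3, 4], [3, 4, 5]]) == pytest.approx(0.5)

    def test_all_equal_flagged(self):
        assert np.isnan(st.eta_squared([[1.0, 1.0], [1.0, 1.0]]))


class TestChiSquare:
    def test_perfect_association_phi(self):
        chi2, p, phi, t = st.chi_square_with_v([[10, 0], [0, 10]])
        assert t == "phi" and phi == pytest.approx(1.0)
        chi2, p, phi, t = st.chi_square_with_v([[0, 10], [10, 0]])
        assert phi == pytest.approx(-1.0)

    def test_independent_table_zero_v(self):
        outer = np.outer([10, 20, 30], [5, 10, 15])
        chi2, p, v, t = st.chi_square_with_v(outer)
        assert t == "cramers_v" and v == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_errors(self):
        with pytest.raises(ch.DomainError):
            st.chi_square_with_v([[0, 0], [3, 4]])

    @given(data=st_h.data())
    @settings(max_examples=150, deadline=None)
    def test_first_principles_oracle(self, data):
        r = data.draw(st_h.integers(2, 6))
        c = data.draw(st_h.integers(2, 5))
        t = np.array(
            data.draw(
                st_h.lists(
                    st_h.lists(st_h.integers(1, 40), min_size=c, max_size=c),
                    min_size=r, max_size=r,
                )
            ),
            dtype=float,
        )
        chi2, p, eff, eff_type = st.chi_square_with_v(t)
        n = t.sum()
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
        chi2_oracle = float(((t - expected) ** 2 / expected).sum())
        assert chi2 == pytest.approx(chi2_oracle, rel=1e-10)
        if eff_type == "cramers_v":
            assert eff == pytest.approx(np.sqrt(chi2_oracle / (n * (min(t.shape) - 1))))
            assert 0.0 <= eff <= 1.0
        else:
            assert -1.0 <= eff <= 1.0
            assert abs(eff) == pytest.approx(np.sqrt(chi2_oracle / n))


def _usage_cohort(weights, n, seed):
    cfg = sy.SynthConfig(n_users=n, archetype_weights=weights, seed=seed)
    cohort, labels = sy.generate_cohort(cfg)
    arch_to_cluster = {a: i + 1 for i, a in enumerate(sy.ARCHETYPES)}
    assignments = {u.user_id: arch_to_cluster[l] for u, l in zip(cohort, labels)}
    summaries = [oc.summarize_usage(u) for u in cohort]
    return cohort, assignments, summaries


class TestCrossSectional:
    def test_generator_gap_detected_and_largest_for_meals(self):
        cohort, assignments, summaries = _usage_cohort((0.3, 0.25, 0.2, 0.15, 0.1), 600, 30)
        usage = oc.usage_frame(summaries)
        classes = {u.user_id: "stable" for u in cohort}
        results, medians = st.compare_clusters_cross_sectional(usage, {}, assignments)
        by_var = {r.variable: r for r in results}
        meal = by_var["meal_records_per_week"]
        assert meal.significant
        assert meal.effect_value == max(
            r.effect_value for r in results if r.effect_type == "eta_squared"
        )
        assert len(medians) == 5

    def test_permuted_labels_kill_effects(self):
        cohort, assignments, summaries = _usage_cohort((0.3, 0.25, 0.2, 0.15, 0.1), 400, 31)
        usage = oc.usage_frame(summaries)
        rng = np.random.default_rng(0)
        users = list(assignments)
        perm = rng.permutation([assignments[u] for u in users])
        shuffled = dict(zip(users, perm.tolist()))
        results, _ = st.compare_clusters_cross_sectional(usage, {}, shuffled)
        # permutation destroys the association: effects fall below the
        # small-effect threshold (allowing chance-level exceptions)
        n_sig = sum(r.significant for r in results)
        assert n_sig <= 1
        assert all(r.effect_value < 0.05 for r in results if np.isfinite(r.effect_value))


class TestWeeklyTrajectory:
    def test_null_has_no_effects(self):
        # one archetype split into two fake clusters: all |d| small
        cfg = sy.SynthConfig(n_users=600, archetype_weights=(0, 1, 0, 0, 0), seed=32)
        cohort, _ = sy.generate_cohort(cfg)
        assignments = {u.user_id: 2 + (i % 2) for i, u in enumerate(cohort)}
        summaries = [oc.summarize_usage(u) for u in cohort]
        trajs = st.weekly_effect_trajectory(summaries, assignments,
                                            compare_clusters=(2, 3), pairs=((2, 3),))
        for t in trajs:
            if t.comparison.startswith("t_"):
                assert np.nanmax(np.abs(t.effect_curve)) < 0.25

    def test_moderate_vs_yoyo_peak_week(self):
        cfg = sy.SynthConfig(n_users=1000, archetype_weights=(0, 0.5, 0.5, 0, 0), seed=33)
        cohort, labels = sy.generate_cohort(cfg)
        assignments = {u.user_id: {"moderate_decrease": 2, "yo_yo": 3}[l]
                       for u, l in zip(cohort, labels)}
        summaries = [oc.summarize_usage(u) for u in cohort]
        trajs = st.weekly_effect_trajectory(summaries, assignments,
                                            compare_clusters=(2, 3), pairs=((2, 3),))
        meal = next(t for t in trajs
                    if t.variable == "meal_records" and t.comparison == "t_cluster2_vs_3")
        assert len(meal.results) == 16
        assert abs(meal.effect_curve[0]) < 0.2  # indistinguishable week 1
        assert abs(meal.peak_week - 4) <= 1  # divergence peaks near week 4
        assert np.max(np.abs(meal.effect_curve[1:8])) > 0.35

    def test_empty_group_week_flagged_not_fatal(self):
        cfg = sy.SynthConfig(n_users=20, archetype_weights=(0.5, 0.5, 0, 0, 0), seed=34)
        cohort, labels = sy.generate_cohort(cfg)
        assignments = {u.user_id: {"sharp_decrease": 1, "moderate_decrease": 3}[l]
                       for u, l in zip(cohort, labels)}
        assignments[cohort[0].user_id] = 2  # cluster 2 has a single user
        summaries = [oc.summarize_usage(u) for u in cohort]
        trajs = st.weekly_effect_trajectory(summaries, assignments,
                                            compare_clusters=(1, 2, 3), pairs=((2, 3),))
        flagged = [r for t in trajs for r in t.results if r.note == "empty_group"]
        assert flagged and all(not r.significant for r in flagged)


class TestTypeIError:
    def test_anova_null_rejection_rate(self):
        rng = np.random.default_rng(35)
        from scipy.stats import f_oneway

        rejections = 0
        reps = 1000
        for _ in range(reps):
            g = rng.normal(size=(3, 50))
            if f_oneway(*g).pvalue < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07
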