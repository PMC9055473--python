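"""Cross-sectional and weekly group comparisons with effect sizes.

Because the cohorts this pipeline targets are large, p-values alone are
nearly useless — with tens of thousands of users almost any difference is
"significant".  Every comparison therefore carries an effect size, and a
result only counts as significant when the two-sided p-value is < .05
AND the effect exceeds the small-effect threshold for its type
(eta^2 ~ 0.01, Cramer V ~ 0.01, |Cohen d| ~ 0.20).

Test routing: a Kolmogorov-Smirnov normality check (against a normal
with the sample's own mean/SD) decides between one-way ANOVA and the
Kruskal-Wallis test for continuous variables; eta^2 is always computed
from the ANOVA sum-of-squares decomposition so effect sizes stay
comparable across the two routes.  Categorical variables use the Pearson
chi-square with Cramer V (or the signed phi coefficient for 2x2 tables).
The weekly analysis re-runs ANOVA (+ eta^2) across clusters 1-3 and
pooled two-sample t tests (+ Cohen d) for cluster pairs, for each of the
16 program weeks, producing the effect-size trajectories that show when
in the program adherence between clusters diverges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import DomainError
from .outcomes import UsageSummary

__all__ = [
    "EffectSizeResult",
    "WeeklyEffectTrajectory",
    "SMALL_EFFECT",
    "ks_normality",
    "cohen_d",
    "eta_squared",
    "chi_square_with_v",
    "compare_clusters_cross_sectional",
    "weekly_effect_trajectory",
]

ALPHA = 0.05
SMALL_EFFECT = {"eta_squared": 0.01, "cramers_v": 0.01, "phi": 0.01, "cohen_d": 0.20}


@dataclass
class EffectSizeResult:
    comparison_id: str
    variable: str
    groups: list[str]
    test_name: str  # anova | kruskal_wallis | chi_square | t_test
    statistic: float
    p_value: float
    effect_type: str  # cohen_d | eta_squared | cramers_v | phi
    effect_value: float
    significant: bool
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _is_significant(p: float, effect_type: str, effect_value: float) -> bool:
    if not np.isfinite(p) or not np.isfinite(effect_value):
        return False
    return p < ALPHA and abs(effect_value) > SMALL_EFFECT[effect_type]


def ks_normality(sample) -> float:
    """One-sample KS p-value against N(sample mean, sample SD).

    Low p rejects normality and routes the comparison to the
    nonparametric branch.  A (near-)constant sample is degenerate and
    returns 0.0 (treated as non-normal).  Parameters are estimated from
    the sample itself, which makes the test anti-conservative; it is used
    only as a router, not as a reported result.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise DomainError(f"ks_normality: need n >= 3, got {x.size}")
    sd = x.std(ddof=1)
    if sd < 1e-12:
        return 0.0
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def cohen_d(x, y) -> float:
    """Standardized mean difference (x minus y) over the pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DomainError("cohen_d: need n >= 2 per group")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var < 1e-24:
        return float("nan")  # undefined: no within-group variability
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def eta_squared(groups) -> float:
    """SS_between / SS_total from the one-way ANOVA decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise DomainError("eta_squared: need >= 2 groups with n >= 2 each")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total < 1e-24:
        return float("nan")  # undefined: all observations equal
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    return ss_between / ss_total


def chi_square_with_v(table) -> tuple[float, float, float, str]:
    """Pearson chi-square (no continuity correction) plus association size.

    Returns (chi2, p, effect, effect_type) where the effect is the signed
    phi coefficient for a 2x2 table and Cramer V otherwise.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise DomainError("chi_square_with_v: need a non-negative 2-D table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DomainError("chi_square_with_v: table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    n = t.sum()
    r, c = t.shape
    if (r, c) == (2, 2):
        a, b = t[0]
        cc, d = t[1]
        denom = np.sqrt(t.sum(axis=1).prod() * t.sum(axis=0).prod())
        phi = float((a * d - b * cc) / denom)
        return float(chi2), float(p), phi, "phi"
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return float(chi2), float(p), v, "cramers_v"


USAGE_VARIABLES = (
    "meal_records_per_week",
    "weight_records_per_week",
    "messages_sent_per_week",
    "messages_received_per_week",
    "steps_per_day",
)


def _route_continuous(groups: list[np.ndarray]) -> tuple[str, float, float]:
    """KS-routed omnibus test: ANOVA if pooled sample looks normal, else KW."""
    pooled = np.concatenate(groups)
    normal = ks_normality(pooled) >= ALPHA
    if normal:
        res = sps.f_oneway(*groups)
        return "anova", float(res.statistic), float(res.pvalue)
    res = sps.kruskal(*groups)
    return "kruskal_wallis", float(res.statistic), float(res.pvalue)


def compare_clusters_cross_sectional(
    usage: pd.DataFrame,
    classes: dict[str, str],
    assignments: dict[str, int],
    variables=USAGE_VARIABLES,
) -> tuple[list[EffectSizeResult], pd.DataFrame]:
    """Program-level comparison of app use and outcome class across clusters.

    ``usage`` is the per-user rate table (index user_id).  For each
    continuous variable the clusters are compared with a KS-routed ANOVA
    or Kruskal-Wallis test plus eta^2; the weight-class distribution is
    compared with chi-square plus Cramer V.  Also returns a per-cluster
    median (IQR) summary table.
    """
    users = [u for u in usage.index if u in assignments]
    clusters = sorted(set(assignments[u] for u in users))
    results: list[EffectSizeResult] = []
    summary_rows = []

    for var in variables:
        groups = [
            usage.loc[[u for u in users if assignments[u] == c], var].to_numpy(dtype=float)
            for c in clusters
        ]
        test_name, stat, p = _route_continuous(groups)
        eta2 = eta_squared(groups)
        results.append(
            EffectSizeResult(
                comparison_id=f"{var}_across_clusters",
                variable=var,
                groups=[f"cluster{c}" for c in clusters],
                test_name=test_name,
                statistic=stat,
                p_value=p,
                effect_type="eta_squared",
                effect_value=eta2,
                significant=_is_significant(p, "eta_squared", eta2),
            )
        )
        row = {"variable": var}
        for c, g in zip(clusters, groups):
            q1, med, q3 = np.percentile(g, [25, 50, 75]) if g.size else (np.nan,) * 3
            row[f"cluster{c}_median"] = med
            row[f"cluster{c}_iqr"] = q3 - q1
        summary_rows.append(row)

    if classes:
        from .outcomes import contingency_table

        table = contingency_table(assignments, classes)
        counts = table.drop(index="total").drop(columns="total")
        counts = counts.loc[(counts.sum(axis=1) > 0), (counts.sum(axis=0) > 0)]
        chi2, p, eff, eff_type = chi_square_with_v(counts.to_numpy())
        results.append(
            EffectSizeResult(
                comparison_id="weight_class_across_clusters",
                variable="weight_class",
                groups=[f"cluster{c}" for c in counts.columns],
                test_name="chi_square",
                statistic=chi2,
                p_value=p,
                effect_type=eff_type,
                effect_value=eff,
                significant=_is_significant(p, eff_type, eff),
            )
        )
    return results, pd.DataFrame(summary_rows)


@dataclass
class WeeklyEffectTrajectory:
    """16-point effect-size curve for one variable and one comparison."""

    variable: str
    comparison: str
    results: list[EffectSizeResult] = field(default_factory=list)

    @property
    def effect_curve(self) -> np.ndarray:
        return np.array([r.effect_value for r in self.results])

    @property
    def peak_week(self) -> int:
        curve = np.abs(np.nan_to_num(self.effect_curve, nan=-np.inf))
        return int(np.argmax(curve)) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(week=w + 1, **r.to_dict()) for w, r in enumerate(self.results)]
        return pd.DataFrame(rows)


WEEKLY_VARIABLES = ("meal_records", "weight_records", "messages_sent", "messages_received", "steps_per_day")


def weekly_effect_trajectory(
    summaries: list[UsageSummary],
    assignments: dict[str, int],
    compare_clusters: tuple[int, ...] = (1, 2, 3),
    pairs: tuple[tuple[int, int], ...] = ((1, 3), (2, 3)),
    variables=WEEKLY_VARIABLES,
    program_weeks: int = 16,
) -> list[WeeklyEffectTrajectory]:
    """Week-by-week effect-size curves across the converging clusters.

    For every program week and variable: one-way ANOVA with eta^2 across
    ``compare_clusters`` and pooled two-sample t tests with Cohen d for
    each pair in ``pairs``.  Weeks where a group is empty or degenerate
    are flagged in the result note rather than aborting the scan.
    """
    by_cluster: dict[int, list[UsageSummary]] = {}
    for s in summaries:
        c = assignments.get(s.user_id)
        if c is not None:
            by_cluster.setdefault(c, []).append(s)

    def week_values(cluster: int, var: str, week: int) -> np.ndarray:
        return np.array(
            [s.weekly[var][week - 1] for s in by_cluster.get(cluster, [])], dtype=float
        )

    trajectories: list[WeeklyEffectTrajectory] = []
    for var in variables:
        anova_traj = WeeklyEffectTrajectory(var, "anova_clusters_" + "_".join(map(str, compare_clusters)))
        for week in range(1, program_weeks + 1):
            groups = [week_values(c, var, week) for c in compare_clusters]
            base = dict(
                comparison_id=f"{var}_week{week}_anova",
                variable=var,
                groups=[f"cluster{c}" for c in compare_clusters],
                test_name="anova",
            )
            if any(g.size < 2 for g in groups):
                anova_traj.results.append(EffectSizeResult(
                    **base, statistic=float("nan"), p_value=float("nan"),
                    effect_type="eta_squared", effect_value=float("nan"),
                    significant=False, note="empty_group"))
                continue
            res = sps.f_oneway(*groups)
            eta2 = eta_squared(groups)
            anova_traj.results.append(EffectSizeResult(
                **base, statistic=float(res.statistic), p_value=float(res.pvalue),
                effect_type="eta_squared", effect_value=eta2,
                significant=_is_significant(float(res.pvalue), "eta_squared", eta2)))
        trajectories.append(anova_traj)

        for ca, cb in pairs:
            t_traj = WeeklyEffectTrajectory(var, f"t_cluster{ca}_vs_{cb}")
            for week in range(1, program_weeks + 1):
                x, y = week_values(ca, var, week), week_values(cb, var, week)
                base = dict(
                    comparison_id=f"{var}_week{week}_c{ca}v{cb}",
                    variable=var,
                    groups=[f"cluster{ca}", f"cluster{cb}"],
                    test_name="t_test",
                )
                if x.size < 2 or y.size < 2:
                    t_traj.results.append(EffectSizeResult(
                        **base, statistic=float("nan"), p_value=float("nan"),
                        effect_type="cohen_d", effect_value=float("nan"),
                        significant=False, note="empty_group"))
                    continue
                res = sps.ttest_ind(x, y, equal_var=True)  # pooled, matching d's SD
                d = cohen_d(x, y)
                t_traj.results.append(EffectSizeResult(
                    **base, statistic=float(res.statistic), p_value=float(res.pvalue),
                    effect_type="cohen_d", effect_value=d,
                    significant=_is_significant(float(res.pvalue), "cohen_d", d)))
            trajectories.append(t_traj)
    return trajectories
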