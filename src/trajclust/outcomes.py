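"""Weight-change outcomes, loss classes, and per-user app-use summaries.

The program outcome is the percent change from initial to final weight,
binned into six classes that partition the real line: gain of more than
2%, stable (within 2%), and losses of 2-5%, 5-10%, 10-15% and over 15%.
Boundaries belong to the larger-loss side (exactly -5% counts as the
5-10% loss class; exactly +2% is stable), a fixed convention chosen
because prose ranges like "2%-5%" and "5%-10%" overlap at the shared
endpoint.

App-use summaries are program-level rates: meal logs, weight logs and
messages per week (total over the 16 program weeks divided by 16, so a
week without logging drags the rate down rather than being ignored) and
steps per logged day, plus the per-week breakdown used by the weekly
effect-size analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DomainError, Lifelog, weekly_counts

__all__ = [
    "WEIGHT_CLASSES",
    "UsageSummary",
    "percent_change",
    "classify_weight_change",
    "summarize_usage",
    "usage_frame",
    "contingency_table",
]

WEIGHT_CLASSES = ("gain_gt2", "stable", "loss_2_5", "loss_5_10", "loss_10_15", "loss_gt15")


def percent_change(initial_kg: float, final_kg: float) -> float:
    """Signed percent change from initial weight (negative = loss)."""
    if initial_kg <= 0:
        raise DomainError(f"percent_change: initial weight must be > 0, got {initial_kg}")
    return 100.0 * (final_kg - initial_kg) / initial_kg


def classify_weight_change(percent: float) -> str:
    """Map a signed percent change to its weight-change class.

    The six classes tile the line with no gaps or overlaps; each boundary
    belongs to the larger-loss side.
    """
    if percent > 2.0:
        return "gain_gt2"
    if percent > -2.0:
        return "stable"
    if percent > -5.0:
        return "loss_2_5"
    if percent > -10.0:
        return "loss_5_10"
    if percent > -15.0:
        return "loss_10_15"
    return "loss_gt15"


@dataclass
class UsageSummary:
    """Program-level app-use rates for one user, with weekly breakdowns."""

    user_id: str
    meal_records_per_week: float
    weight_records_per_week: float
    messages_sent_per_week: float
    messages_received_per_week: float
    steps_per_day: float
    weekly: dict[str, list[int | float]] = field(default_factory=dict)


def summarize_usage(log: Lifelog, program_weeks: int = 16) -> UsageSummary:
    """Count self-monitoring events per program week and average them.

    Per-week rates use the full program length as denominator.  Steps are
    averaged over days that actually have a step record (a passive
    stream, logged only when the device reported).
    """
    meal_w = weekly_counts(log.meal_logs, program_weeks)
    weight_w = weekly_counts(log.weight_logs, program_weeks)
    sent_w = weekly_counts([m for m in log.messages if m[1] == "sent"], program_weeks)
    recv_w = weekly_counts([m for m in log.messages if m[1] == "received"], program_weeks)

    horizon = 7 * program_weeks
    step_vals = [count for day, count in log.steps if 0 <= day < horizon]
    steps_weekly = [0.0] * program_weeks
    steps_n = [0] * program_weeks
    for day, count in log.steps:
        if 0 <= day < horizon:
            steps_weekly[day // 7] += count
            steps_n[day // 7] += 1
    steps_per_day_weekly = [
        (s / n if n else 0.0) for s, n in zip(steps_weekly, steps_n)
    ]

    return UsageSummary(
        user_id=log.user_id,
        meal_records_per_week=sum(meal_w) / program_weeks,
        weight_records_per_week=sum(weight_w) / program_weeks,
        messages_sent_per_week=sum(sent_w) / program_weeks,
        messages_received_per_week=sum(recv_w) / program_weeks,
        steps_per_day=(float(np.mean(step_vals)) if step_vals else 0.0),
        weekly={
            "meal_records": meal_w,
            "weight_records": weight_w,
            "messages_sent": sent_w,
            "messages_received": recv_w,
            "steps_per_day": steps_per_day_weekly,
        },
    )


def usage_frame(summaries: list[UsageSummary]) -> pd.DataFrame:
    """Flat per-user table of the program-level rates (index = user_id)."""
    df = pd.DataFrame(
        {
            "user_id": [s.user_id for s in summaries],
            "meal_records_per_week": [s.meal_records_per_week for s in summaries],
            "weight_records_per_week": [s.weight_records_per_week for s in summaries],
            "messages_sent_per_week": [s.messages_sent_per_week for s in summaries],
            "messages_received_per_week": [s.messages_received_per_week for s in summaries],
            "steps_per_day": [s.steps_per_day for s in summaries],
        }
    ).set_index("user_id")
    return df


def contingency_table(
    assignments: dict[str, int], classes: dict[str, str]
) -> pd.DataFrame:
    """Weight-class x cluster count table with margins.

    Rows are weight classes (fixed order), columns cluster indices; a
    "total" row/column carries the margins.  The two inputs must cover
    exactly the same users.
    """
    if set(assignments) != set(classes):
        raise DomainError("contingency_table: assignments and classes cover different user sets")
    users = sorted(assignments)
    df = pd.DataFrame(
        {
            "cluster": [assignments[u] for u in users],
            "wclass": pd.Categorical([classes[u] for u in users], categories=WEIGHT_CLASSES),
        }
    )
    table = pd.crosstab(df["wclass"], df["cluster"], dropna=False)
    table.index = table.index.astype(str)
    table.loc["total"] = table.sum(axis=0)
    table["total"] = table.sum(axis=1)
    table.index.name = "weight_class"
    return table
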