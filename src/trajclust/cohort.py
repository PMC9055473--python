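"""Lifelog containers, eligibility screening and cohort-flow accounting.

A *lifelog* is one user's profile plus four timestamped event streams
(weight logs in kg, meal logs, coach-message send/receive events, daily
step counts), with time expressed as integer day indices relative to the
day coaching starts (day 0).  The eligibility cascade mirrors the intake
funnel of a 16-week mobile weight-management program: users must have
weight records, a plausible height, adult age, a starting BMI in the
overweight-or-above range (>= 25 kg/m^2), a final weight in the last
program week (or the week after as a fallback), internally consistent
weight records, and minimal meal-logging adherence.

Each exclusion stage records how many users enter, leave and are removed,
so the result doubles as a participant-flow diagram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Lifelog",
    "CohortFlow",
    "FlowStage",
    "EligibilityRecord",
    "EligibilityCriteria",
    "ExclusionReason",
    "compute_bmi",
    "check_height",
    "extract_initial_weight",
    "extract_final_weight",
    "detect_inconsistent_weights",
    "weekly_counts",
    "week_of_day",
    "apply_eligibility",
    "write_lifelogs_jsonl",
    "read_lifelogs_jsonl",
]

# Week convention: week w (1-based) covers day indices [7*(w-1), 7*w - 1],
# so week 1 = days 0..6 and a 16-week program spans days 0..111.
PROGRAM_WEEKS = 16
HEIGHT_MIN_CM = 125.0
HEIGHT_MAX_CM = 230.0
ADULT_AGE = 18.0
OVERWEIGHT_BMI = 25.0
# Consecutive-pair consistency rule: BMI jump >= 3.5 kg/m^2 within 30 days,
# or >= 7.0 kg/m^2 within 60 days, marks the record stream inconsistent.
BMI_JUMP_1MO = 3.5
BMI_JUMP_2MO = 7.0
DAYS_1MO = 30
DAYS_2MO = 60


class DomainError(ValueError):
    """Raised when an operation receives input outside its contract."""


def week_of_day(day_index: int) -> int:
    """1-based program week containing ``day_index`` (week 1 = days 0-6)."""
    return day_index // 7 + 1


@dataclass
class Lifelog:
    """One user's profile and event streams.

    Event streams are lists of tuples keyed by integer day index (days
    since enrollment; negative = before coaching started).  Streams are
    kept sorted by day index; :meth:`sort_streams` restores the invariant
    after in-place edits.
    """

    user_id: str
    sex: str = "unknown"  # {female, male, unknown}
    age: float | None = None
    height_cm: float | None = None
    enrollment_day: int = 0
    weight_logs: list[tuple[int, float]] = field(default_factory=list)
    meal_logs: list[tuple[int, str]] = field(default_factory=list)
    messages: list[tuple[int, str]] = field(default_factory=list)  # direction: sent|received
    steps: list[tuple[int, int]] = field(default_factory=list)
    target_weight_kg: float | None = None

    def sort_streams(self) -> "Lifelog":
        self.weight_logs.sort(key=lambda x: x[0])
        self.meal_logs.sort(key=lambda x: x[0])
        self.messages.sort(key=lambda x: x[0])
        self.steps.sort(key=lambda x: x[0])
        return self

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "Lifelog":
        d = json.loads(line)
        for key in ("weight_logs", "meal_logs", "messages", "steps"):
            d[key] = [tuple(item) for item in d.get(key, [])]
        return cls(**d)


class ExclusionReason(str, Enum):
    NO_WEIGHT_LOGS = "no_weight_logs"
    HEIGHT_OUT_OF_RANGE = "height_out_of_range"
    MISSING_HEIGHT = "missing_height"
    AGE_INELIGIBLE = "age_ineligible"
    NO_INITIAL_WEIGHT = "no_initial_weight"
    BMI_BELOW_THRESHOLD = "bmi_below_threshold"
    NO_FINAL_WEIGHT = "no_final_weight"
    INCONSISTENT_WEIGHTS = "inconsistent_weights"
    INSUFFICIENT_ADHERENCE = "insufficient_adherence"
    TARGET_ABOVE_INITIAL = "target_above_initial"


@dataclass
class FlowStage:
    stage_name: str
    n_in: int
    n_excluded: int
    n_out: int
    exclusion_reason: str

    def __post_init__(self) -> None:
        if self.n_in != self.n_excluded + self.n_out:
            raise DomainError(
                f"flow stage {self.stage_name!r}: n_in ({self.n_in}) != "
                f"n_excluded + n_out ({self.n_excluded} + {self.n_out})"
            )


@dataclass
class CohortFlow:
    """Ordered stage accounting; counts are conserved stage to stage."""

    stages: list[FlowStage] = field(default_factory=list)

    def add(self, stage_name: str, n_in: int, n_excluded: int, reason: str) -> None:
        self.stages.append(FlowStage(stage_name, n_in, n_excluded, n_in - n_excluded, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.stages])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EligibilityRecord:
    user_id: str
    initial_weight_kg: float | None = None
    initial_day: int | None = None
    final_weight_kg: float | None = None
    final_day: int | None = None
    initial_bmi: float | None = None
    included: bool = False
    exclusion_reason: str | None = None


@dataclass
class EligibilityCriteria:
    """Tunable parameters of the screening cascade.

    ``initial_window`` is the (lo, hi) day-index window, inclusive, within
    which the earliest weight log counts as the initial weight; the default
    admits records from two weeks before coaching through the first
    program week.  ``min_meal_logs_per_week`` > 0 switches on the minimal
    self-monitoring stage (at least that many meal logs in every program
    week).
    """

    program_weeks: int = PROGRAM_WEEKS
    height_min_cm: float = HEIGHT_MIN_CM
    height_max_cm: float = HEIGHT_MAX_CM
    adult_age: float = ADULT_AGE
    min_initial_bmi: float = OVERWEIGHT_BMI
    initial_window: tuple[int, int] = (-14, 7)
    min_meal_logs_per_week: int = 1
    enforce_target_weight: bool = False

    @property
    def final_week_days(self) -> tuple[int, int]:
        w = self.program_weeks
        return (7 * (w - 1), 7 * w - 1)

    @property
    def fallback_week_days(self) -> tuple[int, int]:
        w = self.program_weeks + 1
        return (7 * (w - 1), 7 * w - 1)


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index in kg/m^2."""
    if weight_kg is None or height_cm is None or weight_kg <= 0 or height_cm <= 0:
        raise DomainError(f"compute_bmi needs positive inputs, got weight={weight_kg}, height={height_cm}")
    h_m = height_cm / 100.0
    return weight_kg / (h_m * h_m)


def check_height(height_cm: float | None, criteria: EligibilityCriteria | None = None) -> tuple[bool, str | None]:
    """Plausibility screen on height. Returns (passes, reason-if-failed)."""
    c = criteria or EligibilityCriteria()
    if height_cm is None:
        return False, ExclusionReason.MISSING_HEIGHT.value
    if height_cm < c.height_min_cm or height_cm > c.height_max_cm:
        return False, ExclusionReason.HEIGHT_OUT_OF_RANGE.value
    return True, None


def extract_initial_weight(
    log: Lifelog, window: tuple[int, int] = (-14, 7)
) -> tuple[int, float] | None:
    """Earliest weight log inside the initial window (inclusive), or None.

    The initial weight is the first weight a user logged around program
    start, not the self-reported signup weight; the window defaults to
    two weeks pre-coaching through day 7.
    """
    lo, hi = window
    for day, kg in log.weight_logs:
        if lo <= day <= hi:
            return (day, kg)
        if day > hi:
            break
    return None


def extract_final_weight(
    log: Lifelog, criteria: EligibilityCriteria | None = None
) -> tuple[int, float] | None:
    """Last weight in the final program week; week-after fallback if absent.

    Under the day convention, week 16 spans days 105-111 and the fallback
    week 17 spans days 112-118.  The fallback is consulted only when the
    final week holds no record at all.
    """
    c = criteria or EligibilityCriteria()
    for lo, hi in (c.final_week_days, c.fallback_week_days):
        best = None
        for day, kg in log.weight_logs:
            if lo <= day <= hi:
                best = (day, kg)
        if best is not None:
            return best
    return None


def detect_inconsistent_weights(
    log: Lifelog, height_cm: float
) -> list[tuple[tuple[int, float], tuple[int, float]]]:
    """Flag consecutive weight-log pairs with implausible BMI jumps.

    A pair is flagged when the absolute BMI difference is >= 3.5 kg/m^2
    with the two logs at most 30 days apart, or >= 7.0 kg/m^2 at most 60
    days apart.  Any flag excludes the user.
    """
    if height_cm is None or height_cm <= 0:
        raise DomainError("detect_inconsistent_weights requires a valid height")
    flagged = []
    logs = log.weight_logs
    for (d1, w1), (d2, w2) in zip(logs, logs[1:]):
        gap = d2 - d1
        dbmi = abs(compute_bmi(w2, height_cm) - compute_bmi(w1, height_cm))
        if (gap <= DAYS_1MO and dbmi >= BMI_JUMP_1MO) or (gap <= DAYS_2MO and dbmi >= BMI_JUMP_2MO):
            flagged.append(((d1, w1), (d2, w2)))
    return flagged


def weekly_counts(events: Sequence[tuple[int, object]], program_weeks: int = PROGRAM_WEEKS) -> list[int]:
    """Count events per program week 1..program_weeks (pre/post ignored)."""
    counts = [0] * program_weeks
    for day, _ in events:
        if 0 <= day < 7 * program_weeks:
            counts[day // 7] += 1
    return counts


def _screen_user(log: Lifelog, c: EligibilityCriteria) -> EligibilityRecord:
    rec = EligibilityRecord(user_id=log.user_id)
    # Stage order follows the intake funnel; the first failing stage wins.
    if not log.weight_logs:
        rec.exclusion_reason = ExclusionReason.NO_WEIGHT_LOGS.value
        return rec
    ok, reason = check_height(log.height_cm, c)
    if not ok:
        rec.exclusion_reason = reason
        return rec
    if c.enforce_target_weight and log.target_weight_kg is not None:
        init = extract_initial_weight(log, c.initial_window)
        if init is not None and log.target_weight_kg > init[1]:
            rec.exclusion_reason = ExclusionReason.TARGET_ABOVE_INITIAL.value
            return rec
    if log.age is None or log.age < c.adult_age:
        rec.exclusion_reason = ExclusionReason.AGE_INELIGIBLE.value
        return rec
    init = extract_initial_weight(log, c.initial_window)
    if init is None:
        rec.exclusion_reason = ExclusionReason.NO_INITIAL_WEIGHT.value
        return rec
    rec.initial_day, rec.initial_weight_kg = init
    rec.initial_bmi = compute_bmi(rec.initial_weight_kg, log.height_cm)
    if rec.initial_bmi < c.min_initial_bmi:
        rec.exclusion_reason = ExclusionReason.BMI_BELOW_THRESHOLD.value
        return rec
    final = extract_final_weight(log, c)
    if final is None:
        rec.exclusion_reason = ExclusionReason.NO_FINAL_WEIGHT.value
        return rec
    rec.final_day, rec.final_weight_kg = final
    if detect_inconsistent_weights(log, log.height_cm):
        rec.exclusion_reason = ExclusionReason.INCONSISTENT_WEIGHTS.value
        return rec
    if c.min_meal_logs_per_week > 0:
        wk = weekly_counts(log.meal_logs, c.program_weeks)
        if min(wk) < c.min_meal_logs_per_week:
            rec.exclusion_reason = ExclusionReason.INSUFFICIENT_ADHERENCE.value
            return rec
    rec.included = True
    return rec


# Stage metadata in cascade order: (stage name, exclusion reasons handled there).
_STAGES: list[tuple[str, tuple[str, ...]]] = [
    ("has_weight_logs", (ExclusionReason.NO_WEIGHT_LOGS.value,)),
    ("height_in_range", (ExclusionReason.HEIGHT_OUT_OF_RANGE.value, ExclusionReason.MISSING_HEIGHT.value)),
    ("target_weight_plausible", (ExclusionReason.TARGET_ABOVE_INITIAL.value,)),
    ("adult_age", (ExclusionReason.AGE_INELIGIBLE.value,)),
    ("initial_weight_available", (ExclusionReason.NO_INITIAL_WEIGHT.value,)),
    ("initial_bmi_overweight", (ExclusionReason.BMI_BELOW_THRESHOLD.value,)),
    ("final_weight_available", (ExclusionReason.NO_FINAL_WEIGHT.value,)),
    ("consistent_weights", (ExclusionReason.INCONSISTENT_WEIGHTS.value,)),
    ("minimal_adherence", (ExclusionReason.INSUFFICIENT_ADHERENCE.value,)),
]


def apply_eligibility(
    cohort: Iterable[Lifelog], criteria: EligibilityCriteria | None = None
) -> tuple[list[Lifelog], list[EligibilityRecord], CohortFlow]:
    """Screen a cohort and account for every exclusion.

    Returns the included lifelogs, one :class:`EligibilityRecord` per input
    user (in input order), and a :class:`CohortFlow` whose stage counts are
    conserved (n_in = n_excluded + n_out at every stage).
    """
    c = criteria or EligibilityCriteria()
    cohort = list(cohort)
    records = [_screen_user(log.sort_streams(), c) for log in cohort]
    by_reason: dict[str, int] = {}
    for rec in records:
        if rec.exclusion_reason is not None:
            by_reason[rec.exclusion_reason] = by_reason.get(rec.exclusion_reason, 0) + 1

    flow = CohortFlow()
    n = len(cohort)
    for stage_name, reasons in _STAGES:
        excluded = sum(by_reason.get(r, 0) for r in reasons)
        flow.add(stage_name, n, excluded, "|".join(reasons))
        n -= excluded
    included = [log for log, rec in zip(cohort, records) if rec.included]
    assert n == len(included)
    return included, records, flow


def write_lifelogs_jsonl(cohort: Iterable[Lifelog], path: str | Path) -> None:
    """One user per line, JSON; the package's lifelog interchange format."""
    with open(path, "w") as fh:
        for log in cohort:
            fh.write(log.to_json() + "\n")


def read_lifelogs_jsonl(path: str | Path) -> list[Lifelog]:
    with open(path) as fh:
        return [Lifelog.from_json(line) for line in fh if line.strip()]
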