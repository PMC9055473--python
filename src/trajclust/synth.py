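"""Synthetic 16-week lifelog cohorts with known trajectory structure.

Real mobile weight-management lifelogs are proprietary, so every stage of
the pipeline is exercised on synthetic cohorts built here.  The generator
emulates the structure the analysis assumes rather than any particular
dataset: five latent weight-trajectory archetypes (sharp decrease,
moderate decrease, yo-yo rebound around mid-program, stable/increase, and
a non-converging "other"), cluster-dependent self-monitoring adherence
that is indistinguishable in week 1, peaks in weeks 2-4 and then
diverges, irregular day-level sampling, and optional injected protocol
violations (implausible heights, missing weight records, missing final
weights, inconsistent weight jumps) that exercise every exclusion rule of
the eligibility cascade.

All curve parameterizations are stand-ins chosen for qualitative
plausibility; nothing here is fit to real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import Lifelog

__all__ = [
    "ARCHETYPES",
    "ArchetypeCurve",
    "SynthConfig",
    "ConfigError",
    "archetype_curve",
    "default_adherence",
    "generate_cohort",
    "inject_violations",
]

ARCHETYPES = ("sharp_decrease", "moderate_decrease", "yo_yo", "stable_increase", "other")

VIOLATION_TYPES = ("height_out_of_range", "no_weight_logs", "missing_final_weight", "inconsistent_weight")


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class ArchetypeCurve:
    """A latent trajectory: fractional weight change as a function of week.

    ``mean_trajectory(t)`` maps continuous program time t (in weeks,
    t=0 at enrollment) to the expected fractional change from baseline
    weight (-0.05 = five percent below baseline).
    """

    name: str
    mean_trajectory: Callable[[float], float]
    trajectory_sd: float = 0.0
    nadir_week: float | None = None


def _sharp(t: float, weeks: int = 16) -> float:
    # steady near-linear decline, no plateau, reaching -10% at program end
    lam = 0.8
    return -0.10 * (1.0 - math.exp(-lam * t / weeks)) / (1.0 - math.exp(-lam))


def _moderate(t: float, knee: float = 5.0) -> float:
    # sharp initial reduction reaching -4.5% by the knee week, then plateau
    lam = 3.0
    if t >= knee:
        return -0.045
    return -0.045 * (1.0 - math.exp(-lam * t / knee)) / (1.0 - math.exp(-lam))


def _yo_yo(t: float, nadir: float = 8.0, weeks: int = 16) -> float:
    # decline to a -5% nadir mid-program, then rebound to -0.5%
    if t <= nadir:
        return -0.05 * (1.0 - math.exp(-2.0 * t / nadir)) / (1.0 - math.exp(-2.0))
    return -0.05 + 0.045 * (t - nadir) / (weeks - nadir)


def _stable_increase(t: float, weeks: int = 16) -> float:
    return 0.02 * t / weeks


def _other(t: float, weeks: int = 16) -> float:
    # non-converging oscillation: rise-then-fall-then-rise, ~1.6 cycles
    return 0.02 * math.sin(2.0 * math.pi * t / 10.0 + math.pi)


def archetype_curve(name: str, program_weeks: int = 16, yo_yo_nadir_week: float = 8.0) -> ArchetypeCurve:
    """Return the parametric mean curve for one archetype."""
    if name == "sharp_decrease":
        return ArchetypeCurve(name, lambda t: _sharp(t, program_weeks))
    if name == "moderate_decrease":
        return ArchetypeCurve(name, lambda t: _moderate(t))
    if name == "yo_yo":
        return ArchetypeCurve(
            name,
            lambda t: _yo_yo(t, yo_yo_nadir_week, program_weeks),
            nadir_week=yo_yo_nadir_week,
        )
    if name == "stable_increase":
        return ArchetypeCurve(name, lambda t: _stable_increase(t, program_weeks))
    if name == "other":
        return ArchetypeCurve(name, lambda t: _other(t, program_weeks))
    raise ConfigError(f"archetype name: unknown archetype {name!r}")


def _gap_shape(program_weeks: int, peak_week: int) -> np.ndarray:
    """Adherence-divergence profile over weeks 1..W.

    Zero in week 1 (archetypes start out indistinguishable), linear rise
    to 1 at ``peak_week``, then decay toward a floor of 0.2: the between-
    archetype adherence gap is maximal at the peak week and shrinks, but
    never closes, afterwards.
    """
    h = np.empty(program_weeks)
    for w in range(1, program_weeks + 1):
        if w <= peak_week:
            h[w - 1] = (w - 1) / (peak_week - 1) if peak_week > 1 else 1.0
        else:
            h[w - 1] = max(0.2, 1.0 - 0.25 * (w - peak_week))
    return h


def default_adherence(program_weeks: int = 16, peak_gap_week: int = 4) -> dict:
    """Per-archetype weekly log-rate curves.

    Meal and weight log rates share a common envelope (peaking around week
    3) plus an archetype-specific multiple of the gap profile, so weekly
    rates are identical across archetypes in week 1 and diverge most at
    ``peak_gap_week``.  Message rates are flat; steps are a daily mean.
    Base levels echo the per-week medians typical of this kind of program
    (meal logs ~15-19/week, weight logs ~4-5/week, a few coach messages,
    ~5000 steps/day).
    """
    W = program_weeks
    h = _gap_shape(W, peak_gap_week)
    # common envelope: quick ramp-up, peak week 3, slow fade
    env = np.empty(W)
    for w in range(1, W + 1):
        if w == 1:
            env[w - 1] = 17.0
        elif w == 2:
            env[w - 1] = 17.8
        else:
            env[w - 1] = max(13.0, 18.0 - 0.28 * (w - 3))
    wenv = np.empty(W)
    for w in range(1, W + 1):
        if w == 1:
            wenv[w - 1] = 4.6
        elif w == 2:
            wenv[w - 1] = 5.0
        else:
            wenv[w - 1] = max(4.0, 5.1 - 0.05 * (w - 3))

    meal_offset = {"sharp_decrease": +1.2, "moderate_decrease": 0.0, "yo_yo": -2.5,
                   "stable_increase": -3.0, "other": -3.5}
    wt_offset = {"sharp_decrease": +0.25, "moderate_decrease": 0.0, "yo_yo": -0.6,
                 "stable_increase": -0.5, "other": -0.8}
    msg_sent = {"sharp_decrease": 2.1, "moderate_decrease": 2.1, "yo_yo": 1.9,
                "stable_increase": 1.9, "other": 1.9}
    msg_recv = {"sharp_decrease": 3.0, "moderate_decrease": 3.0, "yo_yo": 2.8,
                "stable_increase": 2.8, "other": 2.8}
    steps_mean = {"sharp_decrease": 5470.0, "moderate_decrease": 5190.0, "yo_yo": 5100.0,
                  "stable_increase": 5070.0, "other": 4810.0}

    params = {}
    for a in ARCHETYPES:
        params[a] = {
            "meal_rates": (env + meal_offset[a] * h).clip(min=0.5).tolist(),
            "weight_rates": (wenv + wt_offset[a] * h).clip(min=0.5).tolist(),
            "msg_sent_rate": msg_sent[a],
            "msg_recv_rate": msg_recv[a],
            "steps_mean": steps_mean[a],
            "steps_sd": 1800.0,
            "step_log_p": 0.85,
        }
    params["peak_gap_week"] = peak_gap_week
    return params


@dataclass
class SynthConfig:
    """Generator settings; defaults define the package's study conditions."""

    n_users: int = 500
    archetype_weights: tuple[float, ...] = (0.45, 0.20, 0.13, 0.13, 0.09)
    program_weeks: int = 16
    weight_noise_sd: float = 0.5  # kg, self-weighing variability
    baseline_bmi_mean: float = 33.6
    baseline_bmi_sd: float = 5.9
    height_mean_cm: float = 166.4
    height_sd_cm: float = 7.4
    age_mean: float = 43.9
    age_sd: float = 10.9
    female_fraction: float = 0.92
    yo_yo_nadir_week: float = 8.0
    # between-user heterogeneity: lognormal sigma on each user's logging
    # rates (mean-1 multiplier) and SD of the per-user daily-step mean.
    # Real cohorts show large between-person spread in both (the printed
    # per-cluster IQRs are of the same order as the medians).
    adherence_user_sd: float = 0.2
    message_user_sd: float = 0.5  # messaging habits vary far more between users
    steps_between_sd: float = 2000.0
    adherence_params: dict = field(default_factory=default_adherence)
    violation_rates: dict = field(default_factory=lambda: {v: 0.0 for v in VIOLATION_TYPES})
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.n_users < 0:
            raise ConfigError(f"n_users: must be >= 0, got {self.n_users}")
        w = np.asarray(self.archetype_weights, dtype=float)
        if w.size != len(ARCHETYPES):
            raise ConfigError(f"archetype_weights: need {len(ARCHETYPES)} entries, got {w.size}")
        if (w < 0).any():
            raise ConfigError("archetype_weights: entries must be >= 0")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ConfigError(f"archetype_weights: must sum to 1, got {w.sum()!r}")
        if self.program_weeks < 1:
            raise ConfigError(f"program_weeks: must be >= 1, got {self.program_weeks}")
        for name in ("weight_noise_sd", "baseline_bmi_sd", "height_sd_cm", "age_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        for vname, rate in self.violation_rates.items():
            if vname not in VIOLATION_TYPES:
                raise ConfigError(f"violation_rates: unknown violation {vname!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"violation_rates[{vname}]: must be in [0, 1], got {rate}")
        return self

    def to_json(self) -> str:
        d = asdict(self)
        d["archetype_weights"] = list(d["archetype_weights"])
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "archetype_weights" in d:
            d["archetype_weights"] = tuple(d["archetype_weights"])
        return cls(**d).validate()


def _gen_user(
    uid: str, archetype: str, cfg: SynthConfig, rng: np.random.Generator
) -> Lifelog:
    W = cfg.program_weeks
    curve = archetype_curve(archetype, W, cfg.yo_yo_nadir_week)
    ap = cfg.adherence_params[archetype]

    sex = "female" if rng.random() < cfg.female_fraction else "male"
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18.0, 90.0))
    height = float(np.clip(rng.normal(cfg.height_mean_cm, cfg.height_sd_cm), 140.0, 205.0))
    bmi = float(np.clip(rng.normal(cfg.baseline_bmi_mean, cfg.baseline_bmi_sd), 25.5, 60.0))
    baseline_kg = bmi * (height / 100.0) ** 2

    weight_logs: list[tuple[int, float]] = []
    meal_logs: list[tuple[int, str]] = []
    messages: list[tuple[int, str]] = []
    steps: list[tuple[int, int]] = []

    # per-user random effects: a mean-1 lognormal multiplier on all logging
    # rates and an individual habitual daily-step level
    sd = cfg.adherence_user_sd
    log_mult = float(rng.lognormal(mean=-0.5 * sd * sd, sigma=sd)) if sd > 0 else 1.0
    msd = cfg.message_user_sd
    msg_mult = float(rng.lognormal(mean=-0.5 * msd * msd, sigma=msd)) if msd > 0 else 1.0
    user_steps_mean = float(max(500.0, rng.normal(ap["steps_mean"], cfg.steps_between_sd)))

    meal_seq = 0
    for w in range(1, W + 1):
        d0 = 7 * (w - 1)
        n_wt = rng.poisson(log_mult * ap["weight_rates"][w - 1])
        for d in sorted(rng.integers(d0, d0 + 7, size=n_wt).tolist()):
            kg = baseline_kg * (1.0 + curve.mean_trajectory(d / 7.0)) + rng.normal(0.0, cfg.weight_noise_sd)
            weight_logs.append((int(d), float(kg)))
        n_meal = rng.poisson(log_mult * ap["meal_rates"][w - 1])
        for d in sorted(rng.integers(d0, d0 + 7, size=n_meal).tolist()):
            meal_logs.append((int(d), f"{uid}-m{meal_seq}"))
            meal_seq += 1
        for direction, rate in (("sent", ap["msg_sent_rate"]), ("received", ap["msg_recv_rate"])):
            n_msg = rng.poisson(msg_mult * rate)
            for d in sorted(rng.integers(d0, d0 + 7, size=n_msg).tolist()):
                messages.append((int(d), direction))
        for d in range(d0, d0 + 7):
            if rng.random() < ap["step_log_p"]:
                steps.append((d, int(max(0.0, rng.normal(user_steps_mean, ap["steps_sd"])))))

    # everyone weighs in on enrollment day (the program asks for it), and a
    # final-program-week log is guaranteed; violations are injected separately
    if not any(d == 0 for d, _ in weight_logs):
        kg = baseline_kg * (1.0 + curve.mean_trajectory(0.0)) + rng.normal(0.0, cfg.weight_noise_sd)
        weight_logs.append((0, float(kg)))
    final_lo, final_hi = 7 * (W - 1), 7 * W - 1
    if not any(final_lo <= d <= final_hi for d, _ in weight_logs):
        d = final_lo + 3
        kg = baseline_kg * (1.0 + curve.mean_trajectory(d / 7.0)) + rng.normal(0.0, cfg.weight_noise_sd)
        weight_logs.append((int(d), float(kg)))

    log = Lifelog(
        user_id=uid, sex=sex, age=round(age, 1), height_cm=round(height, 1),
        weight_logs=weight_logs, meal_logs=meal_logs, messages=messages, steps=steps,
    )
    return log.sort_streams()


def generate_cohort(config: SynthConfig) -> tuple[list[Lifelog], list[str]]:
    """Draw a cohort of lifelogs plus their ground-truth archetype labels.

    Deterministic given ``config.seed``: the same config always yields a
    byte-identical cohort.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = [ARCHETYPES[i] for i in rng.choice(len(ARCHETYPES), size=cfg.n_users,
                                                p=np.asarray(cfg.archetype_weights, float))]
    cohort = [_gen_user(f"u{i:05d}", labels[i], cfg, rng) for i in range(cfg.n_users)]
    return cohort, labels


def inject_violations(
    cohort: Sequence[Lifelog], config: SynthConfig
) -> tuple[list[Lifelog], pd.DataFrame]:
    """Corrupt a configured fraction of users with each protocol violation.

    Users are drawn independently per violation at ``violation_rates``.
    Returns the modified cohort (copies are edited in place on the given
    list) and a manifest DataFrame with one (user_id, violation) row per
    applied corruption.  A violation that has become inapplicable (e.g. an
    inconsistent-weight jump for a user whose weight logs were removed) is
    skipped and does not appear in the manifest.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    manifest_rows: list[dict] = []
    cohort = list(cohort)
    for vname in VIOLATION_TYPES:  # fixed order => deterministic interaction
        rate = cfg.violation_rates.get(vname, 0.0)
        if rate <= 0:
            continue
        hit = rng.random(len(cohort)) < rate
        for log, h in zip(cohort, hit):
            if not h:
                continue
            if vname == "height_out_of_range":
                log.height_cm = float(rng.choice([rng.uniform(100.0, 124.5), rng.uniform(231.0, 255.0)]))
            elif vname == "no_weight_logs":
                log.weight_logs = []
            elif vname == "missing_final_weight":
                cut = 7 * (cfg.program_weeks - 1)
                log.weight_logs = [(d, kg) for d, kg in log.weight_logs if d < cut]
                if not log.weight_logs:
                    continue
            elif vname == "inconsistent_weight":
                if not log.weight_logs or log.height_cm is None or log.height_cm <= 0:
                    continue
                # spike one week after an existing log, sized to a 5 kg/m^2 jump
                # (margin over the 3.5 threshold so ordinary week-to-week
                # trajectory movement cannot mask the violation)
                d0, kg0 = log.weight_logs[rng.integers(0, len(log.weight_logs))]
                delta = 5.0 * (log.height_cm / 100.0) ** 2
                log.weight_logs.append((int(d0) + 7, float(kg0 + delta)))
                log.sort_streams()
            manifest_rows.append({"user_id": log.user_id, "violation": vname})
    manifest = pd.DataFrame(manifest_rows, columns=["user_id", "violation"])
    return cohort, manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)
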