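"""Irregular weight series -> length-16 standardized trajectories.

Each eligible user's weight logs form an irregularly sampled series of
heterogeneous length T_i.  Clustering needs equal-length, scale-free
inputs, so every series passes through the same three steps:

1. *regularize* — collapse duplicate days to their mean, then evaluate
   the piecewise-linear interpolant at 30 equally spaced time points
   spanning [first day, last day].  (For short series this is linear
   interpolation; for dense series it acts as equal-interval resampling —
   the same operation covers both.)
2. *moving average* — a centered window of 15 observations in valid mode,
   30 - 15 + 1 = 16 points out, suppressing day-to-day self-weighing
   noise.
3. *z-normalize* — subtract the mean and divide by the population SD, so
   clustering sees only the shape of the trajectory, never the absolute
   weight.

The pre-smoothing grid length of 30 is the single inferred parameter: it
is the unique value for which a window of 15 leaves exactly 16 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DomainError, Lifelog

__all__ = [
    "WeightSeries",
    "ProcessedSeries",
    "regularize",
    "moving_average",
    "z_normalize",
    "preprocess_pipeline",
    "preprocess_cohort",
    "GRID_LEN",
    "SMOOTHING_WINDOW",
]

GRID_LEN = 30
SMOOTHING_WINDOW = 15
RESAMPLE_THRESHOLD = 30  # series at/above this length count as "long"
_DEGENERATE_SD = 1e-12


@dataclass
class WeightSeries:
    """One user's raw (day, kg) observations, sorted by day."""

    user_id: str
    days: np.ndarray
    values_kg: np.ndarray

    @classmethod
    def from_lifelog(cls, log: Lifelog) -> "WeightSeries":
        if not log.weight_logs:
            raise DomainError(f"user {log.user_id}: no weight logs")
        pairs = sorted(log.weight_logs)
        return cls(
            user_id=log.user_id,
            days=np.array([d for d, _ in pairs], dtype=float),
            values_kg=np.array([kg for _, kg in pairs], dtype=float),
        )

    def dedupe(self) -> tuple[np.ndarray, np.ndarray]:
        """Collapse same-day observations to their mean."""
        df = pd.DataFrame({"day": self.days, "kg": self.values_kg})
        g = df.groupby("day", sort=True)["kg"].mean()
        return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)


@dataclass
class ProcessedSeries:
    user_id: str
    values: np.ndarray  # length 16, mean 0, SD 1 (unless degenerate)
    provenance: dict = field(default_factory=dict)


def regularize(series: WeightSeries, grid_len: int = GRID_LEN) -> np.ndarray:
    """Evaluate the series' piecewise-linear interpolant on an even grid.

    The grid has ``grid_len`` points spanning [first day, last day] after
    duplicate days are averaged.  Requires at least two distinct days.
    """
    days, vals = series.dedupe()
    if days.size < 2:
        raise DomainError(
            f"user {series.user_id}: need >= 2 distinct observation days, got {days.size}"
        )
    grid = np.linspace(days[0], days[-1], grid_len)
    return np.interp(grid, days, vals)


def moving_average(values: np.ndarray, window: int = SMOOTHING_WINDOW) -> np.ndarray:
    """Centered moving average, valid mode: len(out) = len(in) - window + 1."""
    values = np.asarray(values, dtype=float)
    if values.size < window:
        raise DomainError(f"moving_average: need >= {window} values, got {values.size}")
    return np.convolve(values, np.ones(window) / window, mode="valid")


def z_normalize(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale to mean 0, population SD 1; flat series map to zeros.

    Returns (scaled values, degenerate flag).  The degenerate rule keeps a
    perfectly flat trajectory representable instead of dividing by zero.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DomainError("z_normalize: need >= 2 values")
    mu = values.mean()
    sd = values.std(ddof=0)
    if sd < _DEGENERATE_SD:
        return np.zeros_like(values), True
    return (values - mu) / sd, False


def preprocess_pipeline(
    series: WeightSeries, grid_len: int = GRID_LEN, window: int = SMOOTHING_WINDOW
) -> ProcessedSeries:
    """regularize -> moving_average -> z_normalize, with provenance."""
    t_i = series.days.size
    grid = regularize(series, grid_len)
    smooth = moving_average(grid, window)
    values, degenerate = z_normalize(smooth)
    return ProcessedSeries(
        user_id=series.user_id,
        values=values,
        provenance={
            "interpolated": t_i < RESAMPLE_THRESHOLD,
            "resampled_from": int(t_i),
            "smoothing_window": window,
            "grid_len": grid_len,
            "degenerate": degenerate,
        },
    )


def preprocess_cohort(
    cohort: list[Lifelog], grid_len: int = GRID_LEN, window: int = SMOOTHING_WINDOW
) -> tuple[pd.DataFrame, list[ProcessedSeries]]:
    """Process every user; returns a users x 16 matrix (index = user_id)."""
    processed = [
        preprocess_pipeline(WeightSeries.from_lifelog(log), grid_len, window)
        for log in cohort
    ]
    mat = pd.DataFrame(
        np.vstack([p.values for p in processed]) if processed else np.empty((0, grid_len - window + 1)),
        index=[p.user_id for p in processed],
        columns=[f"t{j}" for j in range(grid_len - window + 1)],
    )
    mat.index.name = "user_id"
    return mat, processed
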