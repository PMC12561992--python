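"""Dimensional glucose schedule, its normalization, and the virtual-mouse sampler.

The stimulus is blood glucose in diabetic (BTBR ob/ob-like) mice: a linear
rise ``G(t) = 0.051 t - 9.38`` mmol/l over 336-1008 h (weeks 2-6), then a
piecewise-constant hyperglycemic plateau read from interval means (weekly to
11 weeks, biweekly 12-20 weeks).  The network sees the normalized weight

    WGLU'(t) = (G(t) - gmin) / (gmax - gmin)

with gmin the linear prediction at week 2 and gmax a fixture policy value
(the concentration at which normalized glucose activity reaches 1); schedules
above gmax produce weights above 1, which the model allows for the stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SLOPE",
    "INTERCEPT",
    "LINEAR_SPAN",
    "HOURS_PER_WEEK",
    "GlucoseSchedule",
    "PopulationSchedules",
    "linear_glucose",
    "sample_population",
]

HOURS_PER_WEEK = 168.0
SLOPE = 0.051  # mmol/l per hour
INTERCEPT = -9.38  # mmol/l
LINEAR_SPAN = (336.0, 1008.0)  # hours (weeks 2-6)


def linear_glucose(t, slope: float = SLOPE, intercept: float = INTERCEPT):
    """Linear-segment glucose concentration (mmol/l) for 336 <= t <= 1008 h."""
    t = np.asarray(t, dtype=float)
    if np.any(t < LINEAR_SPAN[0] - 1e-9) or np.any(t > LINEAR_SPAN[1] + 1e-9):
        raise ValueError(f"t outside the linear span {LINEAR_SPAN}")
    out = slope * t + intercept
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GlucoseSchedule:
    """Glucose concentration G(t) and its normalized network weight WGLU'(t).

    ``intervals`` are contiguous left-closed/right-open (t_start_h, t_end_h,
    value_mmol_l) steps covering t >= 1008 h.  ``control_time`` (hours)
    implements a glycemic-control intervention: for t >= control_time the
    concentration is reset to gmin so the weight is 0.
    """

    intervals: tuple[tuple[float, float, float], ...]
    gmax: float
    slope: float = SLOPE
    intercept: float = INTERCEPT
    linear_span: tuple[float, float] = LINEAR_SPAN
    control_time: float | None = None

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        if ivs:
            if abs(ivs[0][0] - self.linear_span[1]) > 1e-9:
                raise ValueError("first interval must start where the linear span ends")
            for (a0, a1, _), (b0, _, _) in zip(ivs, ivs[1:]):
                if a1 >= b0 + 1e-9 and abs(a1 - b0) > 1e-9:
                    raise ValueError("intervals overlap")
                if abs(a1 - b0) > 1e-9:
                    raise ValueError("intervals are not contiguous")
        object.__setattr__(self, "intervals", tuple(ivs))
        if self.gmax <= self.gmin:
            raise ValueError("degenerate normalization range: gmax <= gmin")

    @property
    def gmin(self) -> float:
        """Minimum observed glucose: the linear prediction at 2 weeks."""
        return self.slope * self.linear_span[0] + self.intercept

    @property
    def t_end(self) -> float:
        return self.intervals[-1][1] if self.intervals else self.linear_span[1]

    def concentration(self, t):
        """G(t) in mmol/l over the full coverage (vectorized)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < self.linear_span[0] - 1e-9) or np.any(t > self.t_end + 1e-9):
            raise ValueError(
                f"t outside glucose coverage [{self.linear_span[0]}, {self.t_end}] h"
            )
        out = self.slope * np.clip(t, *self.linear_span) + self.intercept
        for t0, t1, val in self.intervals:
            sel = (t >= t0) & ((t < t1) | (t1 >= self.t_end - 1e-9))
            out[sel] = val
        if self.control_time is not None:
            out[t >= self.control_time] = self.gmin
        return out if out.shape != (1,) else float(out[0])

    def weight(self, t):
        """Normalized reaction weight WGLU'(t); may exceed 1."""
        g = self.concentration(t)
        return (g - self.gmin) / (self.gmax - self.gmin)

    def with_control(self, t_control: float) -> "GlucoseSchedule":
        """Glycemic-control intervention: G = gmin (weight 0) for t >= t_control."""
        return replace(self, control_time=float(t_control))

    def extended(self, t_end: float) -> "GlucoseSchedule":
        """Hold the final interval value out to ``t_end`` (for >20-week runs)."""
        if t_end <= self.t_end:
            return self
        t0, _, val = self.intervals[-1]
        ivs = self.intervals[:-1] + ((t0, float(t_end), val),)
        return replace(self, intervals=ivs)


@dataclass(frozen=True)
class PopulationSchedules:
    """Virtual mouse population: shared linear rise, per-mouse interval values."""

    schedules: tuple[GlucoseSchedule, ...]
    seed: int
    interval_stats: tuple[tuple[float, float, float, float], ...]  # t0, t1, mean, sd

    @property
    def n(self) -> int:
        return len(self.schedules)

    def mean_values(self) -> np.ndarray:
        """Per-interval mean over mice of the sampled values."""
        vals = np.array(
            [[iv[2] for iv in s.intervals] for s in self.schedules]
        )
        return vals.mean(axis=0)


def sample_population(
    interval_stats,
    n: int = 100,
    seed: int = 0,
    gmax: float | None = None,
) -> PopulationSchedules:
    """Draw a virtual mouse population from per-interval normal distributions.

    ``interval_stats`` is an iterable of (t_start_h, t_end_h, mean_mmol_l,
    sd_mmol_l); each mouse receives one independent normal draw per interval
    (negative draws are kept with a warning; the model is agnostic).  A fixed
    ``seed`` reproduces the population bitwise.
    """
    stats = [tuple(map(float, row)) for row in interval_stats]
    if n < 1:
        raise ValueError("need at least one mouse")
    for _, _, _, sd in stats:
        if sd < 0:
            raise ValueError("interval SD must be >= 0")
    if gmax is None:
        from .synthetic import default_gmax

        gmax = default_gmax()
    rng = np.random.default_rng(seed)
    # one vector of n draws per interval, assigned mouse-wise
    draws = np.column_stack(
        [rng.normal(mean, sd, size=n) for _, _, mean, sd in stats]
    )
    if np.any(draws < 0):
        warnings.warn(
            "negative glucose draw kept (no truncation policy)", RuntimeWarning
        )
    schedules = tuple(
        GlucoseSchedule(
            intervals=tuple(
                (t0, t1, float(v)) for (t0, t1, _, _), v in zip(stats, row)
            ),
            gmax=gmax,
        )
        for row in draws
    )
    return PopulationSchedules(
        schedules=schedules, seed=seed, interval_stats=tuple(stats)
    )
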