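"""Synthetic study generator: glucose fixtures and fenestration observations.

The package needs two kinds of study inputs that, in the underlying mouse
work, came from external measurement campaigns: per-interval glucose
statistics for diabetic mice, and fenestration density/width observations at
weeks 6/10/15/20 for healthy and diabetic arms.  This module emulates both so
the whole pipeline runs without downloads: glucose follows the documented
linear rise and then a hyperglycemic plateau, and observations are model
predictions under the true structural parameters plus independent additive
normal noise.  Noiseless mode reproduces the model exactly, so calibration
recovery can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network
from .glucose import GlucoseSchedule, HOURS_PER_WEEK, LINEAR_SPAN, linear_glucose
from .structure import FenestrationParams, simulate_structure

__all__ = [
    "default_gmax",
    "make_glucose_fixture",
    "make_observations",
    "SyntheticStudy",
    "make_study",
    "HEALTHY_Y0_NUMBER",
]

OBS_WEEKS = (6, 10, 15, 20)

#: Healthy-arm initial fenestration number: the synthetic healthy cohort is
#: observed while its density is still maturing toward the adult steady state,
#: which is what makes the formation-term parameters identifiable.
HEALTHY_Y0_NUMBER = 5.0

#: default observation noise, ~10% of the baseline density (7.0) and width (47.91 nm)
DENSITY_SD = 0.7
WIDTH_SD = 4.8


def default_gmax() -> float:
    """Normalization ceiling: the linear glucose prediction at week 5 (840 h),
    so normalized glucose activity reaches 1 by 5 weeks."""
    return linear_glucose(5 * HOURS_PER_WEEK)


def default_intervals() -> list[tuple[float, float]]:
    """Measurement-cadence interval boundaries: weekly to 11 weeks, biweekly
    12-20 weeks (hours)."""
    weeks = [6, 7, 8, 9, 10, 11, 12, 14, 16, 18, 20]
    edges = [w * HOURS_PER_WEEK for w in weeks]
    return list(zip(edges[:-1], edges[1:]))


def make_glucose_fixture(
    plateau_mmol_l: float = 43.0,
    sd_mmol_l: float = 3.0,
    seed: int | None = None,
) -> tuple[GlucoseSchedule, list[tuple[float, float, float, float]]]:
    """Build the mean glucose schedule and its interval statistics.

    The plateau must lie above the week-6 linear endpoint (42.03 mmol/l) so
    the schedule never drops when the step segments take over and the
    normalized weight stays >= 1 after week 5.  Returns (schedule, stats)
    where stats rows are (t_start_h, t_end_h, mean_mmol_l, sd_mmol_l).
    """
    g_week6 = linear_glucose(LINEAR_SPAN[1])
    if plateau_mmol_l < g_week6:
        raise ValueError(
            f"plateau {plateau_mmol_l} mmol/l below the week-6 linear endpoint "
            f"({g_week6:.2f} mmol/l)"
        )
    if sd_mmol_l < 0:
        raise ValueError("sd must be >= 0")
    stats = [
        (t0, t1, float(plateau_mmol_l), float(sd_mmol_l))
        for t0, t1 in default_intervals()
    ]
    schedule = GlucoseSchedule(
        intervals=tuple((t0, t1, m) for t0, t1, m, _ in stats),
        gmax=default_gmax(),
    )
    return schedule, stats


def _predict_arm(
    spec: network.NetworkSpec,
    schedule: GlucoseSchedule,
    params: FenestrationParams,
    arm: str,
    weeks,
):
    """Model-truth density (and width for the diabetic arm) at the given weeks."""
    variant = "healthy" if arm == "healthy" else "disease"
    net = network.simulate(
        spec.with_variant(variant), schedule, t_span=(LINEAR_SPAN[0], schedule.t_end)
    )
    y0_number = HEALTHY_Y0_NUMBER if arm == "healthy" else params.yNumber_ss1
    traj = simulate_structure(
        net,
        params,
        y0_number=y0_number,
        number_formation_only=(arm == "healthy"),
    )
    t_obs = np.asarray(weeks, dtype=float) * HOURS_PER_WEEK
    density = np.interp(t_obs, traj.t, traj.number)
    width = np.interp(t_obs, traj.t, traj.diameter)
    return density, width


def make_observations(
    true_params: FenestrationParams,
    schedule: GlucoseSchedule | None = None,
    spec: network.NetworkSpec | None = None,
    arms=("healthy", "diabetic"),
    weeks=OBS_WEEKS,
    sd_density: float = DENSITY_SD,
    sd_width: float = WIDTH_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate fenestration observations with additive normal noise.

    Returns a long-format frame (week, arm, quantity, mean, sd, truth):
    density for both arms, width (nm) for the diabetic arm.  ``mean`` is the
    noisy observed value, ``truth`` the noiseless model prediction.
    """
    if sd_density < 0 or sd_width < 0:
        raise ValueError("noise SDs must be >= 0")
    if spec is None:
        from .modelio import default_model

        spec = default_model()
    if schedule is None:
        schedule, _ = make_glucose_fixture()
    rng = np.random.default_rng(seed)
    rows = []
    for arm in arms:
        density, width = _predict_arm(spec, schedule, true_params, arm, weeks)
        noisy_density = density + rng.normal(0.0, sd_density, size=len(density))
        for w, truth, obs in zip(weeks, density, noisy_density):
            rows.append(
                {
                    "week": w,
                    "arm": arm,
                    "quantity": "density",
                    "mean": obs,
                    "sd": sd_density,
                    "truth": truth,
                }
            )
        if arm == "diabetic":
            noisy_width = width + rng.normal(0.0, sd_width, size=len(width))
            for w, truth, obs in zip(weeks, width, noisy_width):
                rows.append(
                    {
                        "week": w,
                        "arm": arm,
                        "quantity": "width_nm",
                        "mean": obs,
                        "sd": sd_width,
                        "truth": truth,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SyntheticStudy:
    """Bundle of everything a calibration run consumes, plus the truth."""

    true_params: FenestrationParams
    schedule: GlucoseSchedule
    glucose_stats: list[tuple[float, float, float, float]]
    observations: pd.DataFrame
    seed: int


def make_study(
    true_params: FenestrationParams | None = None,
    seed: int = 0,
    sd_density: float = DENSITY_SD,
    sd_width: float = WIDTH_SD,
    plateau_mmol_l: float = 43.0,
    plateau_sd_mmol_l: float = 3.0,
    spec: network.NetworkSpec | None = None,
) -> SyntheticStudy:
    """Default synthetic study: best-fit structural parameters as truth."""
    params = true_params or FenestrationParams()
    schedule, stats = make_glucose_fixture(plateau_mmol_l, plateau_sd_mmol_l)
    obs = make_observations(
        params,
        schedule=schedule,
        spec=spec,
        sd_density=sd_density,
        sd_width=sd_width,
        seed=seed,
    )
    return SyntheticStudy(
        true_params=params,
        schedule=schedule,
        glucose_stats=stats,
        observations=obs,
        seed=seed,
    )
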