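"""Local sensitivity screening and in silico intervention protocols.

Sensitivity uses the normalized local index

    S_{m,k} = 100 * (dY_m / dP_k) * (P_k / Y_m)   [percent]

for outputs m in {fenestration number, diameter} at the final simulation time
and parameters k in {species ymax, reaction weight W}, perturbed one-at-a-time
(complete knockdown: dP = -P, so S = -100 * dY / Y_base).  A positive index
means the inhibition lowered the output.  |S| > 1.5% classifies a target as
sensitive.

Interventions cover the three protocols: time-dependent glycemic control
(weight reset to 0 from t_c), chemical-agent knockouts over the virtual mouse
population (KN93 -> Ca, ML-7 -> MLCK, Y27632 -> Rho/Rock, calyculin A -> MLCP,
cytochalasin B -> stressed actin), and timed 50% partial knockdowns run out to
30 weeks with glucose held at its 20-week value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import network
from .glucose import GlucoseSchedule, HOURS_PER_WEEK, LINEAR_SPAN, PopulationSchedules
from .structure import FenestrationParams, FenestrationTrajectory, simulate_structure

__all__ = [
    "SENSITIVITY_THRESHOLD",
    "AGENT_TARGETS",
    "InterventionPlan",
    "run_model",
    "sensitivity_index",
    "screen_all",
    "apply_intervention",
    "run_intervention",
    "two_sample_ttest",
    "ttest_from_stats",
    "significance_stars",
    "relative_change_from_baseline",
    "timed_perturbations",
    "agents_battery",
]

SENSITIVITY_THRESHOLD = 1.5  # percent; |S| above this is "sensitive"

AGENT_TARGETS = {
    "KN93": "Ca",
    "ML-7": "MLCK",
    "Y27632": "RhoRock",
    "calyculinA": "MLCP",
    "cytochalasinB": "Actin_s",
}


@dataclass(frozen=True)
class InterventionPlan:
    """What is perturbed, when, and by how much.

    ``scale`` is the fraction of the pristine ymax or W retained (0 =
    complete knockdown, 0.5 = 50% reduction); for glucose control it is
    ignored.
    """

    kind: str  # species_knockdown | reaction_inhibition | glucose_control | chemical_agent
    target: str | int | None = None
    scale: float = 0.0
    t_apply: float = LINEAR_SPAN[0]
    t_end: float = 3360.0

    def __post_init__(self) -> None:
        kinds = (
            "species_knockdown",
            "reaction_inhibition",
            "glucose_control",
            "chemical_agent",
        )
        if self.kind not in kinds:
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if not (0.0 <= self.scale <= 1.0):
            raise ValueError("scale must lie in [0, 1]")
        if self.t_apply > self.t_end:
            raise ValueError("t_apply beyond simulation end")


def run_model(
    spec: network.NetworkSpec,
    schedule,
    params: FenestrationParams,
    t_span: tuple[float, float] = (LINEAR_SPAN[0], 3360.0),
    events=(),
    y0_number: float | None = None,
    grid_h: float = 6.0,
) -> tuple[network.NetworkTrajectory, FenestrationTrajectory]:
    """Simulate the network and the structure it drives over ``t_span``."""
    net = network.simulate(spec, schedule, t_span=t_span, events=events, grid_h=grid_h)
    struct = simulate_structure(net, params, y0_number=y0_number)
    return net, struct


def sensitivity_index(y_base: float, y_pert: float, p: float, dp: float) -> float:
    """Normalized local sensitivity in percent: 100 * (dY/dP) * (P/Y)."""
    if y_base == 0:
        raise ZeroDivisionError("zero baseline output")
    if dp == 0:
        raise ZeroDivisionError("zero parameter perturbation")
    return 100.0 * ((y_pert - y_base) / dp) * (p / y_base)


def screen_all(
    spec: network.NetworkSpec,
    schedule,
    params: FenestrationParams,
    t_span: tuple[float, float] = (LINEAR_SPAN[0], 3360.0),
    scale: float = 0.0,
    species: list[str] | None = None,
    reactions: list[int] | None = None,
) -> pd.DataFrame:
    """One-at-a-time knockdown screen over species ymax and reaction weights.

    Each parameter is reduced to ``scale`` of its pristine value for the whole
    simulation; outputs are the fenestration number and diameter at the final
    time.  The stimulus pseudo-reaction is not screened (glucose control is a
    separate intervention).  Returns one row per (target, output).
    """
    _, base = run_model(spec, schedule, params, t_span)
    y_base = {"number": base.number[-1], "diameter": base.diameter[-1]}

    if species is None:
        species = [s.id for s in spec.species]
    if reactions is None:
        reactions = [r.id for r in spec.reactions if not r.is_stimulus]

    rows = []

    def record(kind, target, pristine, perturbed_out):
        dp = (scale - 1.0) * pristine
        for output in ("number", "diameter"):
            s = sensitivity_index(y_base[output], perturbed_out[output], pristine, dp)
            rows.append(
                {
                    "kind": kind,
                    "target": target,
                    "output": output,
                    "S_percent": s,
                    "baseline": y_base[output],
                    "perturbed": perturbed_out[output],
                    "sensitive": abs(s) > SENSITIVITY_THRESHOLD,
                }
            )

    for sid in species:
        pspec = spec.with_overrides(ymax_scale={sid: scale})
        try:
            _, traj = run_model(pspec, schedule, params, t_span)
        except network.SolverError as err:
            raise network.SolverError(f"species {sid} knockdown: {err}") from err
        record(
            "species",
            sid,
            spec.get_species(sid).ymax,
            {"number": traj.number[-1], "diameter": traj.diameter[-1]},
        )
    for rid in reactions:
        pspec = spec.with_overrides(weight_scale={rid: scale})
        try:
            _, traj = run_model(pspec, schedule, params, t_span)
        except network.SolverError as err:
            raise network.SolverError(f"reaction {rid} inhibition: {err}") from err
        record(
            "reaction",
            rid,
            spec.get_reaction(rid).W,
            {"number": traj.number[-1], "diameter": traj.diameter[-1]},
        )
    return pd.DataFrame(rows)


def apply_intervention(
    spec: network.NetworkSpec,
    schedule,
    plan: InterventionPlan,
) -> tuple[network.NetworkSpec, object, tuple]:
    """Translate a plan into (spec, schedule, events) for simulation."""
    if plan.kind == "glucose_control":
        if isinstance(schedule, PopulationSchedules):
            sched = PopulationSchedules(
                schedules=tuple(s.with_control(plan.t_apply) for s in schedule.schedules),
                seed=schedule.seed,
                interval_stats=schedule.interval_stats,
            )
        else:
            sched = schedule.with_control(plan.t_apply)
        return spec, sched, ()
    if plan.kind == "chemical_agent":
        if plan.target not in AGENT_TARGETS:
            raise KeyError(
                f"unknown agent {plan.target!r}; known: {sorted(AGENT_TARGETS)}"
            )
        target = AGENT_TARGETS[plan.target]
        return (
            spec,
            schedule,
            (network.Event(time=plan.t_apply, kind="ymax", target=target, scale=plan.scale),),
        )
    if plan.kind == "species_knockdown":
        if plan.target not in {s.id for s in spec.species}:
            raise KeyError(f"unknown species {plan.target!r}")
        return (
            spec,
            schedule,
            (network.Event(time=plan.t_apply, kind="ymax", target=plan.target, scale=plan.scale),),
        )
    # reaction_inhibition
    if int(plan.target) not in {r.id for r in spec.reactions}:
        raise KeyError(f"unknown reaction {plan.target!r}")
    return (
        spec,
        schedule,
        (network.Event(time=plan.t_apply, kind="W", target=int(plan.target), scale=plan.scale),),
    )


def run_intervention(
    spec: network.NetworkSpec,
    schedule,
    params: FenestrationParams,
    plan: InterventionPlan,
    y0_number: float | None = None,
) -> tuple[network.NetworkTrajectory, FenestrationTrajectory]:
    spec2, sched2, events = apply_intervention(spec, schedule, plan)
    t_span = (LINEAR_SPAN[0], plan.t_end)
    if hasattr(sched2, "t_end") and sched2.t_end < plan.t_end:
        sched2 = sched2.extended(plan.t_end)
    return run_model(spec2, sched2, params, t_span, events=events, y0_number=y0_number)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def two_sample_ttest(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample Student t-test (two-sided)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0  # identical degenerate groups
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def ttest_from_stats(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Same test from summary statistics (for observed-data groups)."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return stars
    return "ns"


def relative_change_from_baseline(
    traj, t_ref: float, t_eval: float
) -> pd.Series:
    """Per-species (or per-output) change y(t_eval) - y(t_ref)."""
    if isinstance(traj, network.NetworkTrajectory):
        lo, hi = traj.t[0], traj.t[-1]
        if not (lo <= t_ref <= hi and lo <= t_eval <= hi):
            raise ValueError("evaluation time outside the trajectory span")
        return pd.Series(
            {
                name: traj.at(name, t_eval) - traj.at(name, t_ref)
                for name in traj.names
            }
        )
    lo, hi = traj.t[0], traj.t[-1]
    if not (lo <= t_ref <= hi and lo <= t_eval <= hi):
        raise ValueError("evaluation time outside the trajectory span")
    n_ref, d_ref = traj.at(t_ref)
    n_ev, d_ev = traj.at(t_eval)
    return pd.Series({"number": n_ev - n_ref, "diameter_nm": d_ev - d_ref})


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def timed_perturbations(
    spec: network.NetworkSpec,
    schedule: GlucoseSchedule,
    params: FenestrationParams,
    targets: list[tuple[str, str | int]],
    weeks=(8, 12, 20),
    scale: float = 0.5,
    t_end: float = 5040.0,
) -> pd.DataFrame:
    """Partial knockdowns applied at several times, run to 30 weeks.

    ``targets`` is a list of ("species", id) / ("reaction", id) pairs.  The
    glucose stimulus is held at its final interval value beyond its coverage.
    Returns final-time outputs per (target, week) plus the no-inhibition row.
    """
    sched = schedule.extended(t_end)
    _, base = run_model(spec, sched, params, (LINEAR_SPAN[0], t_end))
    rows = [
        {
            "kind": "none",
            "target": None,
            "week_applied": None,
            "number_final": base.number[-1],
            "diameter_final": base.diameter[-1],
        }
    ]
    for kind, target in targets:
        for wk in weeks:
            plan = InterventionPlan(
                kind="species_knockdown" if kind == "species" else "reaction_inhibition",
                target=target,
                scale=scale,
                t_apply=wk * HOURS_PER_WEEK,
                t_end=t_end,
            )
            _, traj = run_intervention(spec, sched, params, plan)
            rows.append(
                {
                    "kind": kind,
                    "target": target,
                    "week_applied": wk,
                    "number_final": traj.number[-1],
                    "diameter_final": traj.diameter[-1],
                }
            )
    out = pd.DataFrame(rows)
    out["number_pct_of_base"] = 100.0 * out["number_final"] / base.number[-1]
    out["diameter_pct_above_baseline"] = (
        100.0 * (out["diameter_final"] - params.yDiameter0) / params.yDiameter0
    )
    return out


def agents_battery(
    spec: network.NetworkSpec,
    population: PopulationSchedules,
    params: FenestrationParams,
    agents=tuple(AGENT_TARGETS),
    t_eval_week: float = 20.0,
    reference_groups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Chemical-agent knockouts over the virtual mouse population.

    Simulates every mouse without treatment and under each agent (target ymax
    set to 0 at the initial time), reporting the population mean/SD of number
    and diameter at ``t_eval_week`` plus pooled-variance t-tests against the
    no-treatment group and any reference groups given as rows
    (group, quantity, mean, sd, n).
    """
    t_eval = t_eval_week * HOURS_PER_WEEK

    def population_outputs(events) -> tuple[np.ndarray, np.ndarray]:
        nums, dias = [], []
        for sched in population.schedules:
            _, traj = run_model(
                spec, sched, params, (LINEAR_SPAN[0], t_eval), events=events
            )
            n, d = traj.at(t_eval)
            nums.append(n)
            dias.append(d)
        return np.array(nums), np.array(dias)

    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    groups["no_treatment"] = population_outputs(())
    for agent in agents:
        target = AGENT_TARGETS[agent]
        ev = (network.Event(time=LINEAR_SPAN[0], kind="ymax", target=target, scale=0.0),)
        groups[agent] = population_outputs(ev)

    rows = []
    ref_n, ref_d = groups["no_treatment"]
    for name, (nums, dias) in groups.items():
        row = {
            "group": name,
            "number_mean": nums.mean(),
            "number_sd": nums.std(ddof=1),
            "diameter_mean": dias.mean(),
            "diameter_sd": dias.std(ddof=1),
            "n": len(nums),
        }
        if name != "no_treatment":
            for label, vals, ref in (
                ("number", nums, ref_n),
                ("diameter", dias, ref_d),
            ):
                t, p = two_sample_ttest(vals, ref)
                row[f"{label}_t_vs_none"] = t
                row[f"{label}_p_vs_none"] = p
                row[f"{label}_stars_vs_none"] = significance_stars(p)
        if reference_groups is not None:
            for ref_row in reference_groups.itertuples(index=False):
                vals = nums if ref_row.quantity == "density" else dias
                t, p = ttest_from_stats(
                    vals.mean(),
                    vals.std(ddof=1),
                    len(vals),
                    ref_row.mean,
                    ref_row.sd,
                    ref_row.n,
                )
                row[f"p_vs_{ref_row.group}_{ref_row.quantity}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
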