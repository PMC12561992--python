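"""Fenestration number and diameter dynamics driven by the signaling network.

Number (dimensionless density scale) balances formation by relaxed actin
fibers against loss by stressed fibers,

    dN/dt = kform * Actin_r * |Nss1 - N|^nf - kloss * Actin_s * |Nss2 - N|^nf,

so the healthy (Nss1) and diseased (Nss2) levels are semi-stable fixed points
of their own terms.  Diameter (nm) is stressed by phosphorylated myosin light
chain and restored linearly,

    dD/dt = ks * (pMLC - pMLC0)^nf - kd * (D - D0).

The power on (pMLC - pMLC0) is evaluated sign-preservingly so transient
excursions below baseline remain defined for non-integer nf.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkTrajectory, SolverError

__all__ = [
    "FenestrationParams",
    "FenestrationTrajectory",
    "number_rhs",
    "diameter_rhs",
    "simulate_structure",
    "simulate_coupled",
    "diameter_closed_form",
]

DRIVER_SPECIES = ("Actin_s", "Actin_r", "pMLC")


@dataclass(frozen=True)
class FenestrationParams:
    """Structural rate constants and set points (best-fit defaults)."""

    kform: float = 1.01  # 1/h, fenestration formation rate
    kloss: float = 4.61  # 1/h, fenestration loss rate
    nf: float = 4.00  # shape factor
    yNumber_ss1: float = 7.00  # healthy steady-state number
    yNumber_ss2: float = 4.02  # diseased steady-state number
    ks: float = 65.9  # nm/h, diameter stress rate
    kd: float = 2.04  # 1/h, diameter restoration rate
    pMLC0: float = 0.0  # baseline normalized pMLC
    yDiameter0: float = 47.91  # nm, baseline diameter
    tau_pMLC: float = 400.0  # h, pMLC activation time constant

    def __post_init__(self) -> None:
        for name in ("kform", "kloss", "ks", "kd", "tau_pMLC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nf < 1:
            raise ValueError("nf must be >= 1")
        if not (self.yNumber_ss1 > self.yNumber_ss2 > 0):
            raise ValueError("need yNumber_ss1 > yNumber_ss2 > 0")
        if self.yDiameter0 <= 0:
            raise ValueError("yDiameter0 must be > 0")
        if not (0.0 <= self.pMLC0 <= 1.0):
            raise ValueError("pMLC0 must lie in [0, 1]")

    def replace(self, **kw) -> "FenestrationParams":
        return replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FenestrationParams":
        return cls(**json.loads(text))


@dataclass
class FenestrationTrajectory:
    """Time course of fenestration number and diameter (nm)."""

    t: np.ndarray
    number: np.ndarray
    diameter: np.ndarray

    def at(self, time: float) -> tuple[float, float]:
        return (
            float(np.interp(time, self.t, self.number)),
            float(np.interp(time, self.t, self.diameter)),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.t, "number": self.number, "diameter_nm": self.diameter}
        )


def _signed_power(x, p: float):
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.abs(x) ** p
    return out if out.ndim else float(out)


def number_rhs(
    y_number, actin_r, actin_s, params: FenestrationParams
):
    """d(number)/dt from relaxed (formation) and stressed (loss) actin activity."""
    return params.kform * actin_r * np.abs(
        params.yNumber_ss1 - y_number
    ) ** params.nf - params.kloss * actin_s * np.abs(
        params.yNumber_ss2 - y_number
    ) ** params.nf


def diameter_rhs(y_diameter, pmlc, params: FenestrationParams):
    """d(diameter)/dt (nm/h) from pMLC stress and linear restoration."""
    return params.ks * _signed_power(
        pmlc - params.pMLC0, params.nf
    ) - params.kd * (y_diameter - params.yDiameter0)


def diameter_closed_form(
    t, pmlc_held: float, params: FenestrationParams, y0: float | None = None
):
    """Analytic diameter under constant pMLC (for verification):
    D(t) = D0 + [(ks/kd)(p - p0)^nf - (D0 - y0)·0] (1 - e^(-kd t)) + (y0-D0)e^(-kd t)."""
    t = np.asarray(t, dtype=float)
    d0 = params.yDiameter0 if y0 is None else y0
    gain = (params.ks / params.kd) * _signed_power(
        pmlc_held - params.pMLC0, params.nf
    )
    return (
        params.yDiameter0
        + gain
        + (d0 - params.yDiameter0 - gain) * np.exp(-params.kd * t)
    )


def simulate_structure(
    drivers,
    params: FenestrationParams,
    y0_number: float | None = None,
    y0_diameter: float | None = None,
    t_span: tuple[float, float] | None = None,
    t_eval: np.ndarray | None = None,
    number_formation_only: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-6,
) -> FenestrationTrajectory:
    """Integrate the number/diameter ODEs driven by network trajectories.

    ``drivers`` is a :class:`NetworkTrajectory` containing Actin_s, Actin_r
    and pMLC (interpolated piecewise-linearly on its grid), or a dict mapping
    those names to callables t -> activity.  Initial values default to the
    healthy baselines (number 7.00, diameter 47.91 nm).
    ``number_formation_only`` drops the loss term (healthy-arm calibration).
    """
    if isinstance(drivers, NetworkTrajectory):
        missing = [s for s in DRIVER_SPECIES if s not in drivers.names]
        if missing:
            raise ValueError(f"driver species missing from trajectory: {missing}")
        fns = {s: drivers.interpolant(s) for s in DRIVER_SPECIES}
        if t_span is None:
            t_span = (float(drivers.t[0]), float(drivers.t[-1]))
        if t_eval is None:
            t_eval = drivers.t
    else:
        missing = [s for s in DRIVER_SPECIES if s not in drivers]
        if missing:
            raise ValueError(f"driver species missing: {missing}")
        fns = drivers
        if t_span is None:
            raise ValueError("t_span required with callable drivers")
        if t_eval is None:
            t_eval = np.linspace(*t_span, 500)

    n0 = params.yNumber_ss1 if y0_number is None else float(y0_number)
    d0 = params.yDiameter0 if y0_diameter is None else float(y0_diameter)

    a_r, a_s, pm = fns["Actin_r"], fns["Actin_s"], fns["pMLC"]

    def rhs(t: float, y: np.ndarray) -> list[float]:
        num, dia = y
        dn = params.kform * float(a_r(t)) * abs(params.yNumber_ss1 - num) ** params.nf
        if not number_formation_only:
            dn -= (
                params.kloss
                * float(a_s(t))
                * abs(params.yNumber_ss2 - num) ** params.nf
            )
        dd = params.ks * _signed_power(
            float(pm(t)) - params.pMLC0, params.nf
        ) - params.kd * (dia - params.yDiameter0)
        return [dn, dd]

    sol = solve_ivp(
        rhs,
        t_span,
        [n0, d0],
        method="LSODA",
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"structure integration failed: {sol.message}")
    return FenestrationTrajectory(t=sol.t, number=sol.y[0], diameter=sol.y[1])


def simulate_coupled(
    spec,
    glucose,
    params: FenestrationParams,
    t_span: tuple[float, float] = (336.0, 3360.0),
    y0_number: float | None = None,
    y0_diameter: float | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    grid_h: float = 6.0,
) -> tuple[NetworkTrajectory, FenestrationTrajectory]:
    """Integrate the network and the structure ODEs as one joint system.

    Cross-check for the driven mode: both must agree to solver tolerance
    since the structure states do not feed back into the network.
    """
    from .network import _Compiled

    comp = _Compiled(spec)
    weight_fn = glucose if callable(glucose) else glucose.weight
    net_rhs = comp.rhs(weight_fn)
    i_s = [s.id for s in spec.species].index("Actin_s")
    i_r = [s.id for s in spec.species].index("Actin_r")
    i_p = [s.id for s in spec.species].index("pMLC")
    n_net = len(spec.species)

    def rhs(t, y):
        dnet = net_rhs(t, y[:n_net])
        num, dia = y[n_net], y[n_net + 1]
        dn = number_rhs(num, max(y[i_r], 0.0), max(y[i_s], 0.0), params)
        dd = diameter_rhs(dia, y[i_p], params)
        return np.concatenate([dnet, [dn, dd]])

    y0 = np.concatenate(
        [
            [s.y0 for s in spec.species],
            [
                params.yNumber_ss1 if y0_number is None else y0_number,
                params.yDiameter0 if y0_diameter is None else y0_diameter,
            ],
        ]
    )
    t_eval = np.arange(t_span[0], t_span[1] + 0.5 * grid_h, grid_h)
    t_eval[-1] = min(t_eval[-1], t_span[1])
    sol = solve_ivp(
        rhs, t_span, y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SolverError(f"coupled integration failed: {sol.message}")
    net = NetworkTrajectory(
        t=sol.t, y=sol.y[:n_net], names=tuple(s.id for s in spec.species)
    )
    struct = FenestrationTrajectory(
        t=sol.t, number=sol.y[n_net], diameter=sol.y[n_net + 1]
    )
    return net, struct
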