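"""Deterministic 1D mean-field dynamics of the carried cargo.

The reduced equations of motion for the cargo position x and velocity v are

    dx/dt = v
    dv/dt = q(x, v)
    q(x, v) = k_c [ n sinh(v/f_ind) - 2 (v + g tanh(x/eps)) cosh(v/f_ind) ]
              - v (g/eps) sech^2(x/eps)

The sinh term is the self-amplifying tug-of-war of the uninformed pullers,
the cosh term relaxes the velocity toward the group consensus, and the tanh
profile is the restoring pull of the informed ants toward the opening at
x = 0, regularized over a length eps ~ cargo radius.

In the eps -> 0 limit the restoring profile becomes g*sign(x) and the sech^2
term concentrates into an impulse at the origin: a cargo crossing the opening
with speed u loses exactly 2g of velocity if u > 2g, and is reflected
(cannot cross) if u <= 2g.  The piecewise integrator implements the smooth
half-space fields with event-located crossings applying this rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import InvalidParameterError, RescaledParams
from .trajectory import Trajectory

__all__ = [
    "PhasePoint",
    "NullclineBranch",
    "restoring_force",
    "q_eval",
    "jacobian_origin",
    "integrate",
    "half_space_excursion",
    "nullcline_branches",
    "nullcline_roots",
    "v_window",
]


@dataclass(frozen=True)
class PhasePoint:
    x: float
    v: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.v)):
            raise ValueError("phase point must be finite")


@dataclass
class NullclineBranch:
    """One continuity-assembled solution branch of q(x, v) = 0."""

    x: np.ndarray
    v: np.ndarray
    label: str = ""


def restoring_force(
    x,
    g: float,
    eps: float = 0.0,
    mode: Literal["tanh", "sign", "projection2d"] = "tanh",
    r: float = 1.0,
):
    """Restoring force (per gamma, velocity units) of the informed ants.

    tanh: g*tanh(x/eps).  sign: g*sign(x) with sign(0) = 0.  projection2d:
    x-component of a unit pull from a cargo center at height ``r`` above the
    wall toward the opening at the origin, scaled by g — the geometric profile
    the tanh regularization approximates when eps ~ r.
    """
    x = np.asarray(x, dtype=float)
    if mode == "tanh":
        if eps <= 0:
            raise InvalidParameterError("tanh mode requires eps > 0; use mode='sign'")
        out = g * np.tanh(x / eps)
    elif mode == "sign":
        out = g * np.sign(x)
    elif mode == "projection2d":
        if r <= 0:
            raise InvalidParameterError("projection2d mode requires r > 0")
        out = g * x / np.sqrt(x * x + r * r)
    else:
        raise InvalidParameterError(f"unknown restoring mode {mode!r}")
    return out if out.ndim else float(out)


def q_eval(pt: PhasePoint | tuple, rp: RescaledParams) -> float:
    """Acceleration q(x, v) of the reduced equations of motion.

    For eps = 0 the piecewise field is evaluated: sign(x) replaces tanh and
    the sech^2 impulse (supported only at x = 0) is dropped.
    """
    x, v = (pt.x, pt.v) if isinstance(pt, PhasePoint) else pt
    n, g, f, eps, k_c = rp.n, rp.g, rp.f_ind, rp.eps, rp.k_c
    u = v / f
    if eps > 0:
        restoring = g * math.tanh(x / eps)
        impulse = v * (g / eps) / math.cosh(x / eps) ** 2
    else:
        restoring = g * (0.0 if x == 0 else math.copysign(1.0, x))
        impulse = 0.0
    return k_c * (n * math.sinh(u) - 2.0 * (v + restoring) * math.cosh(u)) - impulse


def jacobian_origin(rp: RescaledParams) -> np.ndarray:
    """Linearization of (dx/dt, dv/dt) = (v, q) at the fixed point (0, 0).

    Only defined for eps > 0; the eps = 0 field is discontinuous at x = 0 and
    origin stability there is assessed by simulation of the piecewise flow.
    """
    if rp.eps <= 0:
        raise InvalidParameterError(
            "jacobian_origin requires eps > 0 (discontinuous field at eps = 0)"
        )
    dq_dx = -2.0 * rp.k_c * rp.g / rp.eps
    dq_dv = rp.k_c * (rp.n / rp.f_ind - 2.0) - rp.g / rp.eps
    return np.array([[0.0, 1.0], [dq_dx, dq_dv]])


def v_window(rp: RescaledParams) -> float:
    """Velocity window bound |v| <= n + g + 5*f_ind containing all nullcline roots."""
    return rp.n + rp.g + 5.0 * rp.f_ind


def _smooth_rhs(rp: RescaledParams):
    n, g, f, eps, k_c = rp.n, rp.g, rp.f_ind, rp.eps, rp.k_c

    def rhs(t, y):
        x, v = y
        u = v / f
        th = math.tanh(x / eps)
        sech2 = 1.0 - th * th
        dv = k_c * (n * math.sinh(u) - 2.0 * (v + g * th) * math.cosh(u)) - v * (
            g / eps
        ) * sech2
        return (v, dv)

    return rhs


def _half_rhs(rp: RescaledParams, s: float):
    # smooth field inside the half-space sign(x) = s, for the eps = 0 system
    n, g, f, k_c = rp.n, rp.g, rp.f_ind, rp.k_c
    gs = g * s

    def rhs(t, y):
        v = y[1]
        u = v / f
        return (v, k_c * (n * math.sinh(u) - 2.0 * (v + gs) * math.cosh(u)))

    return rhs


_RTOL, _ATOL = 1e-8, 1e-10


def half_space_excursion(
    rp: RescaledParams,
    v0: float,
    x_escape: float = 20.0,
    t_max: float = 200.0,
):
    """Integrate one excursion into the half-space x > 0 of the eps = 0 field.

    Starts at (x, v) = (0+, v0) with v0 > 0 and runs the smooth half-space
    field (restoring -g) until the trajectory returns to x = 0, escapes past
    ``x_escape``, or times out.  Returns (outcome, value, sol) where outcome is
    'return' (value = |v| at return), 'escape' (value = terminal v), or
    'timeout'.  Excursions in x < 0 follow by the (x, v) -> (-x, -v) symmetry.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")

    def hit_origin(t, y):
        return y[0]

    hit_origin.terminal = True
    hit_origin.direction = -1.0

    def hit_escape(t, y):
        return y[0] - x_escape

    hit_escape.terminal = True
    hit_escape.direction = 1.0

    sol = solve_ivp(
        _half_rhs(rp, +1.0),
        (0.0, t_max),
        (1e-12, v0),
        method="LSODA",
        events=(hit_origin, hit_escape),
        rtol=_RTOL,
        atol=_ATOL,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"excursion integration failed: {sol.message}")
    if sol.t_events[0].size:
        return "return", abs(sol.y_events[0][0][1]), sol
    if sol.t_events[1].size:
        return "escape", sol.y_events[1][0][1], sol
    return "timeout", sol.y[1, -1], sol


def integrate(
    rp: RescaledParams,
    ic: PhasePoint | tuple,
    T: float,
    max_step: float | None = None,
    dt_out: float = 0.01,
    x_escape: float = 50.0,
) -> Trajectory:
    """Integrate the mean-field equations from ``ic`` for duration ``T``.

    eps > 0: adaptive stiff-capable integration of the smooth field.
    eps = 0: piecewise integration with event-located x = 0 crossings; a
    crossing at speed u > 2g transmits with speed u - 2g, a crossing at
    u <= 2g reflects the cargo, which marks capture by the convergent mode
    (meta['converged'] = True) and ends the run at the origin.

    Trajectories that pass ``x_escape`` are flagged meta['escaped'] = True
    (unbounded ballistic motion of the low-individuality phase).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    x0, v0 = (ic.x, ic.v) if isinstance(ic, PhasePoint) else map(float, ic)
    meta = {"kind": "meanfield", "rp": rp, "converged": False, "escaped": False}

    if rp.eps > 0:
        sol = solve_ivp(
            _smooth_rhs(rp),
            (0.0, T),
            (x0, v0),
            method="LSODA",
            rtol=_RTOL,
            atol=_ATOL,
            dense_output=True,
            max_step=max_step or np.inf,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1]:.3g}, state={sol.y[:, -1]}: "
                f"{sol.message}"
            )
        t = np.arange(0.0, T + 0.5 * dt_out, dt_out)
        t = t[t <= sol.t[-1]]
        y = sol.sol(t)
        return Trajectory(t=t, x=y[0], v=y[1], meta=meta)

    # eps = 0: piecewise field with crossing rule at x = 0
    if x0 == 0.0 and v0 == 0.0:
        t = np.arange(0.0, T + 0.5 * dt_out, dt_out)
        return Trajectory(t=t, x=np.zeros_like(t), v=np.zeros_like(t), meta=meta)

    ts: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    vs: list[np.ndarray] = []
    t_now, x_now, v_now = 0.0, x0, v0
    two_g = 2.0 * rp.g
    # side of the current smooth segment
    s = math.copysign(1.0, x_now) if x_now != 0 else math.copysign(1.0, v_now)

    def crossing(t, y):
        return y[0]

    crossing.terminal = True

    def escape(t, y):
        return abs(y[0]) - x_escape

    escape.terminal = True
    escape.direction = 1.0

    while t_now < T:
        crossing.direction = -s
        sol = solve_ivp(
            _half_rhs(rp, s),
            (t_now, T),
            (x_now, v_now),
            method="LSODA",
            events=(crossing, escape),
            rtol=_RTOL,
            atol=_ATOL,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1]:.3g}, state={sol.y[:, -1]}: "
                f"{sol.message}"
            )
        seg_end = sol.t[-1]
        tt = np.arange(t_now, seg_end, dt_out)
        yy = sol.sol(tt) if tt.size else np.empty((2, 0))
        ts.append(tt)
        xs.append(yy[0] if tt.size else np.empty(0))
        vs.append(yy[1] if tt.size else np.empty(0))

        if sol.t_events[1].size:  # escaped
            meta["escaped"] = True
            ts.append(np.array([seg_end]))
            xs.append(np.array([sol.y[0, -1]]))
            vs.append(np.array([sol.y[1, -1]]))
            break
        if not sol.t_events[0].size:  # ran to T
            ts.append(np.array([seg_end]))
            xs.append(np.array([sol.y[0, -1]]))
            vs.append(np.array([sol.y[1, -1]]))
            break

        t_now = sol.t_events[0][0]
        u = sol.y_events[0][0][1]  # velocity at the crossing, sign = -s
        if abs(u) > two_g:
            v_now = u - two_g * math.copysign(1.0, u)
            x_now = 0.0
            s = -s
            ts.append(np.array([t_now]))
            xs.append(np.array([0.0]))
            vs.append(np.array([v_now]))
        else:
            # reflected by the impulse at the opening: convergent capture
            meta["converged"] = True
            ts.append(np.array([t_now]))
            xs.append(np.array([0.0]))
            vs.append(np.array([0.0]))
            break

    t = np.concatenate(ts)
    x = np.concatenate(xs)
    v = np.concatenate(vs)
    keep = np.concatenate(([True], np.diff(t) > 0))
    return Trajectory(t=t[keep], x=x[keep], v=v[keep], meta=meta)


def nullcline_roots(x: float, rp: RescaledParams, n_scan: int = 400) -> list[float]:
    """All real roots v of q(x, v) = 0 at fixed x, by sign-bracketed search."""
    vmax = v_window(rp)
    grid = np.linspace(-vmax, vmax, n_scan)
    qs = np.array([q_eval((x, v), rp) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        a, b = qs[i], qs[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(
                brentq(lambda v: q_eval((x, v), rp), grid[i], grid[i + 1], xtol=1e-12)
            )
    if qs[-1] == 0.0:
        roots.append(grid[-1])
    return roots


def nullcline_branches(
    rp: RescaledParams, x_grid: np.ndarray, n_scan: int = 400
) -> list[NullclineBranch]:
    """Solution branches of q(x, v) = 0 over ``x_grid``, assembled by continuity.

    Roots at consecutive x values are chained to the nearest open branch;
    branch changes in root count open/close branches.  Labels record the
    ordering (lower/middle/upper) of each branch at its first point.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    open_branches: list[tuple[list[float], list[float]]] = []
    done: list[tuple[list[float], list[float]]] = []
    jump_tol = 0.25 * v_window(rp)
    for x in x_grid:
        roots = sorted(nullcline_roots(x, rp, n_scan=n_scan))
        unclaimed = list(roots)
        still_open = []
        for bx, bv in open_branches:
            if unclaimed:
                j = int(np.argmin([abs(r - bv[-1]) for r in unclaimed]))
                if abs(unclaimed[j] - bv[-1]) < jump_tol:
                    bx.append(x)
                    bv.append(unclaimed.pop(j))
                    still_open.append((bx, bv))
                    continue
            done.append((bx, bv))
        open_branches = still_open
        for r in unclaimed:
            open_branches.append(([x], [r]))
    done.extend(open_branches)
    branches = []
    for k, (bx, bv) in enumerate(sorted(done, key=lambda b: b[1][0])):
        branches.append(
            NullclineBranch(x=np.array(bx), v=np.array(bv), label=f"branch_{k}")
        )
    return branches
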