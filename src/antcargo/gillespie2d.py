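"""Stochastic simulation of a ring cargo carried along a wall with an opening.

The cargo is a rigid ring of radius ``r`` with ``n_max`` binding sites evenly
spaced around its perimeter.  Each occupied site holds a puller (pulls with
force f0 along its body-axis unit vector), a lifter (no force), or an
informed ant (pulls with force f0 from the cargo center toward the center of
the opening).  The wall lies along y = 0 with the opening centered at x = 0;
the transport region is y > 0 and the ring touches the wall at y = r.  The
opening (width 0.5 cm) is narrower than any cargo, so the ring can slide
along the wall but never pass through.

Event kinetics (exact Gillespie chain): informed attachment to empty sites
(k_on), uninformed detachment (k_off), force-dependent role switching (k_c),
informed -> uninformed conversion (k_forget) with the new role drawn from the
role-switching equilibrium, and re-orientation of pullers (k_orient), which
relocates a puller to the empty site whose pulling direction best aligns
with the sensed force.  Each site's pulling axis is pinned outward radial by
the grip geometry — this is what bounds the persistence of the collective
pull, exactly as the fixed front/back pools do in the 1D model.  Motion is
overdamped (v = f_tot/gamma) with sliding contact at the wall; only
translation is simulated — re-orientation along the ring stands in for
rotation of the cargo body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import InvalidParameterError, PhysicalParams, params_2d
from .trajectory import Trajectory

__all__ = [
    "EMPTY", "PULLER", "LIFTER", "INFORMED",
    "CargoState2D",
    "build_cargo",
    "total_force_2d",
    "sensed_force",
    "rates_2d",
    "apply_event_2d",
    "advance_and_constrain",
    "run_2d",
]

EMPTY, PULLER, LIFTER, INFORMED = 0, 1, 2, 3


@dataclass
class CargoState2D:
    """Ring-cargo state: center kinematics plus per-site role and body axis."""

    center: np.ndarray            # (x, y) in cm
    velocity: np.ndarray          # (vx, vy) in cm/s
    r: float
    angles: np.ndarray            # fixed site angles on the ring
    occupancy: np.ndarray         # int codes per site
    p: np.ndarray                 # (n_max, 2) body-axis unit vectors
    t: float = 0.0

    @property
    def n_max(self) -> int:
        return len(self.angles)

    def counts(self) -> tuple[int, int, int, int]:
        occ = self.occupancy
        return (
            int(np.sum(occ == PULLER)),
            int(np.sum(occ == LIFTER)),
            int(np.sum(occ == INFORMED)),
            int(np.sum(occ == EMPTY)),
        )

    def check(self) -> None:
        norms = np.linalg.norm(self.p, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("body axes must be unit vectors")
        if self.center[1] < self.r - 1e-9:
            raise ValueError("cargo penetrates the wall")


def build_cargo(r: float, n_max: int) -> CargoState2D:
    """Empty ring cargo touching the wall at the opening (center at (0, r)).

    Sites sit at angles 2*pi*k/n_max with body axes initially outward radial.
    """
    if n_max < 1:
        raise InvalidParameterError("n_max must be at least 1")
    angles = 2.0 * np.pi * np.arange(n_max) / n_max
    p = np.column_stack([np.cos(angles), np.sin(angles)])
    return CargoState2D(
        center=np.array([0.0, r]),
        velocity=np.zeros(2),
        r=r,
        angles=angles,
        occupancy=np.zeros(n_max, dtype=np.int8),
        p=p,
    )


def total_force_2d(state: CargoState2D, params: PhysicalParams) -> np.ndarray:
    """Vector sum of puller forces and the informed pull toward the opening."""
    pullers = state.occupancy == PULLER
    f = state.p[pullers].sum(axis=0) if pullers.any() else np.zeros(2)
    n_inf = int(np.sum(state.occupancy == INFORMED))
    if n_inf:
        d = -state.center
        norm = np.linalg.norm(d)
        if norm > 0:
            f = f + n_inf * d / norm
    return params.f0 * f


def sensed_force(state: CargoState2D, params: PhysicalParams) -> np.ndarray:
    """Force the carriers respond to: total force net of the wall reaction.

    In wall contact the normal reaction cancels any force component pressing
    into the wall, so the force transmitted to motion (gamma*v, the quantity
    the overdamped 1D reduction identifies with the sensed force) is the
    tangential remainder.  Role switching, the equilibrium role draw, and
    re-orientation all use this force; away from the wall it equals the raw
    force sum.
    """
    f = total_force_2d(state, params)
    if state.center[1] <= state.r + 1e-12 and f[1] < 0:
        f = f.copy()
        f[1] = 0.0
    return f


def _switch_rates(state: CargoState2D, params: PhysicalParams, f_tot: np.ndarray):
    """Per-site role-switch rates (zero on empty/informed sites)."""
    proj = state.p @ f_tot / params.F_ind
    rates = np.zeros(state.n_max)
    lifters = state.occupancy == LIFTER
    pullers = state.occupancy == PULLER
    rates[lifters] = params.k_c * np.exp(proj[lifters])
    rates[pullers] = params.k_c * np.exp(-proj[pullers])
    return rates


def rates_2d(state: CargoState2D, params: PhysicalParams) -> dict:
    """Aggregate event rates for the current state."""
    n_p, n_l, n_inf, n_empty = state.counts()
    f_tot = sensed_force(state, params)
    switch = _switch_rates(state, params, f_tot)
    rates = {
        "attach": params.k_on * n_empty,
        "detach": params.k_off * (n_p + n_l),
        "switch": float(switch.sum()),
        "forget": params.k_forget * n_inf,
        "orient": params.k_orient * n_p,
    }
    rates["_switch_per_site"] = switch
    rates["_f_tot"] = f_tot
    return rates


def _equilibrium_role(proj_over_F: float, u: float) -> int:
    N_p = 1.0 / (1.0 + math.exp(-2.0 * proj_over_F))
    return PULLER if u < N_p else LIFTER


def apply_event_2d(
    state: CargoState2D,
    event: str,
    params: PhysicalParams,
    rng: np.random.Generator,
    rates: dict | None = None,
) -> CargoState2D:
    """Apply one drawn event in place and return the state.

    attach: a uniformly chosen empty site gains an informed ant.  detach: a
    uniformly chosen uninformed ant leaves.  switch: a site chosen with
    probability proportional to its role-switch rate flips role.  forget: a
    uniformly chosen informed ant becomes uninformed with the role drawn from
    the role-switching equilibrium at its site.  orient: a uniformly chosen
    puller relocates to the empty site best aligned with the sensed force
    (no-op at zero force, with no empty site, or when no site improves
    alignment).
    """
    if rates is None:
        rates = rates_2d(state, params)
    occ = state.occupancy
    f_tot = rates["_f_tot"]
    if event == "attach":
        empties = np.nonzero(occ == EMPTY)[0]
        if not empties.size:
            raise RuntimeError("attach drawn with no empty site")
        occ[rng.choice(empties)] = INFORMED
    elif event == "detach":
        uninfo = np.nonzero((occ == PULLER) | (occ == LIFTER))[0]
        if not uninfo.size:
            raise RuntimeError("detach drawn with no uninformed ant")
        occ[rng.choice(uninfo)] = EMPTY
    elif event == "switch":
        per_site = rates["_switch_per_site"]
        tot = per_site.sum()
        if tot <= 0:
            raise RuntimeError("switch drawn with zero switch rate")
        i = int(np.searchsorted(np.cumsum(per_site), rng.random() * tot))
        occ[i] = PULLER if occ[i] == LIFTER else LIFTER
    elif event == "forget":
        informed = np.nonzero(occ == INFORMED)[0]
        if not informed.size:
            raise RuntimeError("forget drawn with no informed ant")
        i = int(rng.choice(informed))
        proj = float(state.p[i] @ f_tot) / params.F_ind
        occ[i] = _equilibrium_role(proj, rng.random())
    elif event == "orient":
        pullers = np.nonzero(occ == PULLER)[0]
        if not pullers.size:
            raise RuntimeError("orient drawn with no puller")
        norm = np.linalg.norm(f_tot)
        empties = np.nonzero(occ == EMPTY)[0]
        if norm > 0 and empties.size:
            i = int(rng.choice(pullers))
            align = state.p[empties] @ (f_tot / norm)
            j = int(empties[np.argmax(align)])
            if align.max() > float(state.p[i] @ (f_tot / norm)):
                occ[i] = EMPTY
                occ[j] = PULLER
    else:
        raise ValueError(f"unknown event {event!r}")
    return state


def advance_and_constrain(state: CargoState2D, dt: float) -> CargoState2D:
    """Ballistic advance over dt with sliding contact at the wall.

    The wall (y = 0, contact at center height y = r) removes the normal
    component of displacement and velocity; the opening is narrower than the
    cargo, so no passage is possible and contact holds across it.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    state.center = state.center + state.velocity * dt
    if state.center[1] < state.r:
        state.center[1] = state.r
        if state.velocity[1] < 0:
            state.velocity = state.velocity.copy()
            state.velocity[1] = 0.0
    return state


def _refresh_velocity(state: CargoState2D, params: PhysicalParams) -> np.ndarray:
    f_tot = total_force_2d(state, params)
    v = f_tot / params.gamma
    if state.center[1] <= state.r + 1e-12 and v[1] < 0:
        v = v.copy()
        v[1] = 0.0
    state.velocity = v
    return f_tot


def run_2d(
    r: float,
    params: PhysicalParams | None = None,
    T: float = 100.0,
    seed: int = 0,
    initial_state: CargoState2D | None = None,
) -> Trajectory:
    """Simulate the ring cargo of radius ``r`` for ``T`` seconds.

    ``params`` defaults to the standard parameter column for that radius.
    The initial occupancy is drawn at the stationary population means; the
    cargo starts touching the wall at the opening.  Returns an event-time
    trajectory with center kinematics and population counts.
    """
    if params is None:
        params = params_2d(r)
    if params.n_tot + params.G > params.n_max + 1e-9:
        raise InvalidParameterError("mean carrier numbers exceed the site count")
    rng = np.random.default_rng(seed)
    state = initial_state if initial_state is not None else build_cargo(r, params.n_max)
    if initial_state is None:
        # stationary occupancy means of the attach/forget/detach kinetics
        k1 = params.k_forget / params.k_off
        k2 = params.k_forget / params.k_on
        denom = 1.0 + k1 + k2
        n_u = int(round(k1 / denom * params.n_max))
        n_i = int(round(1.0 / denom * params.n_max))
        sites = rng.permutation(params.n_max)
        for j, i in enumerate(sites[:n_u]):
            state.occupancy[i] = PULLER if j % 2 else LIFTER
        for i in sites[n_u : n_u + n_i]:
            state.occupancy[i] = INFORMED
    _refresh_velocity(state, params)

    ts, xs, ys, vxs, vys, nps, nls, nis = ([] for _ in range(8))

    def record() -> None:
        n_p, n_l, n_inf, _ = state.counts()
        ts.append(state.t)
        xs.append(state.center[0])
        ys.append(state.center[1])
        vxs.append(state.velocity[0])
        vys.append(state.velocity[1])
        nps.append(n_p)
        nls.append(n_l)
        nis.append(n_inf)

    record()
    while state.t < T:
        rates = rates_2d(state, params)
        R_tot = rates["attach"] + rates["detach"] + rates["switch"] + rates[
            "forget"
        ] + rates["orient"]
        if R_tot <= 0:
            raise RuntimeError("absorbing state reached: total event rate is zero")
        dt = -math.log(1.0 - rng.random()) / R_tot
        advance_and_constrain(state, dt)
        state.t += dt
        target = rng.random() * R_tot
        acc = 0.0
        for name in ("attach", "detach", "switch", "forget", "orient"):
            acc += rates[name]
            if target < acc:
                apply_event_2d(state, name, params, rng, rates=rates)
                break
        _refresh_velocity(state, params)
        record()
    state.check()
    t = np.asarray(ts)
    keep = np.concatenate(([True], np.diff(t) > 0))
    return Trajectory(
        t=t[keep],
        x=np.asarray(xs)[keep],
        v=np.asarray(vxs)[keep],
        y=np.asarray(ys)[keep],
        vy=np.asarray(vys)[keep],
        n_pullers=np.asarray(nps)[keep],
        n_lifters=np.asarray(nls)[keep],
        n_informed=np.asarray(nis)[keep],
        meta={"kind": "gillespie2d", "r": r, "seed": seed, "params": params},
    )
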