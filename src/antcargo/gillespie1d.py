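"""Exact stochastic simulation of the 1D cargo under three kinetic schemes.

The cargo is a point particle on a line with ``n_max`` binding sites split
equally between a front (+x facing) and a back (-x facing) pool.  Uninformed
ants occupying sites switch between puller and lifter roles at force-dependent
rates; the total force converts instantaneously to velocity (overdamped,
v = f_tot/gamma).  The restoring pull of the informed ants points toward the
opening at x = 0.

Schemes (increasing noise content):

1. ``role_switch`` — fixed, fully-occupied uninformed population; constant
   informed force G.
2. ``attach_detach`` — uninformed ants additionally attach (k_on per empty
   site) and detach (k_off per ant); G constant.
3. ``informed`` — newly attached ants are informed pullers occupying sites;
   they forget (become uninformed) at k_forget, so the restoring force
   fluctuates around its mean.

The simulation is an exact Gillespie chain: exponential waiting times with
the total event rate, event class chosen by cumulative-rate comparison in the
order attach, detach, role-switch, forget; the cargo drifts ballistically
between events and the velocity is recomputed after every event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import InvalidParameterError, PhysicalParams
from .trajectory import Trajectory

__all__ = [
    "CargoState1D",
    "SCHEMES",
    "role_switch_rates",
    "total_force_1d",
    "removal_role_assignment",
    "gillespie_step",
    "run_scheme",
]

SCHEMES = {1: "role_switch", 2: "attach_detach", 3: "informed"}
_SCHEME_IDS = {v: k for k, v in SCHEMES.items()}


@dataclass
class CargoState1D:
    """Point-cargo state: position, velocity, and per-side site occupancies."""

    x: float = 0.0
    v: float = 0.0
    t: float = 0.0
    n_p_front: int = 0
    n_p_back: int = 0
    n_l_front: int = 0
    n_l_back: int = 0
    n_inf_front: int = 0
    n_inf_back: int = 0
    n_max: int = 0

    @property
    def n_inf(self) -> int:
        return self.n_inf_front + self.n_inf_back

    @property
    def n_uninformed(self) -> int:
        return self.n_p_front + self.n_p_back + self.n_l_front + self.n_l_back

    @property
    def n_empty(self) -> int:
        return self.n_max - self.n_uninformed - self.n_inf

    def check(self) -> None:
        counts = (
            self.n_p_front, self.n_p_back, self.n_l_front, self.n_l_back,
            self.n_inf_front, self.n_inf_back,
        )
        if any(c < 0 for c in counts) or self.n_empty < 0:
            raise ValueError(f"invalid occupancy {counts}, n_max={self.n_max}")


def role_switch_rates(
    force_projection: float, F_ind: float, k_c: float
) -> tuple[float, float]:
    """Per-ant (lifter->puller, puller->lifter) rates for projection f_tot.p_i.

    k_c exp(+proj/F_ind) and k_c exp(-proj/F_ind): an ant aligned with the
    total force is recruited into pulling and rarely quits.
    """
    if F_ind <= 0:
        raise InvalidParameterError("F_ind must be positive")
    e = math.exp(force_projection / F_ind)
    return k_c * e, k_c / e


def _restoring_profile(x: float, mode: str, eps: float) -> float:
    if mode == "sign":
        return 0.0 if x == 0 else math.copysign(1.0, x)
    if mode == "tanh":
        if eps <= 0:
            raise InvalidParameterError("tanh restoring requires eps > 0")
        return math.tanh(x / eps)
    raise InvalidParameterError(f"unknown restoring mode {mode!r}")


def total_force_1d(
    state: CargoState1D,
    f0: float,
    G_effective: float,
    restoring_mode: str = "sign",
    eps: float = 0.0,
) -> float:
    """Net force on the cargo: uninformed tug-of-war minus informed restoring.

    f_tot = f0 [ (n_p_front - n_p_back) - G_eff * s(x) ] with s the sign or
    tanh profile; the lifter friction term is neglected (cargo fully lifted).
    """
    s = _restoring_profile(state.x, restoring_mode, eps)
    return f0 * ((state.n_p_front - state.n_p_back) - G_effective * s)


def removal_role_assignment(
    force_projection: float, F_ind: float, u: float
) -> str:
    """Role drawn from the role-switching equilibrium at one site.

    The stationary puller probability is N_p = 1/(1+exp(-2 proj/F_ind));
    returns 'puller' iff the uniform draw u < N_p.
    """
    N_p = 1.0 / (1.0 + math.exp(-2.0 * force_projection / F_ind))
    return "puller" if u < N_p else "lifter"


class _Sim:
    """Mutable simulation core shared by gillespie_step and run_scheme."""

    def __init__(
        self,
        scheme: str,
        p: PhysicalParams,
        restoring_mode: str = "sign",
        eps: float = 0.0,
        freeze_position: bool = False,
        state: CargoState1D | None = None,
    ):
        if scheme in _SCHEME_IDS:
            pass
        elif scheme in SCHEMES:  # numeric id
            scheme = SCHEMES[scheme]
        else:
            raise InvalidParameterError(f"unknown scheme {scheme!r}")
        self.scheme = scheme
        self.p = p
        self.restoring_mode = restoring_mode
        self.eps = eps
        self.freeze_position = freeze_position
        if p.n_tot > p.n_max:
            raise InvalidParameterError("n_tot cannot exceed n_max")
        if p.n_max % 2:
            raise InvalidParameterError("n_max must be even (front/back pools)")
        self.cap = p.n_max // 2
        self.state = state if state is not None else self._initial_state()
        self.state.check()
        self._refresh_force()

    def _initial_state(self) -> CargoState1D:
        p = self.p
        if self.scheme == "role_switch":
            n_u, n_i = int(round(p.n_tot)), 0
        elif self.scheme == "attach_detach":
            P_u = p.k_on / (p.k_on + p.k_off)
            n_u, n_i = int(round(P_u * p.n_max)), 0
        else:
            k1, k2 = p.k_forget / p.k_off, p.k_forget / p.k_on
            denom = 1.0 + k1 + k2
            n_u = int(round(k1 / denom * p.n_max))
            n_i = int(round(1.0 / denom * p.n_max))
        q, r = divmod(n_u, 4)  # equal puller/lifter split on both sides
        iq, ir = divmod(n_i, 2)
        return CargoState1D(
            n_p_front=q, n_l_front=q + r // 2,
            n_p_back=q, n_l_back=q + r - r // 2,
            n_inf_front=iq + ir, n_inf_back=iq,
            n_max=p.n_max,
        )

    def _G_effective(self) -> float:
        return self.state.n_inf if self.scheme == "informed" else self.p.G

    def _refresh_force(self) -> None:
        self.f_tot = total_force_1d(
            self.state, self.p.f0, self._G_effective(), self.restoring_mode, self.eps
        )
        self.state.v = self.f_tot / self.p.gamma

    def rates(self) -> dict[str, float]:
        p, st = self.p, self.state
        phi = math.exp(self.f_tot / p.F_ind)
        r = {
            "attach": 0.0,
            "detach": 0.0,
            "switch_lf": st.n_l_front * p.k_c * phi,      # front lifter -> puller
            "switch_pf": st.n_p_front * p.k_c / phi,      # front puller -> lifter
            "switch_lb": st.n_l_back * p.k_c / phi,       # back lifter -> puller
            "switch_pb": st.n_p_back * p.k_c * phi,       # back puller -> lifter
            "forget": 0.0,
        }
        if self.scheme != "role_switch":
            r["attach"] = p.k_on * st.n_empty
            r["detach"] = p.k_off * st.n_uninformed
        if self.scheme == "informed":
            r["forget"] = p.k_forget * st.n_inf
        return r

    # --- event applications ------------------------------------------------
    def _side_projection(self, front: bool) -> float:
        return self.f_tot if front else -self.f_tot

    def _empty_on(self, front: bool) -> int:
        st = self.state
        if front:
            return self.cap - st.n_p_front - st.n_l_front - st.n_inf_front
        return self.cap - st.n_p_back - st.n_l_back - st.n_inf_back

    def _choose_side(self, w_front: float, w_back: float, rng) -> bool:
        tot = w_front + w_back
        return rng.random() * tot < w_front

    def apply(self, event: str, rng) -> None:
        st, p = self.state, self.p
        if event == "attach":
            front = self._choose_side(self._empty_on(True), self._empty_on(False), rng)
            if self.scheme == "informed":
                if front:
                    st.n_inf_front += 1
                else:
                    st.n_inf_back += 1
            else:
                role = removal_role_assignment(
                    self._side_projection(front), p.F_ind, rng.random()
                )
                self._add_uninformed(front, role)
        elif event == "detach":
            front = self._choose_side(
                st.n_p_front + st.n_l_front, st.n_p_back + st.n_l_back, rng
            )
            role = removal_role_assignment(
                self._side_projection(front), p.F_ind, rng.random()
            )
            self._remove_uninformed(front, role)
        elif event == "forget":
            front = self._choose_side(st.n_inf_front, st.n_inf_back, rng)
            if front:
                st.n_inf_front -= 1
            else:
                st.n_inf_back -= 1
            role = removal_role_assignment(
                self._side_projection(front), p.F_ind, rng.random()
            )
            self._add_uninformed(front, role)
        elif event == "switch_lf":
            st.n_l_front -= 1
            st.n_p_front += 1
        elif event == "switch_pf":
            st.n_p_front -= 1
            st.n_l_front += 1
        elif event == "switch_lb":
            st.n_l_back -= 1
            st.n_p_back += 1
        elif event == "switch_pb":
            st.n_p_back -= 1
            st.n_l_back += 1
        else:
            raise ValueError(f"unknown event {event!r}")
        self._refresh_force()

    def _add_uninformed(self, front: bool, role: str) -> None:
        st = self.state
        if role == "puller":
            if front:
                st.n_p_front += 1
            else:
                st.n_p_back += 1
        else:
            if front:
                st.n_l_front += 1
            else:
                st.n_l_back += 1

    def _remove_uninformed(self, front: bool, role: str) -> None:
        st = self.state
        # fall back to the available type if the equilibrium draw is infeasible
        if front:
            if role == "puller" and st.n_p_front == 0:
                role = "lifter"
            elif role == "lifter" and st.n_l_front == 0:
                role = "puller"
            if role == "puller":
                st.n_p_front -= 1
            else:
                st.n_l_front -= 1
        else:
            if role == "puller" and st.n_p_back == 0:
                role = "lifter"
            elif role == "lifter" and st.n_l_back == 0:
                role = "puller"
            if role == "puller":
                st.n_p_back -= 1
            else:
                st.n_l_back -= 1

    def step(self, rng) -> tuple[float, str]:
        rates = self.rates()
        R_tot = sum(rates.values())
        if R_tot <= 0:
            raise RuntimeError("absorbing state reached: total event rate is zero")
        u1 = 1.0 - rng.random()  # uniform on (0, 1]
        dt = -math.log(u1) / R_tot
        if not self.freeze_position:
            self.state.x += self.state.v * dt
        self.state.t += dt
        target = rng.random() * R_tot
        acc = 0.0
        order = ("attach", "detach", "switch_lf", "switch_pf", "switch_lb",
                 "switch_pb", "forget")
        event = order[-1]
        for name in order:
            acc += rates[name]
            if target < acc:
                event = name
                break
        self.apply(event, rng)
        return dt, event


def gillespie_step(
    state: CargoState1D,
    scheme: str | int,
    params: PhysicalParams,
    rng: np.random.Generator,
    restoring_mode: str = "sign",
    eps: float = 0.0,
) -> tuple[float, str, CargoState1D]:
    """One exact Gillespie event: waiting time, event class, updated state.

    The cargo position advances ballistically over the waiting time before
    the event is applied; the velocity is recomputed from the force balance
    afterwards.
    """
    sim = _Sim(
        SCHEMES.get(scheme, scheme), params, restoring_mode, eps, state=state
    )
    dt, event = sim.step(rng)
    return dt, event, sim.state


def run_scheme(
    scheme: str | int,
    params: PhysicalParams | None = None,
    T: float = 100.0,
    seed: int = 0,
    x0: float = 0.0,
    restoring_mode: str = "sign",
    eps: float = 0.0,
    freeze_position: bool = False,
    initial_state: CargoState1D | None = None,
) -> Trajectory:
    """Simulate one kinetic scheme for duration ``T`` seconds.

    ``params`` defaults to the scheme's standard parameter column.  Returns an
    event-time trajectory (resample for uniform-grid analyses).
    """
    from .params import PARAMS_1D_PROCESS

    name = SCHEMES.get(scheme, scheme)
    if name not in _SCHEME_IDS:
        raise InvalidParameterError(f"unknown scheme {scheme!r}")
    if params is None:
        params = PARAMS_1D_PROCESS[_SCHEME_IDS[name]]
    rng = np.random.default_rng(seed)
    sim = _Sim(name, params, restoring_mode, eps, freeze_position, initial_state)
    sim.state.x = x0
    sim._refresh_force()

    ts, xs, vs, nps, nls, nis = [], [], [], [], [], []

    def record() -> None:
        st = sim.state
        ts.append(st.t)
        xs.append(st.x)
        vs.append(st.v)
        nps.append(st.n_p_front + st.n_p_back)
        nls.append(st.n_l_front + st.n_l_back)
        nis.append(st.n_inf if name == "informed" else params.G)

    record()
    while sim.state.t < T:
        sim.step(rng)
        record()
    st = sim.state
    st.check()
    t = np.asarray(ts)
    keep = np.concatenate(([True], np.diff(t) > 0))
    return Trajectory(
        t=t[keep],
        x=np.asarray(xs)[keep],
        v=np.asarray(vs)[keep],
        n_pullers=np.asarray(nps)[keep],
        n_lifters=np.asarray(nls)[keep],
        n_informed=np.asarray(nis)[keep],
        meta={
            "kind": "gillespie1d",
            "scheme": name,
            "seed": seed,
            "params": params,
            "restoring_mode": restoring_mode,
        },
    )
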