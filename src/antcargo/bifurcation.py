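"""Bifurcation structure of the mean-field cargo dynamics in the (g, f_ind) plane.

Three critical lines organize the dynamics:

* **Hopf** (f_c1, closed form): for eps > 0 the origin loses stability below
  f_c1 = (n/2) / (1 + g/(2 k_c eps)) through a subcritical Hopf bifurcation;
  as eps -> 0, f_c1 -> 0 and the origin is stable for all f_ind.
* **Homoclinic** (f_c2, transcendental): the velocity nullcline branches in
  each half-space merge, converting unbounded ballistic escape into a bounded
  relaxation-oscillation limit cycle.  The merge velocity is
  v = -g + sqrt((n/2)(n/2 - f)) and substituting it into the nullcline
  tangency condition gives f = (n/2) sech^2(v/f), solved here by bracketed
  root finding.
* **Saddle-node of cycles** (f_c3, numeric): the stable limit cycle and the
  separatrix (unstable cycle) coalesce.  Located by bisection on the
  existence of a fixed point of the Poincare half-map on the section x = 0.

Phases: (i) f < f_c2 — bistability of convergence and ballistic escape;
(ii) f_c2 <= f < f_c3 — bistability of convergence and relaxation
oscillations; (iii) f >= f_c3 — global convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from . import meanfield
from .params import InvalidParameterError, RescaledParams

__all__ = [
    "BifurcationResult",
    "PhaseDiagram",
    "ConvergedToOrigin",
    "EscapedToInfinity",
    "hopf_threshold",
    "homoclinic_velocity",
    "homoclinic_threshold",
    "homoclinic_threshold_simulated",
    "poincare_half_map",
    "cycle_amplitude_margin",
    "section_fixed_points",
    "saddle_node_threshold",
    "classify_phase",
    "phase_diagram",
]


class ConvergedToOrigin(Exception):
    """The orbit was captured by the convergent mode before returning."""


class EscapedToInfinity(Exception):
    """The orbit left the computational window ballistically."""


@dataclass
class BifurcationResult:
    f_c1: float
    f_c2: float | None
    f_c3: float | None
    v_plus: float | None
    v_minus: float | None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class PhaseDiagram:
    g: np.ndarray
    f_ind: np.ndarray
    labels: np.ndarray  # shape (len(f_ind), len(g)), dtype object (strings)
    critical_curves: dict = field(default_factory=dict)


def hopf_threshold(rp: RescaledParams) -> float:
    """Critical individuality of the subcritical Hopf bifurcation of the origin.

    f_c1 = (n/2) / (1 + g/(2 k_c eps)); the fixed point is stable for
    f_ind > f_c1.  Continuous in eps with f_c1 -> 0 as eps -> 0.
    """
    if rp.eps == 0:
        return 0.0
    return (rp.n / 2.0) / (1.0 + rp.g / (2.0 * rp.k_c * rp.eps))


def homoclinic_velocity(rp: RescaledParams) -> tuple[float, float]:
    """Cargo velocities (v_plus, v_minus) at the homoclinic transition.

    v_pm = +-g -+ sqrt((n/2)(n/2 - f_ind)); requires f_ind <= n/2 for a real
    radicand (beyond that the nullcline branches no longer meet).
    """
    radicand = (rp.n / 2.0) * (rp.n / 2.0 - rp.f_ind)
    if radicand < 0:
        raise InvalidParameterError(
            f"f_ind must not exceed n/2 = {rp.n / 2:.4g} for real transition velocities"
        )
    s = math.sqrt(radicand)
    return (rp.g - s, -rp.g + s)


def _homoclinic_residual(f: float, n: float, g: float) -> float:
    arg = (-g + math.sqrt((n / 2.0) * (n / 2.0 - f))) / f
    if abs(arg) > 300.0:  # sech^2 underflows to 0
        return -f
    return (n / 2.0) / math.cosh(arg) ** 2 - f


def homoclinic_threshold(
    n: float, g: float, k_c: float = 1.0, n_scan: int = 4000
) -> float:
    """Homoclinic critical individuality f_c2, root of the tangency equation.

    Solves f = (n/2) sech^2((-g + sqrt((n/2)(n/2-f)))/f) for f in (0, n/2) by
    scanning for the first sign change from below and bisecting to residual
    < 1e-10.  (k_c rescales time only and does not move the threshold.)
    """
    if n <= 0 or g < 0:
        raise InvalidParameterError("need n > 0 and g >= 0")
    fs = np.linspace(n / 2.0 * 1e-4, n / 2.0 * (1 - 1e-9), n_scan)
    res = np.array([_homoclinic_residual(f, n, g) for f in fs])
    idx = np.nonzero(res[:-1] * res[1:] < 0)[0]
    if idx.size == 0:
        raise InvalidParameterError(
            f"no homoclinic threshold in (0, n/2) for n={n}, g={g}"
        )
    i = idx[0]
    root = brentq(
        _homoclinic_residual, fs[i], fs[i + 1], args=(n, g), xtol=1e-14, rtol=1e-15
    )
    assert abs(_homoclinic_residual(root, n, g)) < 1e-10
    return float(root)


def homoclinic_threshold_simulated(
    n: float,
    g: float,
    k_c: float = 1.0,
    tol: float = 1e-3,
    v0: float | None = None,
) -> float:
    """Homoclinic threshold located by direct simulation of the piecewise flow.

    Bisects f_ind on the outcome of a fast launch from the origin section:
    below the threshold the cargo escapes ballistically along the free
    nullcline branch; above it the branch is gone and the orbit returns.
    Independent of the transcendental-equation route.
    """
    v_launch = v0 if v0 is not None else n

    def escapes(f: float) -> bool:
        rp = RescaledParams(n=n, g=g, f_ind=f, eps=0.0, k_c=k_c)
        outcome, _, _ = meanfield.half_space_excursion(rp, v_launch)
        return outcome == "escape"

    lo, hi = 0.02 * n, 0.5 * n * (1 - 1e-6)
    if not escapes(lo) or escapes(hi):
        raise RuntimeError("bisection bracket invalid for the escape criterion")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if escapes(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def poincare_half_map(rp: RescaledParams, v0: float, x_escape: float = 20.0) -> float:
    """Half-return map on the section x = 0: post-crossing speed -> next one.

    By the (x, v) -> (-x, -v) symmetry of the flow, period-1 orbits of the
    full return map are fixed points of this half map.  For eps = 0 the
    crossing applies the impulse rule (transmit with u - 2g, reflect when
    u <= 2g, raising ConvergedToOrigin); for eps > 0 the smooth flow is
    followed to the next downward crossing.
    """
    if v0 <= 0:
        raise ValueError("the section requires v0 > 0")
    if rp.eps == 0:
        outcome, val, _ = meanfield.half_space_excursion(rp, v0, x_escape=x_escape)
        if outcome == "escape":
            raise EscapedToInfinity(f"orbit escaped past x={x_escape}")
        if outcome == "timeout":
            raise RuntimeError("half-space excursion did not return in time")
        if val <= 2.0 * rp.g:
            raise ConvergedToOrigin(
                f"crossing speed {val:.4g} <= 2g = {2 * rp.g:.4g}: reflected"
            )
        return val - 2.0 * rp.g

    def downward(t, y):
        return y[0]

    downward.terminal = True
    downward.direction = -1.0

    def escape(t, y):
        return abs(y[0]) - x_escape

    escape.terminal = True
    escape.direction = 1.0

    sol = solve_ivp(
        meanfield._smooth_rhs(rp),
        (0.0, 500.0),
        (1e-12, v0),
        method="LSODA",
        events=(downward, escape),
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"return-map integration failed: {sol.message}")
    if sol.t_events[1].size:
        raise EscapedToInfinity(f"orbit escaped past x={x_escape}")
    if not sol.t_events[0].size:
        raise RuntimeError("no section crossing found")
    return abs(sol.y_events[0][0][1])


def cycle_amplitude_margin(
    rp: RescaledParams, n_grid: int = 25
) -> tuple[float, float]:
    """Maximum of H(v) - v over the section, and its location.

    H is the Poincare half map; a non-negative maximum certifies a fixed
    point (a periodic orbit).  Speeds mapping to convergence or escape
    contribute -inf.
    """
    v_floor = 2.0 * rp.g + 1e-4 if rp.eps == 0 else 1e-3
    v_ceil = rp.n / 2.0 + rp.g + 3.0 * rp.f_ind

    def margin(v: float) -> float:
        try:
            return poincare_half_map(rp, v) - v
        except (ConvergedToOrigin, EscapedToInfinity):
            return -np.inf

    grid = np.linspace(v_floor, v_ceil, n_grid)
    vals = np.array([margin(v) for v in grid])
    j = int(np.argmax(vals))
    if not np.isfinite(vals[j]):
        return -np.inf, float(grid[j])
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda v: -margin(v), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    if -res.fun >= vals[j]:
        return float(-res.fun), float(res.x)
    return float(vals[j]), float(grid[j])


def section_fixed_points(rp: RescaledParams) -> tuple[float, float]:
    """Section speeds (v_unstable, v_stable) of the separatrix and stable cycle.

    Roots of H(v) - v bracketing the positive bump of the margin; raises
    InvalidParameterError when no cycle exists (phase iii).
    """
    best, v_at = cycle_amplitude_margin(rp)
    if not (best > 0):
        raise InvalidParameterError("no limit cycle at these parameters")

    def margin(v: float) -> float:
        try:
            return poincare_half_map(rp, v) - v
        except (ConvergedToOrigin, EscapedToInfinity):
            return -1.0

    v_floor = 2.0 * rp.g + 1e-4 if rp.eps == 0 else 1e-3
    v_ceil = rp.n / 2.0 + rp.g + 3.0 * rp.f_ind
    lo = v_at
    while margin(lo) > 0 and lo > v_floor + 1e-6:
        lo = max(v_floor, lo - 0.01)
    v_u = brentq(margin, lo, v_at, xtol=1e-9) if margin(lo) < 0 else lo
    hi = v_at
    while margin(hi) > 0 and hi < v_ceil:
        hi = min(v_ceil, hi + 0.01)
    v_s = brentq(margin, v_at, hi, xtol=1e-9) if margin(hi) < 0 else hi
    return float(v_u), float(v_s)


def saddle_node_threshold(
    n: float,
    g: float,
    k_c: float = 1.0,
    eps: float = 0.0,
    tol: float = 1e-3,
    f_lo: float | None = None,
) -> float:
    """Saddle-node-of-cycles threshold f_c3 by return-map bisection.

    Bisects f_ind on the existence of a fixed point of the Poincare half map
    (positive amplitude margin), starting from a bracket [f_c2 + delta, n/2].
    The stable cycle and the separatrix annihilate at the returned value.
    """
    if f_lo is None:
        f_lo = homoclinic_threshold(n, g, k_c) + 2e-3
    f_hi = n / 2.0 * (1 - 1e-6)

    def has_cycle(f: float) -> bool:
        rp = RescaledParams(n=n, g=g, f_ind=f, eps=eps, k_c=k_c)
        best, _ = cycle_amplitude_margin(rp)
        return best > 0

    if not has_cycle(f_lo):
        raise RuntimeError(
            f"no stable cycle at f_ind={f_lo:.4g}; cannot bracket the saddle-node"
        )
    if has_cycle(f_hi):
        raise RuntimeError(f"cycle persists at f_ind={f_hi:.4g}; no saddle-node found")
    lo, hi = f_lo, f_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_cycle(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_phase(
    g: float,
    f_ind: float,
    n: float = 0.8,
    k_c: float = 1.0,
    eps: float = 0.0,
    f_c2: float | None = None,
    f_c3: float | None = None,
) -> str:
    """Phase label of a (g, f_ind) point.

    phase_i: bistability with ballistic escape (f_ind < f_c2); phase_ii:
    bistability with relaxation oscillations (f_c2 <= f_ind < f_c3);
    phase_iii: global convergence (f_ind >= f_c3).  For eps > 0 points below
    the Hopf threshold are flagged unstable_no_bistability.  Precomputed
    f_c2/f_c3 may be passed to amortize grid scans.
    """
    if g < 0:
        raise InvalidParameterError("g must be non-negative")
    if eps > 0:
        f_c1 = hopf_threshold(RescaledParams(n=n, g=g, f_ind=max(f_ind, 1e-9), eps=eps, k_c=k_c))
        if f_ind < f_c1:
            return "unstable_no_bistability"
    if f_c2 is None:
        f_c2 = homoclinic_threshold(n, g, k_c)
    if f_ind < f_c2:
        return "phase_i"
    if f_c3 is None:
        f_c3 = saddle_node_threshold(n, g, k_c, eps=eps)
    if f_ind < f_c3:
        return "phase_ii"
    return "phase_iii"


def phase_diagram(
    g_range: tuple[float, float],
    f_range: tuple[float, float],
    n: float = 0.8,
    k_c: float = 1.0,
    eps: float = 0.0,
    resolution: int = 8,
) -> PhaseDiagram:
    """Grid of phase labels over (g, f_ind) with cached critical curves."""
    if resolution < 1:
        raise InvalidParameterError("resolution must be positive")
    gs = np.linspace(*g_range, resolution)
    fs = np.linspace(*f_range, resolution)
    labels = np.empty((len(fs), len(gs)), dtype=object)
    curves = {"g": gs, "f_c2": [], "f_c3": [], "f_c1": []}
    for j, g in enumerate(gs):
        f_c2 = homoclinic_threshold(n, g, k_c)
        try:
            f_c3 = saddle_node_threshold(n, g, k_c, eps=eps)
        except RuntimeError:
            f_c3 = math.nan
        curves["f_c2"].append(f_c2)
        curves["f_c3"].append(f_c3)
        curves["f_c1"].append(
            0.0
            if eps == 0
            else hopf_threshold(RescaledParams(n=n, g=g, f_ind=0.1, eps=eps, k_c=k_c))
        )
        for i, f in enumerate(fs):
            labels[i, j] = classify_phase(
                g, f, n, k_c, eps,
                f_c2=f_c2, f_c3=None if math.isnan(f_c3) else f_c3,
            )
    curves = {k: np.asarray(v) for k, v in curves.items()}
    return PhaseDiagram(g=gs, f_ind=fs, labels=labels, critical_curves=curves)


def bifurcation_summary(
    n: float, g: float, k_c: float = 1.0, eps: float = 0.0
) -> BifurcationResult:
    """All critical values at one (n, g): Hopf, homoclinic (with transition
    velocities) and saddle-node thresholds, with solver diagnostics."""
    f_c2 = homoclinic_threshold(n, g, k_c)
    rp2 = RescaledParams(n=n, g=g, f_ind=f_c2, eps=eps, k_c=k_c)
    v_p, v_m = homoclinic_velocity(rp2)
    try:
        f_c3 = saddle_node_threshold(n, g, k_c, eps=eps)
    except RuntimeError as exc:
        f_c3 = None
        diag = {"saddle_node": str(exc)}
    else:
        diag = {}
    f_c1 = 0.0 if eps == 0 else hopf_threshold(rp2)
    diag["homoclinic_residual"] = _homoclinic_residual(f_c2, n, g)
    return BifurcationResult(
        f_c1=f_c1, f_c2=f_c2, f_c3=f_c3, v_plus=v_p, v_minus=v_m, diagnostics=diag
    )
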