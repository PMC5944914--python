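"""Physical and rescaled parameter sets for the ant cooperative-transport model.

The model describes a rigid cargo carried by a group of ants along a linear
obstacle with a narrow opening.  Uninformed carriers switch stochastically
between *puller* and *lifter* roles in response to the total force they sense;
*informed* ants pull toward the opening with a fixed force.  The mechanical
response is overdamped: total force converts to velocity through the response
coefficient ``gamma`` (f_tot = gamma * v).

Rescaling the 1D mean-field equations by gamma yields three velocity-scale
parameters that organize the whole phase diagram:

* ``n = f0 * n_tot / gamma`` — total pulling capacity of the uninformed group,
* ``g = f0 * G / gamma`` — restoring force of the informed ants,
* ``f_ind = F_ind / gamma`` — rescaled individuality, the force threshold above
  which a single ant responds to the group, expressed as a velocity.

This module also implements the steady-state occupancy relations used to
estimate the binding-site count and the forgetting rate from mean carrier
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "PhysicalParams",
    "RescaledParams",
    "SteadyStateOccupancy",
    "rescale_parameters",
    "occupancy_steady_state",
    "estimate_binding_sites",
    "estimate_forget_rate",
    "gamma_for_radius",
    "PARAMS_1D_MODEL",
    "PARAMS_1D_PROCESS",
    "params_2d",
]


class InvalidParameterError(ValueError):
    """Raised when a parameter combination violates the model's preconditions."""


@dataclass(frozen=True)
class PhysicalParams:
    """Kinetic and mechanical constants of the ant-cargo system.

    Forces are measured in units of the single-ant force ``f0`` unless stated;
    rates are per second, lengths in cm.
    """

    f0: float = 1.0            # force applied by a single pulling ant
    F_ind: float = 23.0        # individuality force threshold
    gamma: float = 100.0       # mechanical cargo response coefficient
    n_tot: float = 80.0        # mean number of uninformed carriers
    G: float = 10.0            # mean number of informed pullers
    n_max: int = 80            # total binding sites on the cargo
    k_c: float = 1.0           # basal role-switching rate
    k_on: float = 0.0          # attachment rate (per empty site)
    k_off: float = 0.0         # detachment rate (per uninformed ant)
    k_forget: float = 0.0      # informed -> uninformed conversion rate
    k_orient: float = 0.0      # puller reorientation rate (2D only)
    r: float = 0.0             # cargo radius (0 for the point-cargo 1D model)
    opening_width: float = 0.5  # width of the opening in the obstacle

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise InvalidParameterError("gamma must be positive")
        if self.f0 <= 0:
            raise InvalidParameterError("f0 must be positive")
        if self.F_ind <= 0:
            raise InvalidParameterError("F_ind must be positive")
        for name in ("k_c", "k_on", "k_off", "k_forget", "k_orient"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.n_max < 1 or int(self.n_max) != self.n_max:
            raise InvalidParameterError("n_max must be a positive integer")
        if self.n_tot < 0 or self.G < 0:
            raise InvalidParameterError("carrier numbers must be non-negative")

    def with_(self, **kwargs) -> "PhysicalParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RescaledParams:
    """Reduced parameters of the 1D mean-field equations of motion.

    ``eps`` is the regularization length of the restoring-force profile
    g*tanh(x/eps); ``eps == 0`` encodes the discontinuous g*sign(x) limit.
    """

    n: float
    g: float
    f_ind: float
    eps: float = 0.0
    k_c: float = 1.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise InvalidParameterError("n must be positive")
        if self.g < 0:
            raise InvalidParameterError("g must be non-negative")
        if self.f_ind <= 0:
            raise InvalidParameterError("f_ind must be positive")
        if self.eps < 0:
            raise InvalidParameterError("eps must be non-negative")
        if self.k_c <= 0:
            raise InvalidParameterError("k_c must be positive")

    def with_(self, **kwargs) -> "RescaledParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SteadyStateOccupancy:
    """Stationary fractions of binding sites holding each carrier type."""

    P_u: float                 # fraction holding uninformed ants
    P_inf: float = 0.0         # fraction holding informed ants
    kappa1: float = 0.0        # k_forget / k_off
    kappa2: float = 0.0        # k_forget / k_on


def rescale_parameters(p: PhysicalParams, eps: float = 0.0) -> RescaledParams:
    """Map physical constants to the reduced (n, g, f_ind) parameters.

    n = f0*n_tot/gamma, g = f0*G/gamma, f_ind = F_ind/gamma; all three carry
    velocity units (cm/s).  ``eps`` and ``k_c`` are passed through.
    """
    return RescaledParams(
        n=p.f0 * p.n_tot / p.gamma,
        g=p.f0 * p.G / p.gamma,
        f_ind=p.F_ind / p.gamma,
        eps=eps,
        k_c=p.k_c,
    )


def occupancy_steady_state(
    k_on: float,
    k_off: float,
    k_forget: float = 0.0,
    scheme: Literal["two_state", "three_state"] = "two_state",
) -> SteadyStateOccupancy:
    """Stationary site-occupancy fractions of the attachment kinetics.

    two_state: empty <-> uninformed with rates k_on/k_off, giving
    P_u = k_on/(k_on+k_off).  three_state: empty -> informed (k_on),
    informed -> uninformed (k_forget), uninformed -> empty (k_off), giving
    P_inf = 1/(1+kappa1+kappa2) and P_u = kappa1/(1+kappa1+kappa2) with
    kappa1 = k_forget/k_off, kappa2 = k_forget/k_on.
    """
    if min(k_on, k_off, k_forget) < 0:
        raise InvalidParameterError("rates must be non-negative")
    if scheme == "two_state":
        if k_on + k_off == 0:
            raise InvalidParameterError("k_on + k_off must be positive")
        return SteadyStateOccupancy(P_u=k_on / (k_on + k_off))
    if scheme == "three_state":
        if k_on == 0 or k_off == 0:
            raise InvalidParameterError(
                "three-state kinetics require k_on > 0 and k_off > 0"
            )
        kappa1 = k_forget / k_off
        kappa2 = k_forget / k_on
        denom = 1.0 + kappa1 + kappa2
        return SteadyStateOccupancy(
            P_u=kappa1 / denom, P_inf=1.0 / denom, kappa1=kappa1, kappa2=kappa2
        )
    raise InvalidParameterError(f"unknown scheme {scheme!r}")


def estimate_binding_sites(
    n_tot_mean: float,
    G_mean: float,
    occupancy: SteadyStateOccupancy,
    scheme: Literal["two_state", "three_state"] = "two_state",
) -> float:
    """Estimate the number of binding sites from mean carrier numbers.

    two_state: n_max = n_tot / P_u = n_tot (1 + k_off/k_on).
    three_state: n_max = (n_tot + G) / (P_u + P_inf)
    = (n_tot + G)(1 + kappa2)/(1 + kappa1) ... with the stationary fractions
    above this simplifies to (n_tot + G)(1 + kappa1 + kappa2)/(1 + kappa1).
    """
    if scheme == "two_state":
        if occupancy.P_u <= 0 or occupancy.P_u > 1:
            raise InvalidParameterError("P_u must lie in (0, 1]")
        return n_tot_mean / occupancy.P_u
    if scheme == "three_state":
        occupied = occupancy.P_u + occupancy.P_inf
        if occupied <= 0 or occupied > 1:
            raise InvalidParameterError("P_u + P_inf must lie in (0, 1]")
        return (n_tot_mean + G_mean) / occupied
    raise InvalidParameterError(f"unknown scheme {scheme!r}")


def estimate_forget_rate(
    n_max: float,
    G_mean: float,
    n_tot_mean: float,
    k_on: float,
    k_off: float,
) -> float:
    """Forgetting rate consistent with the three-state stationary occupancy.

    Inverts the three-state site estimate for k_forget:

        k_forget = (n_max/(G+n_tot) - 1) * k_on
                   / (1 - (k_on/k_off) * (n_max/(G+n_tot) - 1))

    The ratio term n_max/(G+n_tot) - 1 is the relative excess of sites over
    carriers; it vanishes (k_forget = 0) when the cargo is fully occupied.
    """
    if G_mean + n_tot_mean <= 0:
        raise InvalidParameterError("G_mean + n_tot_mean must be positive")
    if k_on < 0 or k_off <= 0:
        raise InvalidParameterError("need k_on >= 0 and k_off > 0")
    excess = n_max / (G_mean + n_tot_mean) - 1.0
    denom = 1.0 - (k_on / k_off) * excess
    if denom <= 0:
        raise InvalidParameterError(
            "infeasible parameter combination: denominator of the forget-rate "
            f"estimate is {denom:.3g} <= 0"
        )
    return excess * k_on / denom


def gamma_for_radius(r: float, f0: float = 2.8, v_single: float = 0.14) -> float:
    """Mechanical response coefficient for a ring cargo of radius ``r`` (cm).

    Anchored so that a single ant pulling the smallest cargo (r = 0.5 cm)
    moves it at the observed v_single = f0/gamma = 0.14 cm/s, and scaled
    linearly with radius (gamma grows with the cargo perimeter).
    """
    if r <= 0:
        raise InvalidParameterError("radius must be positive")
    return (f0 / v_single) * (r / 0.5)


# Default parameter sets of the 1D model and the three 1D stochastic schemes.
PARAMS_1D_MODEL = PhysicalParams(
    f0=1.0, F_ind=23.0, gamma=100.0, n_tot=80.0, G=10.0, n_max=80, k_c=1.0
)
PARAMS_1D_PROCESS = {
    1: PARAMS_1D_MODEL,
    2: PARAMS_1D_MODEL.with_(n_tot=100.0, n_max=100, k_on=0.06, k_off=0.015),
    3: PARAMS_1D_MODEL.with_(
        n_tot=110.0, n_max=110, k_on=0.06, k_off=0.015, k_forget=0.12
    ),
}

_PARAMS_2D = {
    2.0: dict(n_max=96, n_tot=52.5, G=8.5),
    1.0: dict(n_max=48, n_tot=25.8, G=4.2),
    0.5: dict(n_max=16, n_tot=8.6, G=1.4),
}


def params_2d(r: float) -> PhysicalParams:
    """Default parameters of the 2D ring-cargo simulation for radius ``r``."""
    try:
        cols = _PARAMS_2D[float(r)]
    except KeyError:
        raise InvalidParameterError(
            f"no default 2D parameter set for r={r}; available radii: 0.5, 1, 2"
        ) from None
    return PhysicalParams(
        f0=2.8,
        F_ind=28.0,
        gamma=gamma_for_radius(r),
        k_c=1.0,
        k_on=0.0214,
        k_off=0.015,
        k_forget=0.09,
        k_orient=0.7,
        r=r,
        **cols,
    )
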