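"""Physics kernel for the straight-duct surrogate of a nasal passage.

The nasal passage is idealised as a straight, rigid, horizontal duct of
hydraulic diameter ``Dh`` and length ``L`` carrying unsteady,
incompressible, fully developed flow.  The pressure drop across the duct
is the sum of a Darcy-Weisbach friction term and a plug-flow inertial
term::

    dP = L * [ 8 rho fD Q|Q| / (pi^2 Dh^5)  +  4 rho / (pi Dh^2) * dQ/dt ]

The inertial term opens the pressure-flow loop into a hysteresis of
width ``W = 8 rho L omega Qmax / (pi Dh^2)`` at zero flow when the flow
is sinusoidal with amplitude ``Qmax`` and angular frequency ``omega``.
All functions here are pure, strict-SI, and accept numpy arrays where a
flowrate argument appears.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .errors import InvalidParameterError, UndefinedFrictionError

ArrayLike = Union[float, np.ndarray]

#: von Karman constant used by the log law and the LES mixing length.
VON_KARMAN = 0.4187


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidProperties:
    """Constant fluid properties (strict SI).

    Parameters
    ----------
    density : float
        Mass density rho in kg/m^3.
    dynamic_viscosity : float
        Dynamic viscosity mu in Pa s.
    """

    density: float
    dynamic_viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidParameterError(f"density must be > 0, got {self.density}")
        if self.dynamic_viscosity <= 0:
            raise InvalidParameterError(
                f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}"
            )

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho in m^2/s."""
        return self.dynamic_viscosity / self.density


#: Standard-condition air used by the simulation protocol
#: (rho = 1.225 kg/m^3, mu = 1.7894e-5 Pa s).
AIR_STANDARD = FluidProperties(density=1.225, dynamic_viscosity=1.7894e-5)

#: Air with the rounded kinematic viscosity nu = 1.5e-5 m^2/s commonly
#: used in order-of-magnitude estimates (same density as AIR_STANDARD).
AIR_ROUNDED_NU = FluidProperties(density=1.225, dynamic_viscosity=1.5e-5 * 1.225)


@dataclass(frozen=True)
class DuctModel:
    """Straight-duct surrogate geometry.

    Parameters
    ----------
    hydraulic_diameter : float
        Dh in metres; for a non-circular cross-section Dh = 4A/O.
    length : float
        Channel length L in metres (L = 0 gives a zero-resistance duct).
    relative_roughness : float
        Wall roughness relative to Dh (dimensionless, >= 0; the nasal
        surrogate is normally smooth, eps_r = 0).
    """

    hydraulic_diameter: float
    length: float
    relative_roughness: float = 0.0

    def __post_init__(self) -> None:
        if self.hydraulic_diameter <= 0:
            raise InvalidParameterError(
                f"hydraulic_diameter must be > 0, got {self.hydraulic_diameter}"
            )
        if self.length < 0:
            raise InvalidParameterError(f"length must be >= 0, got {self.length}")
        if self.relative_roughness < 0:
            raise InvalidParameterError(
                f"relative_roughness must be >= 0, got {self.relative_roughness}"
            )

    @classmethod
    def from_cross_section(
        cls, area: float, perimeter: float, length: float,
        relative_roughness: float = 0.0,
    ) -> "DuctModel":
        """Build a duct from cross-sectional area and wetted perimeter."""
        if area <= 0 or perimeter <= 0:
            raise InvalidParameterError("area and perimeter must be > 0")
        return cls(4.0 * area / perimeter, length, relative_roughness)


class FrictionRegime(str, enum.Enum):
    """Which Darcy friction-factor branch to evaluate."""

    LAMINAR = "laminar"
    TURBULENT = "turbulent"
    BLENDED = "blended"


def _cosine_taper(re: ArrayLike, lo: float, hi: float) -> ArrayLike:
    """Weight wt(Re): 1 at/below lo, 0 at/above hi, cosine in between."""
    x = np.clip((np.asarray(re, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * x))


@dataclass(frozen=True)
class FrictionPolicy:
    """How the Darcy friction factor fD(Re, eps_r) is evaluated.

    The laminar branch is fD = 64/Re; the turbulent branch is the
    Haaland correlation.  ``blended`` takes a smooth weighted average
    ``wt*f_lam + (1-wt)*f_turb`` across the transitional band
    [blend_lower, blend_upper] (default 2000-4000) with a cosine taper,
    so fD is continuous in Re and coincides with the pure branches
    outside the band.
    """

    regime: FrictionRegime = FrictionRegime.BLENDED
    blend_lower: float = 2000.0
    blend_upper: float = 4000.0
    weight: Callable[[ArrayLike, float, float], ArrayLike] = field(
        default=_cosine_taper, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.blend_lower < self.blend_upper:
            raise InvalidParameterError(
                "blend_lower must be < blend_upper "
                f"(got {self.blend_lower}, {self.blend_upper})"
            )

    def wt(self, re: ArrayLike) -> ArrayLike:
        """Laminar weight: 1 below blend_lower, 0 above blend_upper."""
        return self.weight(re, self.blend_lower, self.blend_upper)


LAMINAR = FrictionPolicy(regime=FrictionRegime.LAMINAR)
HAALAND = FrictionPolicy(regime=FrictionRegime.TURBULENT)
BLENDED = FrictionPolicy(regime=FrictionRegime.BLENDED)


@dataclass(frozen=True)
class DimensionlessNumbers:
    """Bundle of the dimensionless diagnostics of a flow condition."""

    reynolds: float
    womersley: float
    relative_hysteresis_width: float
    cfl: float = 0.0
    frequency: float = 0.0

    def __post_init__(self) -> None:
        for name in ("reynolds", "womersley", "relative_hysteresis_width", "cfl"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def reynolds_number(
    flowrate: ArrayLike, duct: DuctModel, fluid: FluidProperties
) -> ArrayLike:
    """Reynolds number for internal duct flow, Re = 4|Q| / (pi nu Dh)."""
    nu = fluid.kinematic_viscosity
    return 4.0 * np.abs(flowrate) / (math.pi * nu * duct.hydraulic_diameter)


def haaland_friction_factor(re: ArrayLike, relative_roughness: float = 0.0) -> ArrayLike:
    """Explicit Haaland correlation for the turbulent Darcy friction factor.

    1/sqrt(fD) = -1.8 log10[ (eps_r/3.7)^1.11 + 6.9/Re ]
    """
    if relative_roughness < 0:
        raise InvalidParameterError("relative_roughness must be >= 0")
    re = np.asarray(re, dtype=float)
    if np.any(re <= 0):
        raise UndefinedFrictionError("Haaland friction factor requires Re > 0")
    inv_sqrt = -1.8 * np.log10((relative_roughness / 3.7) ** 1.11 + 6.9 / re)
    out = 1.0 / inv_sqrt**2
    return float(out) if out.ndim == 0 else out


def friction_factor(
    re: ArrayLike,
    relative_roughness: float = 0.0,
    policy: FrictionPolicy = BLENDED,
) -> ArrayLike:
    """Darcy friction factor under the given regime policy.

    Laminar: 64/Re.  Turbulent: Haaland.  Blended: cosine-weighted
    average across the transitional Reynolds band.
    """
    re_arr = np.asarray(re, dtype=float)
    if policy.regime is FrictionRegime.TURBULENT:
        return haaland_friction_factor(re, relative_roughness)
    if np.any(re_arr <= 0):
        raise UndefinedFrictionError(
            "laminar friction factor 64/Re diverges at Re = 0; "
            "use the linear-law form of the friction term instead"
        )
    f_lam = 64.0 / re_arr
    if policy.regime is FrictionRegime.LAMINAR:
        return float(f_lam) if f_lam.ndim == 0 else f_lam
    f_turb = haaland_friction_factor(re_arr, relative_roughness)
    w = policy.wt(re_arr)
    out = w * f_lam + (1.0 - w) * f_turb
    return float(out) if out.ndim == 0 else out


def _friction_flux(
    flowrate: ArrayLike,
    duct: DuctModel,
    fluid: FluidProperties,
    policy: FrictionPolicy,
) -> ArrayLike:
    """fD(Re) * Q|Q|, evaluated stably through Q = 0.

    With fD = 64/Re the product is linear in Q (64/Re * Q|Q|
    = 16 pi nu Dh Q), so the laminar contribution is evaluated in that
    analytic form and the apparent 0/0 at zero flow never occurs; the
    turbulent contribution vanishes quadratically at Q = 0 and its
    blend weight is 1 (pure laminar) there anyway.
    """
    q = np.asarray(flowrate, dtype=float)
    nu = fluid.kinematic_viscosity
    dh = duct.hydraulic_diameter
    lam = 16.0 * math.pi * nu * dh * q  # 64/Re * Q|Q|, exact for all Q
    if policy.regime is FrictionRegime.LAMINAR:
        out = lam
    else:
        re = reynolds_number(q, duct, fluid)
        with np.errstate(divide="ignore"):
            f_turb = np.where(
                re > 0, haaland_friction_factor(np.where(re > 0, re, 1.0),
                                                duct.relative_roughness), 0.0
            )
        turb = f_turb * q * np.abs(q)
        if policy.regime is FrictionRegime.TURBULENT:
            out = turb
        else:
            w = policy.wt(re)
            out = w * lam + (1.0 - w) * turb
    return float(out) if np.ndim(out) == 0 else out


def hagen_poiseuille_resistance(duct: DuctModel, fluid: FluidProperties) -> float:
    """Laminar flow resistance R = 128 L mu / (pi Dh^4) in Pa s/m^3."""
    return (
        128.0 * duct.length * fluid.dynamic_viscosity
        / (math.pi * duct.hydraulic_diameter**4)
    )


def combine_unilateral_resistances(
    r_left: Optional[float], r_right: Optional[float]
) -> float:
    """Bilateral resistance of two parallel passages: 1/R = 1/Rl + 1/Rr.

    An occluded side is passed as ``None`` (never 0 or inf); the open
    side's resistance is then returned unchanged.
    """
    sides = [r for r in (r_left, r_right) if r is not None]
    if not sides:
        raise InvalidParameterError("at least one side must be present")
    for r in sides:
        if r <= 0:
            raise InvalidParameterError(f"unilateral resistance must be > 0, got {r}")
    if len(sides) == 1:
        return sides[0]
    return 1.0 / (1.0 / sides[0] + 1.0 / sides[1])


def pressure_drop(
    flowrate: ArrayLike,
    flow_derivative: ArrayLike,
    duct: DuctModel,
    fluid: FluidProperties,
    policy: FrictionPolicy = BLENDED,
) -> ArrayLike:
    """Unsteady Bernoulli pressure drop across the duct, in Pa.

    dP = L * [ 8 rho fD Q|Q| / (pi^2 Dh^5) + 4 rho / (pi Dh^2) dQ/dt ]

    The friction term is written fD * Q|Q| so that it opposes the flow
    in both breathing directions; at dQ/dt = 0 with laminar friction it
    reduces exactly to the Hagen-Poiseuille line R_HP * Q.
    """
    rho = fluid.density
    dh = duct.hydraulic_diameter
    flux = _friction_flux(flowrate, duct, fluid, policy)
    friction = 8.0 * rho * flux / (math.pi**2 * dh**5)
    unsteady = 4.0 * rho / (math.pi * dh**2) * np.asarray(flow_derivative, dtype=float)
    out = duct.length * (friction + unsteady)
    return float(out) if np.ndim(out) == 0 else out


def hysteresis_width(
    duct: DuctModel, fluid: FluidProperties, protocol: "BreathingProtocol"
) -> float:
    """Loop width at zero flow for sinusoidal breathing, in Pa.

    W = 8 rho L omega Qmax / (pi Dh^2) — twice the inertial pressure
    drop at the zero-flow instants, where |dQ/dt| = omega * Qmax.
    """
    return (
        8.0 * fluid.density * duct.length * protocol.angular_frequency
        * protocol.peak_flowrate / (math.pi * duct.hydraulic_diameter**2)
    )


def relative_hysteresis_width(
    hydraulic_diameter: float, period: float, fluid: FluidProperties
) -> float:
    """Hysteresis width normalised by the peak laminar pressure drop.

    W_rel = omega Dh^2 / (16 nu); independent of L and Qmax, so it
    isolates the duct size and the breathing period as the controls of
    loop openness.
    """
    if hydraulic_diameter <= 0:
        raise InvalidParameterError("hydraulic_diameter must be > 0")
    if period <= 0:
        raise InvalidParameterError("period must be > 0")
    omega = 2.0 * math.pi / period
    return omega * hydraulic_diameter**2 / (16.0 * fluid.kinematic_viscosity)


def womersley_number(
    hydraulic_diameter: float, frequency: float, fluid: FluidProperties
) -> float:
    """Womersley number Wo = Dh sqrt(pi f / (2 nu)).

    The ratio of transient inertial to viscous forces in pulsatile
    flow; Wo < 1 marks quasi-steady behaviour.
    """
    if hydraulic_diameter <= 0:
        raise InvalidParameterError("hydraulic_diameter must be > 0")
    if frequency < 0:
        raise InvalidParameterError("frequency must be >= 0")
    nu = fluid.kinematic_viscosity
    return hydraulic_diameter * math.sqrt(math.pi * frequency / (2.0 * nu))
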