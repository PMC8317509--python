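"""Per-beat hydrodynamics: thrust, power, drag coefficient, reference drag.

The central relation is the beat-averaged equation of motion

    M (1 + k_added) * dU/dt = T_mean - D_mean,

with mean acceleration (U_f - U_i)/T_beat over one tailbeat and mean drag
D_mean = 1/2 rho S_a C_D U_avg^2. Solving for the drag coefficient gives

    C_D = [T_mean - M (1 + k_added) dU/T_beat] / (1/2 rho S_a U_avg^2),

whose second numerator term is the unsteadiness correction; setting
dU = 0 recovers the familiar steady thrust-equals-drag case. Reordering
for the mean thrust power gives the lunge-power estimator used with the
routine-mean drag coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .exceptions import EstimationError, InvalidInputError
from .photogrammetry import WhaleMorphology
from .tailbeats import TailbeatCycle

__all__ = [
    "Environment",
    "HydroRecord",
    "mean_thrust_and_power",
    "drag_coefficient_beat",
    "routine_drag_summary",
    "lunge_thrust_power",
    "rigid_body_reference",
    "dimensionless_numbers",
]


@dataclass(frozen=True)
class Environment:
    """Seawater properties: density rho (kg/m^3), kinematic viscosity nu (m^2/s)."""

    rho: float = 1025.0
    nu: float = 1.05e-6

    def __post_init__(self) -> None:
        if not 1000.0 < self.rho < 1050.0:
            raise InvalidInputError("rho must lie in (1000, 1050) kg/m^3")
        if not 0.8e-6 < self.nu < 2e-6:
            raise InvalidInputError("nu must lie in (0.8e-6, 2e-6) m^2/s")


@dataclass
class HydroRecord:
    """Per-tailbeat hydrodynamic estimates."""

    t_start_s: float
    t_end_s: float
    mode: str
    f_hz: float
    u_avg_mps: float
    delta_u_mps: float
    sigma: float
    theta: float
    ct: float
    eta: float
    thrust_n: float
    thrust_power_w: float
    mass_specific_power_wkg: float
    drag_coefficient: float
    correction_fraction: float
    reynolds: float
    strouhal: float
    cd_flagged: bool = False


def mean_thrust_and_power(
    ct: float, u_avg: float, fluke_area_m2: float, env: Environment
) -> tuple[float, float]:
    """Mean thrust T = 1/2 rho U^2 F_a C_T and thrust power P = T*U."""
    if u_avg <= 0 or fluke_area_m2 <= 0 or ct < 0:
        raise InvalidInputError("u_avg, fluke_area and C_T must be positive")
    thrust = 0.5 * env.rho * u_avg**2 * fluke_area_m2 * ct
    return thrust, thrust * u_avg


def unsteady_term(morph: WhaleMorphology, delta_u: float, t_beat: float) -> float:
    """Acceleration-reaction force M (1 + k_added) dU / T_beat (N)."""
    if t_beat <= 0:
        raise InvalidInputError("t_beat must be strictly positive")
    return morph.mass_kg * (1.0 + morph.added_mass_coeff) * delta_u / t_beat


def drag_coefficient_beat(
    thrust_n: float,
    morph: WhaleMorphology,
    beat: TailbeatCycle,
    env: Environment,
) -> tuple[float, float]:
    """Per-beat drag coefficient with acceleration correction.

    Returns ``(C_D, correction_fraction)`` where the correction fraction
    is the magnitude of the acceleration-reaction term relative to the
    thrust term. A negative C_D (correction exceeding thrust) is
    returned as-is; the caller flags rather than drops it.
    """
    if morph.wetted_area_m2 <= 0:
        raise InvalidInputError("wetted area must be strictly positive")
    if beat.u_avg_mps is None or beat.u_avg_mps <= 1.0:
        raise InvalidInputError("beat mean speed must exceed 1 m/s")
    term2 = unsteady_term(morph, beat.delta_u_mps, beat.duration_s)
    denom = 0.5 * env.rho * morph.wetted_area_m2 * beat.u_avg_mps**2
    cd = (thrust_n - term2) / denom
    correction = abs(term2) / abs(thrust_n) if thrust_n != 0 else math.inf
    return cd, correction


def routine_drag_summary(records: list[HydroRecord]) -> float:
    """Mean drag coefficient over routine beats, excluding flagged ones."""
    values = [
        r.drag_coefficient
        for r in records
        if r.mode == "routine" and not r.cd_flagged
    ]
    if not values:
        raise EstimationError("no unflagged routine beats to average")
    return sum(values) / len(values)


def lunge_thrust_power(
    cd_routine: float,
    morph: WhaleMorphology,
    beat: TailbeatCycle,
    env: Environment,
) -> float:
    """Mean thrust power of a lunge-associated beat (algebraic inverse of
    the drag-coefficient relation, using the routine-mean C_D)."""
    if beat.u_avg_mps is None or beat.u_avg_mps <= 0:
        raise InvalidInputError("beat mean speed must be strictly positive")
    drag = 0.5 * env.rho * morph.wetted_area_m2 * cd_routine * beat.u_avg_mps**2
    accel = unsteady_term(morph, beat.delta_u_mps, beat.duration_s)
    return (drag + accel) * beat.u_avg_mps


class RigidBodyReference(NamedTuple):
    reynolds: float
    cd_mod: float
    drag_parasite_n: float


def rigid_body_reference(
    morph: WhaleMorphology, u_mps: float, env: Environment
) -> RigidBodyReference:
    """Airship (rigid-hull) reference drag at speed U.

    Re = L*U/nu; the modelled drag coefficient follows the Hoerner
    streamlined-body correlation with a turbulent flat-plate skin
    friction coefficient:

        C_f = 0.072 Re^(-1/5)
        C_D,mod = C_f [1 + 1.5 (W/L)^1.5 + 7 (W/L)^3]

    and the parasite drag force is 1/2 rho S_a C_D,mod U^2.
    """
    if u_mps <= 0:
        raise InvalidInputError("speed must be strictly positive")
    if morph.max_diameter_m >= morph.body_length_m:
        raise InvalidInputError("max diameter must be smaller than body length")
    re = morph.body_length_m * u_mps / env.nu
    cf = 0.072 * re ** (-0.2)
    ratio = morph.max_diameter_m / morph.body_length_m
    cd_mod = cf * (1.0 + 1.5 * ratio**1.5 + 7.0 * ratio**3)
    drag = 0.5 * env.rho * morph.wetted_area_m2 * cd_mod * u_mps**2
    return RigidBodyReference(re, cd_mod, drag)


def dimensionless_numbers(
    f_hz: float,
    u_avg: float,
    thrust_power_w: float,
    morph: WhaleMorphology,
    amplitude: str = "body",
) -> tuple[float, float]:
    """Strouhal number and mass-specific thrust power.

    St = f*A/U with wake-width amplitude A = 0.2*L (``amplitude="body"``,
    the total excursion convention of prior tag studies) or A = 2*h
    (``amplitude="heave"``).
    """
    if u_avg <= 0:
        raise InvalidInputError("speed must be strictly positive")
    if morph.mass_kg <= 0:
        raise InvalidInputError("mass must be strictly positive")
    if amplitude == "body":
        a = 0.2 * morph.body_length_m
    elif amplitude == "heave":
        a = 2.0 * morph.heave_amplitude_m
    else:
        raise InvalidInputError(f"unknown amplitude convention {amplitude!r}")
    return f_hz * a / u_avg, thrust_power_w / morph.mass_kg
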