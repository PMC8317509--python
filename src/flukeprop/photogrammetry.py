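"""Aerial-photogrammetry morphometrics.

Converts pixel measurements from drone images into metric body
measurements via the ground sampling distance (GSD), and derives
allometric body mass and wetted surface area from total length.

The mass and wetted-area regressions are power laws ``a * L**b`` whose
coefficients are species specific and must come from the literature.
The defaults shipped here are *placeholders* (a cube law for mass, a
square law for area) intended for synthetic work and unit tests only;
scientific use requires explicit coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "CameraSpec",
    "WhaleMorphology",
    "AllometryCoefficients",
    "AllometricScalars",
    "PLACEHOLDER_ALLOMETRY",
    "ground_sampling_distance",
    "pixels_to_meters",
    "meters_to_pixels",
    "allometric_scalars",
]


@dataclass(frozen=True)
class CameraSpec:
    """Camera and flight parameters needed for the GSD computation.

    Parameters
    ----------
    altitude_m : float
        Altitude of the aircraft above the animal, in metres.
    focal_length_mm : float
        Lens focal length, in millimetres.
    sensor_width_mm : float
        Physical sensor width, in millimetres.
    image_width_px : int
        Image resolution width, in pixels.
    """

    altitude_m: float
    focal_length_mm: float
    sensor_width_mm: float
    image_width_px: int

    def __post_init__(self) -> None:
        for name in ("altitude_m", "focal_length_mm", "sensor_width_mm", "image_width_px"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"CameraSpec.{name} must be strictly positive")


@dataclass
class WhaleMorphology:
    """Morphometrics of a single animal.

    ``heave_amplitude_m`` defaults to one-fifth of body length and
    ``attack_angle_rad`` to 30 degrees, the validated estimates used when
    the fluke motion itself cannot be observed from the tag. The
    added-mass coefficient ``added_mass_coeff`` is the acceleration
    reaction coefficient (0.03 for blue and minke whales, 0.05 for
    humpback whales).
    """

    species: str
    body_length_m: float
    max_diameter_m: float
    fluke_chord_m: float
    fluke_area_m2: float
    wetted_area_m2: float
    mass_kg: float
    added_mass_coeff: float = 0.03
    heave_amplitude_m: float | None = None
    attack_angle_rad: float = math.radians(30.0)

    def __post_init__(self) -> None:
        if self.body_length_m <= 0:
            raise InvalidInputError("body_length_m must be strictly positive")
        if not 0 < self.max_diameter_m < self.body_length_m:
            raise InvalidInputError("max_diameter_m must lie in (0, body_length_m)")
        for name in ("fluke_chord_m", "fluke_area_m2", "wetted_area_m2", "mass_kg"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if not 0 <= self.added_mass_coeff <= 0.2:
            raise InvalidInputError("added_mass_coeff must lie in [0, 0.2]")
        if self.heave_amplitude_m is None:
            self.heave_amplitude_m = 0.2 * self.body_length_m


@dataclass(frozen=True)
class AllometryCoefficients:
    """Power-law coefficients for one species.

    mass = ``mass_a * L**mass_b`` (kg); wetted area =
    ``area_c * L**area_d`` (m^2). ``chord_fraction`` and
    ``fluke_area_fraction`` give fluke chord as a fraction of L and fluke
    planform area as a fraction of L^2.
    """

    mass_a: float
    mass_b: float
    area_c: float
    area_d: float
    k_added: float = 0.03
    chord_fraction: float = 0.054
    fluke_area_fraction: float = 0.02
    diameter_fraction: float = 0.2
    provenance: str = "unspecified"


#: Placeholder defaults (cube-law mass, square-law area). NOT literature
#: values; synthetic/testing use only.
PLACEHOLDER_ALLOMETRY: dict[str, AllometryCoefficients] = {
    "default": AllometryCoefficients(
        mass_a=10.0,
        mass_b=3.0,
        area_c=0.4,
        area_d=2.0,
        provenance="placeholder cube/square laws; supply species coefficients for scientific use",
    ),
}


class AllometricScalars(NamedTuple):
    mass_kg: float
    wetted_area_m2: float
    provenance: str


def ground_sampling_distance(cam: CameraSpec) -> float:
    """Metric ground length of one image pixel.

    GSD = altitude * sensor_width / (focal_length * image_width); the
    millimetre units of sensor width and focal length cancel, leaving
    metres per pixel.
    """
    return cam.altitude_m * cam.sensor_width_mm / (cam.focal_length_mm * cam.image_width_px)


def pixels_to_meters(n_pix: float, gsd: float) -> float:
    """Convert a pixel measurement to metres given the GSD (m/px)."""
    if n_pix < 0:
        raise InvalidInputError("pixel count must be non-negative")
    if gsd <= 0:
        raise InvalidInputError("gsd must be strictly positive")
    return n_pix * gsd


def meters_to_pixels(length_m: float, gsd: float) -> float:
    """Inverse of :func:`pixels_to_meters`."""
    if length_m < 0:
        raise InvalidInputError("length must be non-negative")
    if gsd <= 0:
        raise InvalidInputError("gsd must be strictly positive")
    return length_m / gsd


def allometric_scalars(
    length_m: float,
    coeffs: dict[str, AllometryCoefficients] | AllometryCoefficients | None = None,
    species: str = "default",
) -> AllometricScalars:
    """Body mass and wetted surface area from total length.

    Parameters
    ----------
    length_m : float
        Total body length, metres.
    coeffs : mapping or AllometryCoefficients, optional
        Per-species coefficient table, or a single coefficient set.
        Defaults to the labelled placeholders.
    species : str
        Species key into the table; falls back to ``"default"``.
    """
    if length_m <= 0:
        raise InvalidInputError("length_m must be strictly positive")
    if coeffs is None:
        coeffs = PLACEHOLDER_ALLOMETRY
    if isinstance(coeffs, AllometryCoefficients):
        c = coeffs
    else:
        if species in coeffs:
            c = coeffs[species]
        elif "default" in coeffs:
            c = coeffs["default"]
        else:
            raise ConfigurationError(
                f"no allometry coefficients for species {species!r} and no default entry"
            )
    mass = c.mass_a * length_m**c.mass_b
    area = c.area_c * length_m**c.area_d
    return AllometricScalars(mass, area, c.provenance)
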