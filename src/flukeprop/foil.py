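"""Unsteady lifting-surface propulsion coefficients.

Maps per-beat kinematics to the two non-dimensional inputs of lunate-tail
propulsion theory — the reduced frequency sigma and the feathering
parameter theta — and returns the thrust coefficient C_T and Froude
efficiency eta.

Two interchangeable engines are provided:

* ``analytic`` (default): a two-dimensional closed form built on the
  Theodorsen lift-deficiency function ``C(k) = F(k) + iG(k)``. The
  pure-heave limit uses the classical Garrick result
  ``eta_heave = (F^2 + G^2)/F``; partial feathering is an explicit blend
  ``eta = (1 + theta)/2 + (eta_heave - 1/2)(1 - theta)`` chosen to
  satisfy all the known limits (eta -> 1 as sigma -> 0 for any theta,
  eta = 1 at theta = 1, thrust proportional to ``(1 - theta)^2`` hence
  zero for a fully feathered foil).
* ``tabulated``: bilinear interpolation of a user-supplied
  ``CoeffSurface`` — for example one digitised from published
  three-dimensional lifting-surface curves. Queries outside the grid are
  clipped to the nearest edge (flat extrapolation) with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import hankel2

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "FoilState",
    "CoeffSurface",
    "reduced_frequency",
    "feathering_parameter",
    "theodorsen",
    "foil_coefficients",
    "read_surface",
    "write_surface",
]


@dataclass(frozen=True)
class FoilState:
    """Non-dimensional and dimensional state of one oscillating-foil beat.

    ``sigma`` is the reduced frequency, ``theta`` the feathering
    parameter in [0, 1]; ``omega_rps = 2*pi*f`` is the angular fluking
    frequency, ``heave_m`` the single-sided heave amplitude and
    ``attack_rad`` the maximum fluke angle of attack.
    """

    sigma: float
    theta: float
    omega_rps: float
    chord_m: float
    heave_m: float
    attack_rad: float
    speed_mps: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")
        if not 0.0 <= self.theta <= 1.0:
            raise InvalidInputError("theta must lie in [0, 1]")

    @classmethod
    def from_kinematics(
        cls,
        f_hz: float,
        speed_mps: float,
        chord_m: float,
        heave_m: float,
        attack_rad: float,
        convention: str = "half_chord",
    ) -> "FoilState":
        """Build the foil state from per-beat kinematics."""
        omega = 2.0 * math.pi * f_hz
        sigma = reduced_frequency(f_hz, chord_m, speed_mps, convention)
        theta = feathering_parameter(attack_rad, speed_mps, omega, heave_m)
        return cls(sigma, theta, omega, chord_m, heave_m, attack_rad, speed_mps)


def reduced_frequency(
    f_hz: float, chord_m: float, speed_mps: float, convention: str = "half_chord"
) -> float:
    """Reduced frequency sigma = omega * C / (2U) (half-chord convention).

    The half-chord form matches the argument of the Theodorsen function;
    ``convention="full_chord"`` gives sigma = omega * C / U instead.
    """
    if speed_mps <= 0:
        raise InvalidInputError("speed must be strictly positive")
    if chord_m <= 0:
        raise InvalidInputError("chord must be strictly positive")
    omega = 2.0 * math.pi * f_hz
    if convention == "half_chord":
        return omega * chord_m / (2.0 * speed_mps)
    if convention == "full_chord":
        return omega * chord_m / speed_mps
    raise ConfigurationError(f"unknown reduced-frequency convention {convention!r}")


def feathering_parameter(
    attack_rad: float, speed_mps: float, omega_rps: float, heave_m: float
) -> float:
    """Feathering parameter theta = alpha * U / (omega * h), clipped to [0, 1].

    theta is the ratio of the maximum fluke pitch angle alpha to the
    maximum path angle ``omega*h/U`` of the pitching axis: 0 is pure
    heave, 1 a fully feathered (thrust-less) foil. Raw values above 1 —
    possible for slow fluking at high measured speed — are clipped with a
    warning rather than raised, since tag noise can produce them.
    """
    if omega_rps * heave_m <= 0:
        raise InvalidInputError("omega*heave must be strictly positive")
    raw = attack_rad * speed_mps / (omega_rps * heave_m)
    if raw < 0:
        raise InvalidInputError("attack angle and speed must be non-negative")
    if raw > 1.0:
        warnings.warn(
            f"feathering parameter {raw:.3f} > 1 clipped to 1 (fully feathered)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return raw


def theodorsen(k):
    """Theodorsen lift-deficiency function C(k) = F + iG.

    Computed as ``H1(2)(k) / (H1(2)(k) + i*H0(2)(k))`` with Hankel
    functions of the second kind. Accepts scalars or arrays; C(0) = 1 by
    definition (quasi-steady limit), and F -> 1/2, G -> 0 as k -> inf.
    """
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise InvalidInputError("reduced frequency k must be non-negative")
    out = np.empty(k_arr.shape, dtype=complex)
    zero = k_arr == 0
    out[zero] = 1.0 + 0.0j
    kv = k_arr[~zero]
    if kv.size:
        h1 = hankel2(1, kv)
        h0 = hankel2(0, kv)
        out[~zero] = h1 / (h1 + 1j * h0)
    if np.isscalar(k) or k_arr.ndim == 0:
        return complex(out.reshape(-1)[0])
    return out


def _analytic_ct_eta(sigma, theta, heave_m, chord_m):
    """Closed-form (C_T, eta) on the Theodorsen blend; vectorised."""
    sigma = np.asarray(sigma, dtype=float)
    theta = np.asarray(theta, dtype=float)
    c = theodorsen(sigma)
    c = np.asarray(c)
    F, G = c.real, c.imag
    mag2 = F * F + G * G
    eta_heave = np.where(F > 0, mag2 / np.where(F > 0, F, 1.0), 1.0)
    eta = (1.0 + theta) / 2.0 + (eta_heave - 0.5) * (1.0 - theta)
    half_chord = chord_m / 2.0
    ct = np.pi * sigma**2 * (heave_m / half_chord) ** 2 * mag2 * (1.0 - theta) ** 2
    return ct, eta


@dataclass
class CoeffSurface:
    """Tabulated (sigma, theta) -> (C_T, eta) surface.

    ``ct_table`` and ``eta_table`` are indexed ``[i_sigma, j_theta]``.
    eta must lie in (0, 1]; C_T must be non-negative and identically zero
    along the theta = 1 column if that column is present.
    """

    sigma_grid: np.ndarray
    theta_grid: np.ndarray
    ct_table: np.ndarray
    eta_table: np.ndarray
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        self.ct_table = np.asarray(self.ct_table, dtype=float)
        self.eta_table = np.asarray(self.eta_table, dtype=float)
        if np.any(np.diff(self.sigma_grid) <= 0) or np.any(np.diff(self.theta_grid) <= 0):
            raise InvalidInputError("surface grids must be strictly ascending")
        shape = (self.sigma_grid.size, self.theta_grid.size)
        if self.ct_table.shape != shape or self.eta_table.shape != shape:
            raise InvalidInputError(f"tables must have shape {shape}")
        if np.any(self.eta_table <= 0) or np.any(self.eta_table > 1):
            raise InvalidInputError("eta table values must lie in (0, 1]")
        if np.any(self.ct_table < 0):
            raise InvalidInputError("C_T table values must be non-negative")
        j_feathered = np.isclose(self.theta_grid, 1.0)
        if np.any(j_feathered) and not np.allclose(self.ct_table[:, j_feathered], 0.0):
            raise InvalidInputError("C_T must vanish along the theta = 1 column")

    def interpolate(self, sigma: float, theta: float) -> tuple[float, float]:
        """Bilinear interpolation; clips to the grid edges with a warning."""
        s, t = float(sigma), float(theta)
        s_lo, s_hi = self.sigma_grid[0], self.sigma_grid[-1]
        t_lo, t_hi = self.theta_grid[0], self.theta_grid[-1]
        if not (s_lo <= s <= s_hi) or not (t_lo <= t <= t_hi):
            warnings.warn(
                f"(sigma={s:.4g}, theta={t:.4g}) outside tabulated surface; "
                "clipping to grid edge (flat extrapolation)",
                RuntimeWarning,
                stacklevel=2,
            )
            s = min(max(s, s_lo), s_hi)
            t = min(max(t, t_lo), t_hi)
        i = int(np.clip(np.searchsorted(self.sigma_grid, s) - 1, 0, self.sigma_grid.size - 2))
        j = int(np.clip(np.searchsorted(self.theta_grid, t) - 1, 0, self.theta_grid.size - 2))
        ds = self.sigma_grid[i + 1] - self.sigma_grid[i]
        dt = self.theta_grid[j + 1] - self.theta_grid[j]
        u = (s - self.sigma_grid[i]) / ds
        v = (t - self.theta_grid[j]) / dt

        def bilin(tab):
            return (
                tab[i, j] * (1 - u) * (1 - v)
                + tab[i + 1, j] * u * (1 - v)
                + tab[i, j + 1] * (1 - u) * v
                + tab[i + 1, j + 1] * u * v
            )

        return float(bilin(self.ct_table)), float(bilin(self.eta_table))


def foil_coefficients(
    state: FoilState,
    engine: str = "analytic",
    surface: CoeffSurface | None = None,
) -> tuple[float, float]:
    """Thrust coefficient and Froude efficiency for one beat.

    Returns ``(C_T, eta)``. The analytic engine evaluates the Theodorsen
    closed form; the tabulated engine interpolates a ``CoeffSurface``.
    """
    if engine == "analytic":
        ct, eta = _analytic_ct_eta(state.sigma, state.theta, state.heave_m, state.chord_m)
        return float(ct), float(eta)
    if engine == "tabulated":
        if surface is None:
            raise ConfigurationError("tabulated engine requires a CoeffSurface")
        return surface.interpolate(state.sigma, state.theta)
    raise ConfigurationError(f"unknown foil engine {engine!r}")


# --- surface file format -------------------------------------------------
#
# Plain-text layout:
#   # comment lines (first stores provenance)
#   sigma: v1 v2 ...
#   theta: v1 v2 ...
#   [CT]
#   one row per sigma value, whitespace-delimited, theta across columns
#   [eta]
#   same layout


def write_surface(surface: CoeffSurface, path) -> None:
    """Write a :class:`CoeffSurface` in the documented text layout."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# flukeprop coefficient surface\n# provenance: {surface.provenance}\n")
        fh.write("sigma: " + " ".join(f"{v:.10g}" for v in surface.sigma_grid) + "\n")
        fh.write("theta: " + " ".join(f"{v:.10g}" for v in surface.theta_grid) + "\n")
        for name, tab in (("CT", surface.ct_table), ("eta", surface.eta_table)):
            fh.write(f"[{name}]\n")
            for row in tab:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_surface(path) -> CoeffSurface:
    """Read a surface written by :func:`write_surface`."""
    provenance = "user-supplied"
    sigma = theta = None
    blocks: dict[str, list[list[float]]] = {}
    current: list[list[float]] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# provenance:"):
                    provenance = line.split(":", 1)[1].strip()
                continue
            if line.startswith("sigma:"):
                sigma = np.array([float(v) for v in line.split(":", 1)[1].split()])
            elif line.startswith("theta:"):
                theta = np.array([float(v) for v in line.split(":", 1)[1].split()])
            elif line.startswith("[") and line.endswith("]"):
                current = blocks.setdefault(line[1:-1], [])
            elif current is not None:
                current.append([float(v) for v in line.split()])
            else:
                raise ConfigurationError(f"unparseable surface line: {line!r}")
    if sigma is None or theta is None or "CT" not in blocks or "eta" not in blocks:
        raise ConfigurationError("surface file missing sigma/theta grids or CT/eta blocks")
    return CoeffSurface(
        sigma, theta, np.array(blocks["CT"]), np.array(blocks["eta"]), provenance
    )
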