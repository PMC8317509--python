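"""Deployment-level model object tying the pipeline together.

:class:`SwimmingPerformance` holds one deployment's inputs (tag series,
lunge events, morphology, environment, engine choice); :meth:`fit` runs
tailbeat detection, the lifting-surface propulsion model and the per-beat
hydrodynamics, and returns a :class:`SwimmingPerformanceResults` carrying
the per-beat table, the routine-mean drag coefficient with its standard
error, QC counts and a text ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tailbeats as tb
from .exceptions import ConfigurationError, EstimationError
from .foil import CoeffSurface, FoilState, foil_coefficients
from .hydro import (
    Environment,
    HydroRecord,
    dimensionless_numbers,
    drag_coefficient_beat,
    lunge_thrust_power,
    mean_thrust_and_power,
    rigid_body_reference,
)
from .photogrammetry import WhaleMorphology
from .stats import efficiency_speed_curve
from .tailbeats import DetectionConfig, LungeEvent, QCSummary, TagSeries

__all__ = ["SwimmingPerformance", "SwimmingPerformanceResults"]

BEAT_COLUMNS = [
    "t_start_s",
    "t_end_s",
    "mode",
    "f_hz",
    "u_avg_mps",
    "delta_u_mps",
    "sigma",
    "theta",
    "ct",
    "eta",
    "thrust_n",
    "thrust_power_w",
    "mass_specific_power_wkg",
    "drag_coefficient",
    "correction_fraction",
    "reynolds",
    "strouhal",
    "cd_flagged",
]


class SwimmingPerformance:
    """Oscillatory-swimming performance model for one tagged deployment.

    Parameters
    ----------
    series : TagSeries
        10-Hz tag record (time, transverse gyro, speed, depth).
    morphology : WhaleMorphology
        Photogrammetric morphometrics of the tagged animal.
    lunges : sequence of LungeEvent or float, optional
        Lunge deceleration times.
    env : Environment, optional
        Seawater density and viscosity.
    detection : DetectionConfig, optional
        Tailbeat segmentation thresholds.
    engine : {"analytic", "tabulated"}
        Foil-coefficient engine; ``tabulated`` requires ``surface``.
    sigma_convention : {"half_chord", "full_chord"}
        Reduced-frequency convention.
    """

    def __init__(
        self,
        series: TagSeries,
        morphology: WhaleMorphology,
        lunges=(),
        env: Environment | None = None,
        detection: DetectionConfig | None = None,
        engine: str = "analytic",
        surface: CoeffSurface | None = None,
        sigma_convention: str = "half_chord",
        window_s: float = 10.0,
        filtration_s: float = 30.0,
        whale_id: str = "whale-1",
    ) -> None:
        if engine == "tabulated" and surface is None:
            raise ConfigurationError("tabulated engine requires a coefficient surface")
        if engine not in ("analytic", "tabulated"):
            raise ConfigurationError(f"unknown foil engine {engine!r}")
        self.series = series
        self.morphology = morphology
        self.lunges = [
            ev if isinstance(ev, LungeEvent) else LungeEvent(float(ev)) for ev in lunges
        ]
        self.env = env or Environment()
        self.detection = detection or DetectionConfig()
        self.engine = engine
        self.surface = surface
        self.sigma_convention = sigma_convention
        self.window_s = window_s
        self.filtration_s = filtration_s
        self.whale_id = whale_id

    @classmethod
    def from_tables(cls, tag_path, lunges_path=None, morphology=None, **kwargs):
        """Build from delimited tag and lunge-time tables (see flukeprop.io)."""
        from .io import read_lunges, read_tag_series

        series = read_tag_series(tag_path)
        lunges = read_lunges(lunges_path) if lunges_path else []
        if morphology is None:
            raise ConfigurationError("morphology (WhaleMorphology) is required")
        return cls(series, morphology, lunges=lunges, **kwargs)

    # -- pipeline stages ---------------------------------------------------

    def detect_beats(self) -> list[tb.TailbeatCycle]:
        filtered = tb.lowpass_gyro(
            self.series, self.detection.cutoff_hz, self.detection.filter_order
        )
        cycles = tb.segment_cycles(self.series.time_s, filtered, self.detection)
        cycles = tb.attach_speeds(cycles, self.series)
        cycles = tb.classify_mode(cycles, self.lunges, self.window_s, self.filtration_s)
        return cycles

    def fit(self) -> "SwimmingPerformanceResults":
        """Run detection -> foil model -> hydrodynamics and collect results."""
        cycles = self.detect_beats()
        qc = tb.deployment_qc(cycles)
        morph = self.morphology
        rows: list[dict] = []
        records: list[HydroRecord] = []

        for cyc in cycles:
            rec = HydroRecord(
                t_start_s=cyc.t_start_s,
                t_end_s=cyc.t_end_s,
                mode=cyc.mode,
                f_hz=cyc.f_hz,
                u_avg_mps=cyc.u_avg_mps if cyc.u_avg_mps is not None else np.nan,
                delta_u_mps=cyc.delta_u_mps,
                sigma=np.nan,
                theta=np.nan,
                ct=np.nan,
                eta=np.nan,
                thrust_n=np.nan,
                thrust_power_w=np.nan,
                mass_specific_power_wkg=np.nan,
                drag_coefficient=np.nan,
                correction_fraction=np.nan,
                reynolds=np.nan,
                strouhal=np.nan,
            )
            if cyc.mode != tb.EXCLUDED and cyc.u_avg_mps is not None:
                state = FoilState.from_kinematics(
                    cyc.f_hz,
                    cyc.u_avg_mps,
                    morph.fluke_chord_m,
                    morph.heave_amplitude_m,
                    morph.attack_angle_rad,
                    self.sigma_convention,
                )
                rec.sigma, rec.theta = state.sigma, state.theta
                rec.reynolds = morph.body_length_m * cyc.u_avg_mps / self.env.nu
                if cyc.mode == tb.ROUTINE:
                    rec.ct, rec.eta = foil_coefficients(state, self.engine, self.surface)
                    rec.thrust_n, rec.thrust_power_w = mean_thrust_and_power(
                        rec.ct, cyc.u_avg_mps, morph.fluke_area_m2, self.env
                    )
                    rec.drag_coefficient, rec.correction_fraction = drag_coefficient_beat(
                        rec.thrust_n, morph, cyc, self.env
                    )
                    rec.cd_flagged = rec.drag_coefficient <= 0
                    rec.strouhal, rec.mass_specific_power_wkg = dimensionless_numbers(
                        cyc.f_hz, cyc.u_avg_mps, rec.thrust_power_w, morph
                    )
            records.append(rec)

        # routine-mean drag coefficient, then lunge-beat power from it
        routine_cd = [
            r.drag_coefficient
            for r in records
            if r.mode == tb.ROUTINE and not r.cd_flagged and np.isfinite(r.drag_coefficient)
        ]
        cd_routine = float(np.mean(routine_cd)) if routine_cd else np.nan
        cd_sem = (
            float(np.std(routine_cd, ddof=1) / math.sqrt(len(routine_cd)))
            if len(routine_cd) > 1
            else np.nan
        )
        for rec, cyc in zip(records, cycles):
            if rec.mode == tb.LUNGE and cyc.u_avg_mps is not None and np.isfinite(cd_routine):
                rec.thrust_power_w = lunge_thrust_power(cd_routine, morph, cyc, self.env)
                rec.thrust_n = rec.thrust_power_w / cyc.u_avg_mps
                rec.strouhal, rec.mass_specific_power_wkg = dimensionless_numbers(
                    cyc.f_hz, cyc.u_avg_mps, rec.thrust_power_w, morph
                )

        for rec in records:
            rows.append({c: getattr(rec, c) for c in BEAT_COLUMNS})
        beats = pd.DataFrame(rows, columns=BEAT_COLUMNS)
        return SwimmingPerformanceResults(
            model=self,
            beats=beats,
            cycles=cycles,
            qc=qc,
            cd_routine=cd_routine,
            cd_routine_sem=cd_sem,
        )


@dataclass
class SwimmingPerformanceResults:
    """Fitted per-beat estimates and deployment-level summaries."""

    model: SwimmingPerformance
    beats: pd.DataFrame
    cycles: list
    qc: QCSummary
    cd_routine: float
    cd_routine_sem: float

    @property
    def routine_beats(self) -> pd.DataFrame:
        return self.beats[self.beats["mode"] == tb.ROUTINE]

    @property
    def lunge_beats(self) -> pd.DataFrame:
        return self.beats[self.beats["mode"] == tb.LUNGE]

    def rigid_body_reference(self, u_mps: float | None = None):
        """Airship-model reference drag at the routine-mean speed (or ``u_mps``)."""
        if u_mps is None:
            u_mps = float(self.routine_beats["u_avg_mps"].mean())
        return rigid_body_reference(self.model.morphology, u_mps, self.model.env)

    def efficiency_speed_curve(self, bin_width: float = 0.25) -> pd.DataFrame:
        routine = self.routine_beats.dropna(subset=["eta", "u_avg_mps"])
        return efficiency_speed_curve(routine["eta"], routine["u_avg_mps"], bin_width)

    def to_frame(self) -> pd.DataFrame:
        """Per-beat table with deployment identifiers attached."""
        out = self.beats.copy()
        out.insert(0, "whale_id", self.model.whale_id)
        out.insert(1, "species", self.model.morphology.species)
        return out

    def summary(self) -> str:
        morph = self.model.morphology
        routine = self.routine_beats
        lunge = self.lunge_beats
        lines = [
            "Swimming performance summary",
            "=" * 60,
            f"whale: {self.model.whale_id} ({morph.species}), "
            f"L = {morph.body_length_m:.2f} m, M = {morph.mass_kg:.0f} kg",
            f"deployment QC: {'included' if self.qc.included else 'EXCLUDED'} "
            f"({self.qc.n_routine} routine, {self.qc.n_lunge_associated} lunge-associated, "
            f"{self.qc.n_excluded} excluded beats)",
        ]
        if len(routine):
            lines += [
                "-" * 60,
                "routine swimming:",
                f"  f         = {routine['f_hz'].mean():.3f} Hz",
                f"  U_avg     = {routine['u_avg_mps'].mean():.2f} m/s",
                f"  eta       = {routine['eta'].mean():.3f}",
                f"  P/M       = {routine['mass_specific_power_wkg'].mean():.3f} W/kg",
                f"  St        = {routine['strouhal'].mean():.3f}",
                f"  C_D       = {self.cd_routine:.4f} "
                + (f"(s.e.m. {self.cd_routine_sem:.4f})" if np.isfinite(self.cd_routine_sem) else ""),
                f"  unsteady correction = {routine['correction_fraction'].mean() * 100:.1f}% of thrust",
            ]
            ref = self.rigid_body_reference()
            lines.append(
                f"  rigid-body reference: Re = {ref.reynolds:.3g}, C_D,mod = {ref.cd_mod:.5f}"
            )
        if len(lunge):
            lines += [
                "-" * 60,
                "lunge-associated swimming:",
                f"  f         = {lunge['f_hz'].mean():.3f} Hz",
                f"  U_avg     = {lunge['u_avg_mps'].mean():.2f} m/s",
                f"  P/M       = {lunge['mass_specific_power_wkg'].mean():.3f} W/kg",
            ]
        return "\n".join(lines)

    def plot_efficiency_speed(self, ax=None):
        """Binned Froude efficiency against swimming speed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.efficiency_speed_curve()
        if len(curve):
            ax.plot(curve["speed_mid"], curve["mean_eta"], "o-")
        ax.set_xlabel("swimming speed (m/s)")
        ax.set_ylabel("Froude efficiency")
        return ax
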