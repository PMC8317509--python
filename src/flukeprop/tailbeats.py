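"""Tailbeat segmentation and classification from tag gyroscope records.

A tailbeat cycle is detected on the low-pass-filtered (0.44 Hz) gyroscope
signal along the transverse axis. Candidate cycles run from one upstroke
onset (negative-to-positive zero crossing, after slow-drift removal) to
the next, and are kept only if the upstroke and downstroke are symmetric:
both half-stroke peak magnitudes above an amplitude floor, half-stroke
duration ratio within a band, and total period within bounds.

Cycles then receive speeds (initial, final, mean over the cycle; the tag
speed channel is only valid above 1 m/s), a mode label (routine,
lunge-associated for beats in the 10 s before a lunge deceleration,
excluded for beats during the post-lunge mouth-open/filtration period),
and the deployment passes quality control only with more than 200
usable beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidInputError

__all__ = [
    "TagSeries",
    "TailbeatCycle",
    "LungeEvent",
    "DetectionConfig",
    "QCSummary",
    "lowpass_gyro",
    "segment_cycles",
    "attach_speeds",
    "classify_mode",
    "deployment_qc",
]

ROUTINE = "routine"
LUNGE = "lunge_associated"
EXCLUDED = "excluded"

#: tag speed-from-vibration is only reliable above this speed (m/s)
SPEED_VALID_MPS = 1.0


@dataclass
class TagSeries:
    """Uniformly sampled 10-Hz tag record.

    ``speed_mps`` carries NaN where the sensor produced no estimate; the
    validity mask additionally requires speed > 1 m/s, below which the
    vibration-based speed measurement is unreliable.
    """

    time_s: np.ndarray
    gyro_y_rps: np.ndarray
    speed_mps: np.ndarray
    depth_m: np.ndarray
    sampling_hz: float = 10.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.gyro_y_rps = np.asarray(self.gyro_y_rps, dtype=float)
        self.speed_mps = np.asarray(self.speed_mps, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        n = self.time_s.size
        if any(a.size != n for a in (self.gyro_y_rps, self.speed_mps, self.depth_m)):
            raise InvalidInputError("all channels must have equal length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise InvalidInputError("time must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sampling_hz, rtol=1e-6, atol=1e-6):
                raise InvalidInputError(
                    f"time grid is not uniform at {self.sampling_hz} Hz"
                )

    @property
    def speed_valid(self) -> np.ndarray:
        return np.isfinite(self.speed_mps) & (self.speed_mps > SPEED_VALID_MPS)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.time_s.size else 0.0


@dataclass
class TailbeatCycle:
    """One segmented oscillation cycle, half-open interval [t_start, t_end)."""

    t_start_s: float
    t_end_s: float
    u_i_mps: float | None = None
    u_f_mps: float | None = None
    u_avg_mps: float | None = None
    delta_u_mps: float = np.nan
    mode: str = ROUTINE

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise InvalidInputError("t_end must exceed t_start")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    @property
    def f_hz(self) -> float:
        return 1.0 / self.duration_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.t_start_s + self.t_end_s)


@dataclass(frozen=True)
class LungeEvent:
    """Time of a lunge deceleration onset (mouth opening), seconds."""

    t_deceleration_s: float


@dataclass(frozen=True)
class DetectionConfig:
    """Segmentation thresholds.

    The amplitude floor, symmetry band and period bounds reconstruct the
    magnitude/duration/shape checks of threshold-based tailbeat
    detection; the running-median window removes DC and slow drift
    before zero-crossing detection.
    """

    cutoff_hz: float = 0.44
    filter_order: int = 3
    amplitude_floor_rps: float = 0.1
    symmetry_band: tuple[float, float] = (0.4, 2.5)
    period_bounds_s: tuple[float, float] = (1.0, 20.0)
    detrend_window_s: float = 30.0


def lowpass_gyro(series: TagSeries, cutoff_hz: float = 0.44, order: int = 3) -> np.ndarray:
    """Zero-phase low-pass filter of the transverse gyroscope channel.

    Butterworth of the given order applied forward-backward (filtfilt),
    so the output is phase-free and the effective attenuation one octave
    above the cutoff well exceeds 20 dB.
    """
    nyq = series.sampling_hz / 2.0
    if cutoff_hz <= 0 or cutoff_hz >= nyq:
        raise InvalidInputError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    if series.gyro_y_rps.size == 0:
        return series.gyro_y_rps.copy()
    b, a = sps.butter(order, cutoff_hz / nyq, btype="low")
    return sps.filtfilt(b, a, series.gyro_y_rps)


def _detrend(x: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1 or x.size == 0:
        return x
    w = min(window_samples | 1, x.size | 1)  # odd window
    from scipy.ndimage import median_filter

    return x - median_filter(x, size=w, mode="nearest")


def segment_cycles(
    time_s: np.ndarray,
    filtered: np.ndarray,
    config: DetectionConfig | None = None,
) -> list[TailbeatCycle]:
    """Segment a filtered gyro signal into tailbeat cycles.

    Cycle boundaries are upstroke onsets (negative-to-positive zero
    crossings of the detrended signal), located with sub-sample linear
    interpolation. A candidate cycle is kept only if

    1. both half-stroke peak magnitudes reach the amplitude floor,
    2. the up/down half-stroke duration ratio lies in the symmetry band,
    3. the total period lies within the period bounds.
    """
    if config is None:
        config = DetectionConfig()
    time_s = np.asarray(time_s, dtype=float)
    x = np.asarray(filtered, dtype=float)
    if x.size < 3:
        return []
    dt = time_s[1] - time_s[0]
    x = _detrend(x, int(round(config.detrend_window_s / dt)))

    s = np.sign(x)
    s[s == 0] = 1.0
    flips = np.nonzero(np.diff(s))[0]  # crossing between i and i+1
    if flips.size < 3:
        return []
    # sub-sample crossing times by linear interpolation
    t_cross = time_s[flips] + dt * x[flips] / (x[flips] - x[flips + 1])
    rising = x[flips] < 0  # negative-to-positive

    cycles: list[TailbeatCycle] = []
    up_idx = np.nonzero(rising)[0]
    lo, hi = config.symmetry_band
    p_lo, p_hi = config.period_bounds_s
    for a_pos in up_idx:
        if a_pos + 2 >= flips.size:
            break
        b_pos = a_pos + 1  # next crossing: positive-to-negative
        c_pos = a_pos + 2  # next upstroke onset
        if rising[b_pos] or not rising[c_pos]:
            continue  # malformed alternation (shouldn't happen)
        t0, t1, t2 = t_cross[a_pos], t_cross[b_pos], t_cross[c_pos]
        seg_up = x[flips[a_pos] + 1 : flips[b_pos] + 1]
        seg_dn = x[flips[b_pos] + 1 : flips[c_pos] + 1]
        if seg_up.size == 0 or seg_dn.size == 0:
            continue
        peak_up = float(np.max(seg_up))
        peak_dn = float(-np.min(seg_dn))
        if peak_up < config.amplitude_floor_rps or peak_dn < config.amplitude_floor_rps:
            continue
        dur_up, dur_dn = t1 - t0, t2 - t1
        if dur_dn <= 0 or not (lo <= dur_up / dur_dn <= hi):
            continue
        period = t2 - t0
        if not (p_lo <= period <= p_hi):
            continue
        cycles.append(TailbeatCycle(t_start_s=t0, t_end_s=t2))
    return cycles


def attach_speeds(cycles: list[TailbeatCycle], series: TagSeries) -> list[TailbeatCycle]:
    """Attach initial/final/mean speeds to each cycle.

    A cycle containing any invalid speed sample in its window, or with a
    mean speed at or below 1 m/s, is flagged ``excluded`` (not dropped).
    """
    valid = series.speed_valid
    t = series.time_s
    for cyc in cycles:
        sel = (t >= cyc.t_start_s) & (t < cyc.t_end_s)
        if not np.any(sel):
            cyc.mode = EXCLUDED
            continue
        sp = series.speed_mps[sel]
        ok = valid[sel]
        if not np.all(ok):
            cyc.mode = EXCLUDED
            continue
        cyc.u_i_mps = float(sp[0])
        cyc.u_f_mps = float(sp[-1])
        cyc.u_avg_mps = float(np.mean(sp))
        cyc.delta_u_mps = cyc.u_f_mps - cyc.u_i_mps
        if cyc.u_avg_mps <= SPEED_VALID_MPS:
            cyc.mode = EXCLUDED
    return cycles


def classify_mode(
    cycles: list[TailbeatCycle],
    lunges: list[LungeEvent],
    window_s: float = 10.0,
    filtration_s: float = 30.0,
) -> list[TailbeatCycle]:
    """Label cycles routine / lunge_associated / excluded.

    A cycle intersecting any ``[t_lunge - window_s, t_lunge)`` interval is
    lunge-associated; a cycle intersecting ``[t_lunge, t_lunge +
    filtration_s]`` is excluded (the whale's mouth is open or it is
    filtering, so any fluking there carries engulfment drag); all other
    cycles are routine. Cycles already excluded by the speed mask stay
    excluded.
    """
    if window_s < 0 or filtration_s < 0:
        raise InvalidInputError("window and filtration durations must be non-negative")
    times = sorted(ev.t_deceleration_s for ev in lunges)
    for cyc in cycles:
        if cyc.mode == EXCLUDED:
            continue
        mode = ROUTINE
        for tl in times:
            if cyc.t_start_s < tl and cyc.t_end_s > tl - window_s:
                mode = LUNGE
                break
            if cyc.t_start_s <= tl + filtration_s and cyc.t_end_s > tl:
                mode = EXCLUDED
                break
        cyc.mode = mode
    return cycles


@dataclass(frozen=True)
class QCSummary:
    included: bool
    n_total: int
    n_routine: int
    n_lunge_associated: int
    n_excluded: int


def deployment_qc(cycles: list[TailbeatCycle], min_beats: int = 200) -> QCSummary:
    """Deployment inclusion rule: strictly more than ``min_beats`` usable beats."""
    n_routine = sum(1 for c in cycles if c.mode == ROUTINE)
    n_lunge = sum(1 for c in cycles if c.mode == LUNGE)
    n_excluded = sum(1 for c in cycles if c.mode == EXCLUDED)
    usable = n_routine + n_lunge
    return QCSummary(
        included=usable > min_beats,
        n_total=len(cycles),
        n_routine=n_routine,
        n_lunge_associated=n_lunge,
        n_excluded=n_excluded,
    )
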