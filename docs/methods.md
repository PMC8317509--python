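# Methods

This note documents the models implemented in `flukeprop`, their
assumptions, the synthetic-data generator, and the numerical and design
choices made where the problem was genuinely open.

## Propulsion model

Lunate-tail propulsion is modelled as a two-dimensional oscillating foil
in the framework of unsteady thin-airfoil theory. Two non-dimensional
inputs summarise a tailbeat:

* **Reduced frequency** σ = ωC/(2U), with ω = 2πf the angular fluking
  frequency, C the fluke chord and U the beat-mean swimming speed. The
  half-chord convention matches the argument of the Theodorsen function;
  a `full_chord` switch (σ = ωC/U) is provided because both conventions
  circulate in the literature.
* **Feathering parameter** θ = αU/(ωh) ∈ [0, 1]: the ratio of the
  maximum fluke pitch angle α to the maximum path angle ωh/U of the
  pitching axis at heave amplitude h. θ = 0 is pure heave; θ = 1 a fully
  feathered foil that produces no thrust. Raw values above 1 (slow
  fluking at high measured speed; possible under tag noise) are clipped
  to 1 with a per-beat warning rather than raised.

The **analytic engine** (default) evaluates the Theodorsen
lift-deficiency function C(k) = F + iG = H₁⁽²⁾(k) / (H₁⁽²⁾(k) + iH₀⁽²⁾(k))
at k = σ and combines the classical pure-heave (Garrick) Froude
efficiency η_heave = (F² + G²)/F with an explicit feathering blend:

    η  = (1 + θ)/2 + (η_heave − ½)(1 − θ)
    C_T = π σ² (h/(C/2))² (F² + G²) (1 − θ)²

The blend is an approximation chosen to satisfy every limit the theory
fixes: η → 1 as σ → 0 for any θ (quasi-steady ideal), η = 1 at θ = 1
(ideal feathering), thrust ∝ (1 − θ)² and hence zero at θ = 1, and
monotone behaviour in θ (η non-decreasing because η_heave ≤ 1; C_T
non-increasing). It is *not* the full three-dimensional lifting-surface
computation; published digitised curves for finite-aspect-ratio flukes
can be supplied instead through the **tabulated engine**, which
bilinearly interpolates a plain-text (σ, θ) → (C_T, η) surface
(documented layout in `flukeprop.foil`; queries outside the grid clip to
the nearest edge with a warning).

For a routine blue-whale-scale beat (f = 0.18 Hz, U = 2.20 m/s,
L = 22.41 m, α = 30°, h = L/5, C = 1.2 m: σ ≈ 0.308, θ ≈ 0.227) the
analytic engine gives η ≈ 0.775 — inside the >75% efficiency class
reported for oscillatory swimmers, and the quantity
`scripts/acceptance.py` recomputes.

### Defaults taken as field-validated estimates

* attack angle α = 30° (observed range ≈ 20–40°); configs accept degrees,
  radians internally;
* heave amplitude h = L/5, single-sided, used directly in ωh/U;
* added-mass coefficient k_added = 0.03 (0.05 is the humpback value;
  species not covered by the source literature default to 0.03,
  override-able).

## Per-beat hydrodynamics

With C_T from the engine, mean thrust and power over a beat are
T̄ = ½ρU²F_a C_T and P̄ = T̄U (F_a fluke planform area; seawater
ρ = 1025 kg m⁻³, ν = 1.05·10⁻⁶ m² s⁻¹ by default, both configurable).
The beat-averaged equation of motion M(1+k_added)ΔU/T_beat = T̄ − D̄
with D̄ = ½ρS_a C_D U² yields

    C_D = [T̄ − M(1+k_added)ΔU/T_beat] / (½ρS_a U²)

whose second numerator term is the unsteadiness correction (reported as
|term₂|/|term₁|). ΔU = U_f − U_i is taken from the first/last valid
speed samples in the beat window, per the tag-analysis convention.
Negative C_D values (strong decelerations) are retained but flagged;
only the routine-mean C_D excludes them. Lunge-associated thrust power
inverts the same relation using the routine-mean C_D — an exact
algebraic inverse, which the test suite verifies to 10⁻¹⁰.

The rigid-body reference uses the Hoerner streamlined-body correlation
with turbulent flat-plate skin friction, C_f = 0.072 Re^(−1/5),
C_D,mod = C_f[1 + 1.5(W/L)^1.5 + 7(W/L)³]; this reconstruction (constants
from the airship literature) is decreasing in Re and increasing in
fineness W/L. Strouhal number uses wake-width amplitude A = 0.2L (total
excursion convention); a switch selects A = 2h.

## Tailbeat detection

The transverse gyroscope channel is low-pass filtered at 0.44 Hz
(3rd-order Butterworth, forward-backward for zero phase; ≥ 20 dB one
octave above cutoff), then detrended by subtracting a 30-s running
median (the filter passes DC; the source method is silent on
detrending). Cycles run from one upstroke onset (negative→positive zero
crossing, sub-sample interpolated) to the next and are kept only if
both half-stroke peaks reach 0.1 rad/s, the half-stroke duration ratio
lies in [0.4, 2.5], and the period lies in [1, 20] s — a reconstruction
of the magnitude/duration/shape symmetry thresholds, all exposed in
`DetectionConfig`. Speeds below 1 m/s are invalid (vibration-based tag
speed is unreliable there); a beat containing invalid samples or with
mean speed ≤ 1 m/s is excluded. Beats intersecting the 10 s before a
lunge deceleration are lunge-associated; beats in the following 30 s
(mouth open/filtration — duration not specified at source; 30 s default)
are excluded; deployments need > 200 usable beats to pass QC.

## Synthetic deployments

The generator emulates a routine deployment of a cruising rorqual with
occasional feeding lunges. Defaults state a blue-whale-scale world:
L = 22.41 m, f = 0.18 Hz, U = 2.20 m/s, C_D,true = 0.02, gyro amplitude
0.4 rad/s with Gaussian noise sd 0.04 rad/s (SNR 10), 300 routine beats,
2 lunges, 10 Hz sampling. The speed obeys
M(1+k_added)dU/dt = T(t) − ½ρS_a C_D,true U², integrated with a
fixed-step explicit Euler scheme at the sampling rate (adequate for
these smooth dynamics; the unit tests verify the constant-thrust fixed
point exactly and thrust–drag balance at cruise to <1%). Within a beat
T(t) = 2T̄ sin²(φ) — non-negative with cycle mean T̄; intra-beat speed
oscillation follows from this waveform (a `constant` waveform switch
turns it off, since no measured intra-beat amplitude is available to
assert).

**Self-consistency calibration.** T̄ defaults to the analytic engine's
own prediction at the instantaneous speed and frequency, and
`sample_morphology` rescales the fluke area so this thrust balances
C_D,true drag exactly at cruise. Without this step the configured drag
coefficient would not be a recoverable property of the simulated world
(the estimator's thrust would systematically differ from the
simulator's). The calibration is part of the stated world, fixed before
any testing; it requires a coherent configuration (a fluking frequency /
speed / length combination whose feathering parameter stays below 1).

Lunges raise the fluking frequency by 0.102 Hz (the observed mean
routine-to-lunge increase) for the ~10 s before the lunge time — the
higher frequency raises foil thrust and the body accelerates — then
fluking stops for 30 s while drag triples (engulfment), decelerating the
body rapidly. Pre-lunge windows hold an integer number of beats, so
ground-truth boundaries are exact.

What the generator does **not** emulate: 3-D body kinematics,
depth-dependent buoyancy, speed-measurement noise (off by default so
recovery tests isolate estimator error), non-stationary fluking
frequency within a mode, or engulfment-phase fluking. A green recovery
test therefore establishes estimator correctness under the model's own
assumptions, not robustness to real-tag artefacts.

Known numerical effect: sampling U_i/U_f at the first/last 10-Hz sample
of a beat (rather than the exact boundary) aliases the intra-beat speed
oscillation into ΔU and biases recovered C_D by ≈ −1.8% in the default
world — within the 2% noiseless recovery criterion and documented here
rather than patched, since the estimator mirrors what real tag data
permit.

## Aggregation and scaling

Whale/mode-level summaries report mean ± s.e.m. (sd/√n). Allometric
relations are fitted by OLS on log10 axes (slope = scaling exponent, with
SE and 95% CI from `statsmodels`); mixed-effects models and GAM
smoothers used in field analyses are out of scope. The efficiency–speed
curve uses 0.25 m/s bins over [1, 5] m/s, flagging bins with < 5 beats.

Photogrammetry converts pixel measurements to metres via the ground
sampling distance GSD = a·S_w/(l_foc·P_w). Mass and wetted-area
power-law coefficients are species-specific literature values that the
package cannot ship; the defaults (mass 10·L³, S_a 0.4·L²) are labelled
placeholders for synthetic work, and scientific use requires explicit
coefficients.

## Limitations

* The analytic engine is 2-D; finite-aspect-ratio and 3-D effects enter
  only through a user-supplied tabulated surface.
* α and h are validated estimates, not per-beat measurements; η and C_T
  inherit their uncertainty.
* Lunge times are inputs; no automatic lunge detection.
* No engulfment-drag model, metabolic conversion, or raw tag-format
  decoding.
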