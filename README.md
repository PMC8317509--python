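# flukeprop

Oscillatory swimming kinematics and hydrodynamics of large baleen whales,
estimated from animal-borne tag records and drone photogrammetry.

Rorqual whales (blue, fin, sei, Bryde's, humpback, Antarctic minke) swim by
heaving a high-aspect-ratio fluke — lunate-tail propulsion, the same
mechanism as thunniform fish and dolphins, but at body masses up to ~10⁵ kg.
`flukeprop` takes a 10-Hz biologging record (transverse-axis gyroscope,
speed, depth), the times of feeding lunges, and photogrammetric
morphometrics, and estimates per tailbeat:

* **thrust coefficient C_T and Froude efficiency η** from unsteady
  lifting-surface theory, driven by the reduced frequency
  σ = ωC/(2U) and the feathering parameter θ = αU/(ωh)
  (ω = 2πf fluking angular frequency, C fluke chord, h heave amplitude,
  α fluke attack angle, U swimming speed);
* **mean thrust and thrust power** T̄ = ½ρU²F_a·C_T, P̄ = T̄·U;
* **drag coefficient with an unsteadiness correction**, from the
  beat-averaged equation of motion
  M(1+k_added)·ΔU/T_beat = T̄ − ½ρS_a·C_D·U²,
  so C_D = [T̄ − M(1+k_added)ΔU/T_beat]/(½ρS_a U²);
* **lunge-associated thrust power** by inverting that relation with the
  routine-mean drag coefficient;
* Strouhal number, Reynolds number, mass-specific power, and a rigid-body
  (airship) reference drag coefficient for comparison.

Tailbeats are segmented from the low-pass-filtered (0.44 Hz) gyroscope
signal with symmetry thresholds, classified as routine or lunge-associated
(the 10 s before each lunge deceleration), and a deployment must yield
more than 200 usable beats to pass quality control. A synthetic-deployment
generator with known ground truth (beat schedule, drag coefficient)
replaces field data for testing and validation.

## Worked example

```python
import flukeprop as fp

cfg = fp.SimConfig(seed=1)                     # blue-whale-scale deployment
morph, series, truth = fp.generate_deployment(cfg)

model = fp.SwimmingPerformance(series, morph, lunges=truth.lunge_times,
                               whale_id="sim-1")
results = model.fit()
print(results.summary())
```

prints

```
Swimming performance summary
============================================================
whale: sim-1 (synthetic-blue), L = 22.41 m, M = 112545 kg
deployment QC: included (295 routine, 6 lunge-associated, 4 excluded beats)
------------------------------------------------------------
routine swimming:
  f         = 0.180 Hz
  U_avg     = 2.18 m/s
  eta       = 0.772
  P/M       = 0.194 W/kg
  St        = 0.370
  C_D       = 0.0197 (s.e.m. 0.0000)
  unsteady correction = 3.1% of thrust
  rigid-body reference: Re = 4.66e+07, C_D,mod = 0.00251
------------------------------------------------------------
lunge-associated swimming:
  f         = 0.270 Hz
  U_avg     = 2.71 m/s
  P/M       = 0.543 W/kg
```

Reading the numbers: the 22.4-m whale flukes at 0.18 Hz while cruising at
2.2 m/s, with Froude efficiency 0.77 (useful thrust power over total
mechanical power — in the >75% class expected of efficient oscillatory
swimmers) and Strouhal number 0.37, near the efficient 0.25–0.35 band. The
estimated routine drag coefficient (0.0197) recovers the simulator's
ground truth (0.02) and is ~8× the rigid-body reference (0.0025): an
actively heaving body pays far more drag than a towed hull of the same
shape. Mass-specific thrust power roughly triples from routine swimming to
the accelerating tailbeats before a lunge.

The per-beat table is `results.beats` (a pandas DataFrame);
`results.efficiency_speed_curve()` bins η over speed, and
`flukeprop.loglog_scaling_fit` fits allometric exponents across whales.

A CLI wraps the same pipeline:

```sh
flukeprop simulate --seed 1 --out dep/        # tag.csv, lunges.csv, truth.csv, morphology.yaml
flukeprop hydro dep/tag.csv --morph dep/morphology.yaml --lunges dep/lunges.csv
flukeprop run --simulate --seed 1 --out results_dir/
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch through the public API,
the Froude efficiency of a routine blue-whale-scale tailbeat built from
printed parameter values (f = 0.18 Hz, U = 2.20 m/s, L = 22.41 m,
α = 30°, h = L/5, chord 1.2 m), and writes it (in percent) as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, its assumptions, the synthetic-data
generator and all numerical choices.
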