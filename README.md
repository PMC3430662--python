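# tahill

Subject-specific tendon–aponeurosis properties in an EMG-driven Hill-type
model of the ankle.

Most neuromusculoskeletal models describe the series elastic element (SEE) of
a Hill-type muscle — the tendon plus aponeurosis — with one generic
force–strain curve derived from in-vitro tendon tests. In vivo, tendon and
aponeurosis have different stiffnesses and both vary widely between people,
and the SEE's compliance controls how much of a movement's length change the
tendon absorbs versus the muscle fibre (the fibre/MTU *decoupling* that
shapes force production in hopping and running). `tahill` is a library and
CLI for researchers in muscle physiology and biomechanics who want to:

1. characterize a subject's tendon and aponeurosis force–strain curves from
   an isometric ramp, using ultrasound-tracked landmarks and the measured
   joint moment;
2. combine the two tissues into one equivalent tendon–aponeurosis (T-A)
   series element per muscle via rest-length ratios;
3. drive a Hill-type model of the plantar/dorsi-flexors (GL, GM, SOL, TA)
   with processed EMG, calibrate it against inverse-dynamics moments, and
   predict moments, muscle forces and fibre/SEE behaviour on novel trials —
   with either the generic or the subject-specific SEE.

A synthetic-data module generates subjects, isometric ramps, hopping and
running-like trials and speckle ultrasound sequences with known ground
truth, so the full pipeline is testable without human recordings.

## The model in brief

Tissue strains come from tracked lengths: tendon strain
`ε_t = (L_t − L_t0)/L_t0`, aponeurosis length from the series-path geometry
`L_a = L_mt − L_t − L_f·cos α`, and aponeurosis strain likewise. Normalized
force is the joint moment over its isometric-task maximum. Each tissue gets a
monotone quadratic force–strain fit through the origin, and the series
combination

    ε_TA(F) = r·ε_t(F) + (1 − r)·ε_a(F),    r = L_t0/(L_t0 + L_a0)

defines a muscle-specific T-A curve (exact for two springs sharing one
force). In the Hill model, fibre force (active force–length–velocity plus
passive, pennation from constant thickness) is balanced against SEE force at
every time step by a bracketed root solve, and SEE forces times moment arms
sum to the net ankle moment. Calibration tunes bounded per-subject parameters
(maximal-force scales, activation nonlinearity, optionally more) by seeded
multi-start Powell search to match inverse-dynamics moments; prediction
reports R², RMS error, peak forces, and max−min variations of fibre length,
fibre velocity and SEE length. See `docs/methods.md` for the full model.

## Worked example

```python
import tahill as th

subject = th.make_subject(1)                       # synthetic subject, known truth
ramp = th.simulate_isometric_ramp(subject, seed=1)
fit = th.characterize_ramp(
    ramp.series.time, ramp.series.net_moment, ramp.tendon_length_mm,
    ramp.mt_length_mm, ramp.fascicle_length_mm, ramp.pennation_rad,
    subject.rest_geometry[th.MuscleId.GM])
print(f"GM rest-length ratio          : {fit.ratio:.2f}")
print(f"tendon strain at peak force   : {float(fit.tendon.strain_at(1.0)):.4f}")
print(f"aponeurosis strain at peak    : {float(fit.aponeurosis.strain_at(1.0)):.4f}")
print(f"combined T-A strain at peak   : {float(fit.ta_combined.strain_at(1.0)):.4f}")
```

```
GM rest-length ratio          : 0.46
tendon strain at peak force   : 0.0727
aponeurosis strain at peak    : 0.0469
combined T-A strain at peak   : 0.0588
```

The aponeurosis is stiffer than the tendon (smaller strain at the same
force), and the combined T-A strain lies between the two, weighted by the
rest-length ratio. Calibrating the EMG-driven model on one hop and one run
and predicting a held-out hop:

```python
from dataclasses import replace
from tahill.calibration import CalibrationSpec, calibrate, predict

base = {m: replace(p, f_max=p.f_max / 1.3)         # deliberately mis-scaled start
        for m, p in subject.muscle_params.items()}
cal = [th.simulate_dynamic_trial(subject, "hop", seed=11).series,
       th.simulate_dynamic_trial(subject, "run", seed=12).series]
novel = [th.simulate_dynamic_trial(subject, "hop", seed=21).series]
spec = CalibrationSpec(free_parameters=("f_max_scale", "shape_factor"),
                       seed=0, n_starts=2, max_evaluations=120)
result = calibrate(spec, cal, subject.see_ss, base)
metrics = predict(result, novel, subject.see_ss)[0].metrics
print(f"held-out hop moment R^2       : {metrics.r_squared:.3f}")
print(f"held-out RMS error            : {metrics.rms_error:.2f} N.m")
print(f"peak soleus force             : {metrics.max_force[th.MuscleId.SOL]:.0f} N")
print(f"soleus SEE length variation   : {metrics.see_length_variation[th.MuscleId.SOL]:.1f} mm")
```

```
held-out hop moment R^2       : 1.000
held-out RMS error            : 1.20 N.m
peak soleus force             : 2550 N
soleus SEE length variation   : 18.1 mm
```

With the matched subject-specific SEE the calibrated model reproduces the
held-out moment almost exactly; swapping in the stiffer generic SEE on the
same trials lowers held-out R² and flips the fibre/SEE behaviour pattern
(less SEE stretch, more fibre excursion and velocity) — the mechanism the
subject-specific characterization exists to capture.

The same pipeline is scriptable from the shell:

```sh
tahill simulate --seed 1 --outdir subj1          # subject + ramp + hop/run CSVs
tahill characterize --ramp subj1/ramp_trial.csv \
       --rest subj1/rest_geometry.csv --out subj1/fitted_curves.json
tahill calibrate --config calib.yaml --out results.json
```

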