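# Methods

`tahill` implements an EMG-driven neuromusculoskeletal model of the ankle
plantar/dorsi-flexors whose series elastic element (SEE) can be either the
classic generic in-vitro tendon curve or a subject-specific
tendon–aponeurosis (T-A) force–strain relationship characterized in vivo
from ultrasound landmarks. This note records the model, the numerical
choices, the synthetic study conditions, and what the tests do and do not
demonstrate.

## Tendon–aponeurosis characterization

During an isometric plantar-flexion ramp the joint moment rises from rest to
its maximum while the tendon and aponeurosis of the imaged muscle (the medial
gastrocnemius, GM) stretch. Strains are engineering strains relative to the
rest lengths,

    ε_t = (L_t − L_t0) / L_t0,        ε_a = (L_a − L_a0) / L_a0,

with the aponeurosis length obtained from the series-path geometric model of
the muscle–tendon complex,

    L_a = L_mt − L_t − L_f · cos α,

where `L_mt` is the muscle-tendon length, `L_f` the fascicle length and `α`
the pennation angle. The GM moment arm and its relative contribution to the
ankle moment are treated as constant over the ramp, so the **normalized
force** is the measured moment divided by its task maximum. Force–strain
relationships are second-order polynomials of normalized force against
strain, fitted by least squares and **constrained through the origin** (zero
strain carries zero force — the strain definitions make any intercept
unphysical). Fits must be strictly monotone on the observed strain range;
beyond that range the curve continues along its tangent at the largest
observed strain (configurable to clamping), which avoids the non-monotone
rollover a raw quadratic can have.

Tendon and aponeurosis act as two springs in series sharing one force, so the
equivalent T-A element satisfies

    ε_TA(F) = r · ε_t(F) + (1 − r) · ε_a(F),      r = L_t0 / (L_t0 + L_a0),

which is an exact identity for series springs (total elongation over total
rest length). A muscle-specific `r` computed from each muscle's rest lengths
transfers the GM-derived tissue curves to the lateral gastrocnemius and
soleus; the tibialis anterior uses a fixed literature ratio of 0.5 and needs
no rest lengths. A fresh quadratic through the origin is refitted through the
combined strain points on a 21-point force grid; the refit error is far below
measurement noise. Curve inversion (force → strain) is analytic on the
quadratic with a bracketed root-finding fallback, verified to 1e-10 in
normalized force.

Samples with strain below −0.05 are rejected with a warning (measurement
artefacts); mildly negative strains are retained so noise around zero does
not bias the fit.

**Normalization convention.** Because the measured moment is normalized by
its *task* maximum, the characterization recovers force–strain curves on the
task-normalized force scale. The synthetic ramp stores its ground truth on
that same scale (true coefficients divided by the peak normalized SEE force
reached at full activation); with maximal effort the two scales coincide up
to the fibre's force-generating capacity at its shortened length.

## Ultrasound landmark tracking

Landmarks (muscle–tendon junction, aponeurosis and fascicle endpoints) are
tracked frame to frame by normalized cross-correlation (NCC): the template
around the current landmark is scored against every integer-pixel
displacement inside a search window of the next frame; the argmax becomes the
new position and the template is refreshed from the matched frame
(configurable to a fixed template). Ties are broken deterministically by
smallest displacement magnitude, then row-major order. Tracking is
integer-pixel only; sub-pixel refinement is out of scope (clinical practice
pairs this tracker with manual adjustment). Default window sizes (11×11 px
template, ±10 px search) are pragmatic defaults, exposed as parameters.

Each aponeurosis is the line through its two tracked endpoints; the fascicle
line is extended to its intersections with the superficial and deep
aponeurosis lines (fascicles rarely fit in the imaging window), the distance
between intersections is the fascicle length, and the pennation angle is the
acute angle between the fascicle and the deep aponeurosis. Fascicle curvature
is neglected. With two tracked fascicles the per-frame values are averaged.

## EMG processing and activation dynamics

Raw EMG is band-pass filtered (10–500 Hz, 4th-order Butterworth, zero-lag),
full-wave rectified, low-pass filtered (6 Hz, 4th-order Butterworth,
zero-lag) and divided by the subject's per-muscle maximal envelope across all
trials, then clipped to [0, 1]. Excitation becomes activation via the
second-order discrete recursion

    u_t = α e_{t−d} − β1 u_{t−1} − β2 u_{t−2},
    β1 = γ1 + γ2,  β2 = γ1 γ2,  α = 1 + β1 + β2  (unit DC gain),

with poles constrained by |γ| < 1 for stability and an electromechanical
delay `d` quantized to whole samples (default 40 ms at the 125 Hz kinematics
rate, calibratable), followed by the exponential shaping
`a = (e^{Au} − 1)/(e^{A} − 1)` with shape factor `A ∈ [−3, 0)` (the `A → 0`
limit is the identity). Activations are floored at 0.01 by default to keep
the contraction dynamics well-posed.

## Hill-type contraction dynamics

The fibre is a contractile element with Gaussian active force–length
(width 0.45), an exponential passive curve rising from optimal length
(reaching the maximal isometric force at 60% passive strain), and a Hill
force–velocity curve (curvature 0.25, eccentric plateau 1.4, maximal
shortening velocity 10 optimal lengths/s), in series with the SEE; all shape
constants are module-level and configurable. A parallel damping term (0.1 of
maximal force per unit normalized velocity, configurable to zero) stabilizes
the root solve at very low activation. Pennation follows the
constant-thickness model `L_f sin α = L_opt sin α_opt`.

At each time step the fibre length solves

    f_max (a·f_l·f_v + f_p + d·ṽ) · cos α = f_max · F̃_SEE(ε),

with the fibre velocity entering implicitly through a backward finite
difference (first step static). The solver is a bisection-safeguarded secant
(Illinois) on the fibre-length bracket [0.3, 1.8]·L_opt, warm-started from
the previous step's solution, tolerance 1e-10 mm; the accepted residual must
be ≤ 0.1 N. A slack SEE with a force-free fibre is resolved to zero force
with the fibre resting at its previous length (capped at optimum); a slack
SEE with appreciable activation has no equilibrium in the bracket and raises
an error naming the step. The generic SEE is the exponential-toe/linear
tendon curve (toe force 0.33, shape 3, toe end at 0.609 of the strain at
maximal force, linear stiffness 1.712 per unit reference strain), rescaled so
normalized force is exactly 1 at the reference strain (default 0.033,
configurable). The SEE force (equal to the fibre force along the tendon at
equilibrium) times the moment arm, summed over muscles with plantar-flexors
positive and the dorsi-flexor negative, gives the net ankle moment.

## Calibration and prediction

Calibration minimizes the summed squared difference between the model moment
and the inverse-dynamics reference across the configured trials (one hop and
one run by default, jointly). The free-parameter set is configurable; the
default tunes per-muscle maximal-force scales and the shared activation shape
factor, with optional optimal-fibre-length and SEE-rest-length scales and
recursion poles, all within bounds (force scale [0.5, 2], length scales
[0.85, 1.15] and [0.9, 1.1], A [−3, −0.001], poles (−1, 1)). The search is
derivative-free: bounded Powell refinement from a seeded Latin-hypercube set
of starts plus the neutral point, evaluation-capped, deterministic per seed.
An equilibrium failure inside an evaluation scores a large finite penalty
(1e9). Prediction freezes the fitted parameters, forward-runs held-out
trials, and reports R² (coefficient of determination, negative values
reported as-is), RMS error, moment extrema, per-muscle peak force, and
max−min variations of fibre length, fibre velocity and SEE length.

## Synthetic study conditions

The generator stands in for the human recordings and defines the conditions
under which the pipeline is validated.

* **Subjects.** Rest geometry is drawn per muscle from normative ultrasound
  means ± SD (truncated at 2 SD, positivity enforced). GM tendon and
  aponeurosis quadratics place normalized force 1 at strains of about 0.09
  and 0.054 respectively (±8% per-subject jitter, 30% linear toe share): the
  aponeurosis is stiffer than the tendon, and the combined T-A elements are
  roughly twice as compliant as the generic 0.033 curve. Maximal forces are
  ~700/1400/3200/650 N (GL/GM/SOL/TA, ±10%). Fibres rest at 1.15 optimal
  lengths and shorten toward optimum under load, as plantar-flexor fascicles
  do; pennation at optimum follows from constant thickness.
* **Isometric ramp.** Constant muscle-tendon length, smoothstep activation
  0 → 1 over 4 s at 125 Hz; tendon and aponeurosis lengths are emitted by
  inverting the true tissue curves at the solved SEE force, so the
  characterization stage faces an exactly invertible (and, with 0.5 mm
  Gaussian length noise, realistically perturbed) problem.
* **Dynamic trials.** Hop cycles of 0.5 s (run 0.7 s); plantar-flexor MTU
  lengths follow taut-tendon stretch–shorten waveforms oscillating *above*
  rest length with peak-to-peak excursions of 28/28/21 mm (GL/GM/SOL; run
  ×1.3) — commensurate with the SEE stretch at peak force, which is what lets
  a compliant tendon absorb the excursion; the dorsi-flexor moves in
  antiphase at half amplitude. EMG-like envelopes are periodic Gaussian
  bursts (peaks 0.54/0.72/0.81/0.27, baseline 0.1, width 0.18 cycles)
  centred at peak MTU stretch; activation then peaks during late stretch and
  early shortening once the electromechanical delay and filter lag are
  applied, as hopping EMG does relative to ground contact. Moment arms are
  44/48/52/40 mm with a 4% within-cycle modulation. Default trial length 3 s
  at 125 Hz keeps forward solves fast while covering six hop cycles.
  Envelope noise is multiplicative log-normal (positivity-preserving),
  applied only to the stored envelopes — the reference moment remains the
  noise-free forward solution, mirroring EMG measurement noise.
* **Speckle sequences.** A seeded smoothed-noise texture with a bright
  junction-like blob is translated along an integer-pixel path; every frame
  is an exact translate of the first, so integer-exact tracking is the
  correct answer, not an approximation.

What passing these conditions does **not** show: robustness to out-of-plane
probe motion, speckle decorrelation or contrast changes in real B-mode video;
moment-arm or muscle-path model error; EMG crosstalk or electrode lift; or
tasks whose activation–length phase relation differs qualitatively from
hopping/running. The generator shares its muscle model with the estimator by
design (an inverse-crime validation): recovery results certify the pipeline's
internal consistency and identifiability, not model adequacy for real limbs.

## Known limitations

* Integer-pixel tracking bounds landmark accuracy at half a pixel; fascicle
  geometry inherits that error.
* The quadratic T-A form cannot represent a concave-up-to-linear transition
  sharper than its single curvature parameter allows.
* The constant-thickness pennation model degrades for fibre lengths below
  ~0.35 optimal lengths, where the implied sine would exceed 1 and is
  clamped.
* Calibrating only force scales and the activation shape factor leaves
  residual parameter ambiguity (force scales trade off against each other at
  the moment level); held-out moment R² is the meaningful recovery metric,
  not per-parameter error.
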