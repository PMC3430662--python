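"""Synthetic subjects, trials and ultrasound sequences with known ground
truth.

Every stage of the pipeline is exercised against data whose generating model
is known exactly: subjects are sampled around normative rest geometry with
quadratic tendon/aponeurosis curves (aponeurosis stiffer than tendon, and the
combined T-A element 2-3x more compliant than the generic in-vitro curve);
isometric ramps are forward-solved with the true Hill parameters so the
characterization stage can invert them; hopping/running-like trials are
forward simulations of the same model driven by periodic stretch-shorten
muscle-tendon waveforms and EMG-like activation bursts; and speckle image
sequences translate a junction-like feature along a known integer-pixel path
for the tracker.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import TrialSeries
from .errors import InconsistentGeometryError
from .hill_model import (MuscleParams, SeeDefinition, SeeKind,
                         net_joint_moment, solve_equilibrium_trial)
from .reference import REST_GEOMETRY_STATS, TA_RATIO
from .signals import ActivationParams, activation_dynamics
from .ta_characterization import (CurveKind, ForceStrainCurve, MuscleId,
                                  RestGeometry, combine_ta_curve)
from .ultrasound_tracking import FrameSequence

__all__ = ["SyntheticSubject", "SyntheticTrial", "make_subject",
           "simulate_isometric_ramp", "simulate_dynamic_trial",
           "synth_us_sequence"]

# study-condition defaults: tissue strains at maximal isometric force for the
# imaged muscle (aponeurosis stiffer than tendon; combined T-A well more
# compliant than the generic 0.033 curve), toe fraction of the quadratics,
# nominal maximal forces, moment arms and trial waveforms
TENDON_STRAIN_AT_FMAX = 0.09
APO_STRAIN_AT_FMAX = 0.054
CURVE_TOE_FRACTION = 0.3      # linear share of normalized force at eps_max
GENERIC_STRAIN_AT_FMAX = 0.033
F_MAX_NOMINAL = {MuscleId.GL: 700.0, MuscleId.GM: 1400.0,
                 MuscleId.SOL: 3200.0, MuscleId.TA: 650.0}
MOMENT_ARM_NOMINAL_MM = {MuscleId.GL: 44.0, MuscleId.GM: 48.0,
                         MuscleId.SOL: 52.0, MuscleId.TA: 40.0}
MOMENT_SIGNS = {MuscleId.GL: 1.0, MuscleId.GM: 1.0, MuscleId.SOL: 1.0,
                MuscleId.TA: -1.0}
# fibres rest above their optimal length and shorten toward it under load, as
# plantar-flexor fascicles do; rest fascicle length = factor * l_opt
REST_FIBRE_FACTOR = 1.15
# tibialis anterior rest quantities (its T-A lengths are not part of the
# normative table; only the 0.5 ratio is)
TA_SEE_REST_MM = 240.0
TA_L_OPT_MM = 68.0
TA_PENNATION_OPT_RAD = math.radians(9.6)
TASK_CYCLE_S = {"hop": 0.5, "run": 0.7}
# peak-to-peak muscle-tendon excursion over a movement cycle (hop; run scales
# by 1.3), commensurate with the SEE stretch at peak force so the tendon can
# absorb the excursion
MTU_AMPLITUDE_MM = {MuscleId.GL: 28.0, MuscleId.GM: 28.0, MuscleId.SOL: 21.0,
                    MuscleId.TA: 14.0}
ENVELOPE_PEAK = {MuscleId.GL: 0.54, MuscleId.GM: 0.72, MuscleId.SOL: 0.81,
                 MuscleId.TA: 0.27}
ENVELOPE_BASE = 0.1
BURST_CENTER_FRAC = 0.25   # burst centred at peak MTU stretch, minus delays
BURST_WIDTH_FRAC = 0.18


@dataclass
class SyntheticSubject:
    """A subject with fully known curves and Hill parameters."""

    seed: int
    rest_geometry: dict                  # muscle -> RestGeometry
    muscle_params: dict                  # muscle -> MuscleParams (SS rest lengths)
    tendon_curve: ForceStrainCurve       # imaged-muscle tendon truth
    aponeurosis_curve: ForceStrainCurve  # imaged-muscle aponeurosis truth
    ta_curves: dict                      # muscle -> combined T-A truth
    see_ss: dict                         # muscle -> subject-specific SeeDefinition
    see_generic: SeeDefinition
    moment_arms_mm: dict = field(default_factory=lambda: dict(MOMENT_ARM_NOMINAL_MM))
    signs: dict = field(default_factory=lambda: dict(MOMENT_SIGNS))


@dataclass
class SyntheticTrial:
    """One generated trial plus its generating ground truth."""

    task: str
    series: TrialSeries
    activations_true: dict               # muscle -> activation series
    trajectories_true: dict              # muscle -> MuscleTrajectory
    ground_truth: dict = field(default_factory=dict)
    # isometric-ramp measurement channels (imaged muscle only)
    tendon_length_mm: np.ndarray | None = None
    fascicle_length_mm: np.ndarray | None = None
    pennation_rad: np.ndarray | None = None
    mt_length_mm: np.ndarray | None = None


def _quadratic_through_one(strain_at_fmax: float, kind: CurveKind,
                           toe_fraction: float = CURVE_TOE_FRACTION
                           ) -> ForceStrainCurve:
    """Quadratic through the origin reaching normalized force 1 at the given
    strain, with a configurable linear (toe) share."""
    c1 = toe_fraction / strain_at_fmax
    c2 = (1.0 - toe_fraction) / strain_at_fmax**2
    return ForceStrainCurve(kind=kind, c2=c2, c1=c1, eps_max=strain_at_fmax)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n_sd: float = 2.0) -> float:
    """Normal draw truncated at +/- n_sd standard deviations, positive."""
    for _ in range(100):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sd * sd and x > 0:
            return float(x)
    return float(mean)


def make_subject(seed: int = 0) -> SyntheticSubject:
    """Sample one synthetic subject around the normative geometry.

    Rest geometry is drawn per muscle from the normative means +/- SD
    (truncated at 2 SD); the imaged-muscle tendon and aponeurosis quadratics
    get a mild per-subject compliance jitter, and each muscle's combined T-A
    curve follows from its own rest-length ratio.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rest = {}
    for m, stats in REST_GEOMETRY_STATS.items():
        rest[m] = RestGeometry(
            muscle_id=m,
            fascicle_length_rest=_truncated_normal(rng, *stats["fascicle_length_mm"]),
            pennation_rest=math.radians(
                _truncated_normal(rng, *stats["pennation_deg"])),
            tendon_length_rest=_truncated_normal(rng, *stats["tendon_length_mm"]),
            aponeurosis_length_rest=_truncated_normal(
                rng, *stats["aponeurosis_length_mm"]),
        )
    rest[MuscleId.TA] = RestGeometry(muscle_id=MuscleId.TA, ratio=TA_RATIO)

    tendon_curve = _quadratic_through_one(
        TENDON_STRAIN_AT_FMAX * rng.uniform(0.92, 1.08), CurveKind.TENDON)
    apo_curve = _quadratic_through_one(
        APO_STRAIN_AT_FMAX * rng.uniform(0.92, 1.08), CurveKind.APONEUROSIS)

    ta_curves, see_ss, params = {}, {}, {}
    activation = ActivationParams()
    for m in (MuscleId.GL, MuscleId.GM, MuscleId.SOL, MuscleId.TA):
        ratio = rest[m].ratio
        ta_curves[m] = combine_ta_curve(tendon_curve, apo_curve, ratio)
        see_ss[m] = SeeDefinition(kind=SeeKind.SS_TA, curve=ta_curves[m])
        if m is MuscleId.TA:
            l_opt, pen_opt, see_rest = (TA_L_OPT_MM, TA_PENNATION_OPT_RAD,
                                        TA_SEE_REST_MM)
        else:
            g = rest[m]
            # rest fascicles sit above optimal length; pennation at optimum
            # follows from constant muscle thickness
            l_opt = g.fascicle_length_rest / REST_FIBRE_FACTOR
            pen_opt = math.asin(min(
                REST_FIBRE_FACTOR * math.sin(g.pennation_rest), 0.99))
            see_rest = g.tendon_length_rest + g.aponeurosis_length_rest
        params[m] = MuscleParams(
            muscle_id=m,
            f_max=F_MAX_NOMINAL[m] * rng.uniform(0.9, 1.1),
            l_opt=l_opt, see_rest_length=see_rest, pennation_opt=pen_opt,
            activation=activation)
    return SyntheticSubject(
        seed=seed, rest_geometry=rest, muscle_params=params,
        tendon_curve=tendon_curve, aponeurosis_curve=apo_curve,
        ta_curves=ta_curves, see_ss=see_ss,
        see_generic=SeeDefinition(kind=SeeKind.GENERIC,
                                  strain_at_fmax=GENERIC_STRAIN_AT_FMAX))


def _mt_rest_length(subject: SyntheticSubject, m: MuscleId) -> float:
    p = subject.muscle_params[m]
    if m is MuscleId.TA:
        lf_rest = REST_FIBRE_FACTOR * p.l_opt
        sin_rest = p.l_opt * math.sin(p.pennation_opt) / lf_rest
        return p.see_rest_length + lf_rest * math.cos(math.asin(sin_rest))
    return subject.rest_geometry[m].mt_length_rest


def simulate_isometric_ramp(subject: SyntheticSubject, duration: float = 4.0,
                            fs: float = 125.0,
                            length_noise_sd_mm: float = 0.0,
                            seed: int = 0) -> SyntheticTrial:
    """Isometric plantar-flexion ramp of the imaged muscle (GM).

    Muscle-tendon length is held at its rest value while activation ramps
    smoothly from 0 to 1; the fibre/SEE equilibrium is solved with the true
    parameters and the emitted tendon and aponeurosis lengths follow the true
    tissue curves at the solved force, so the characterization stage can
    invert them.  Ground truth is stored in task-normalized force units
    (the measured moment is normalized by its task maximum, so curves are
    recoverable only up to the peak normalized force actually reached).
    """
    m = MuscleId.GM
    p = subject.muscle_params[m]
    geom = subject.rest_geometry[m]
    dt = 1.0 / fs
    n = int(round(duration * fs)) + 1
    t = np.arange(n) * dt
    x = t / duration
    activation = x * x * (3.0 - 2.0 * x)       # smoothstep 0 -> 1
    lmt = np.full(n, geom.mt_length_rest)
    traj = solve_equilibrium_trial(activation, lmt, p, subject.see_ss[m], dt)
    f_norm = traj.see_force / p.f_max
    peak = float(f_norm.max())
    if peak <= 0:
        raise InconsistentGeometryError("ramp produced no force")

    eps_t = np.asarray(subject.tendon_curve.strain_at(f_norm))
    eps_a = np.asarray(subject.aponeurosis_curve.strain_at(f_norm))
    lt = geom.tendon_length_rest * (1.0 + eps_t)
    la = geom.aponeurosis_length_rest * (1.0 + eps_a)
    w = lmt - lt - la                      # fascicle projection on the line
    if np.any(w <= 0):
        raise InconsistentGeometryError("ramp geometry collapsed")
    h = geom.fascicle_length_rest * math.sin(geom.pennation_rest)
    fascicle = np.hypot(w, h)
    pennation = np.arctan2(h, w)
    arm = subject.moment_arms_mm[m]
    moment = traj.see_force * arm / 1000.0

    if length_noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        lt = lt + rng.normal(0.0, length_noise_sd_mm, n)
        fascicle = fascicle + rng.normal(0.0, length_noise_sd_mm, n)

    ratio = geom.ratio
    truth = {
        "peak_norm_force": peak,
        # task-normalized quadratics: F/peak = (c2/peak) eps^2 + (c1/peak) eps
        "tendon_c2c1": (subject.tendon_curve.c2 / peak,
                        subject.tendon_curve.c1 / peak),
        "aponeurosis_c2c1": (subject.aponeurosis_curve.c2 / peak,
                             subject.aponeurosis_curve.c1 / peak),
        "tendon_strain_at_task_max": float(subject.tendon_curve.strain_at(peak)),
        "aponeurosis_strain_at_task_max": float(
            subject.aponeurosis_curve.strain_at(peak)),
        "ta_strain_at_task_max": float(
            ratio * subject.tendon_curve.strain_at(peak)
            + (1.0 - ratio) * subject.aponeurosis_curve.strain_at(peak)),
        "ratio": ratio,
    }
    series = TrialSeries(
        time=t, envelopes={m: activation}, mt_lengths={m: lmt},
        moment_arms={m: np.full(n, arm)}, net_moment=moment,
        signs={m: 1.0}, task="isometric_ramp")
    return SyntheticTrial(
        task="isometric_ramp", series=series,
        activations_true={m: activation}, trajectories_true={m: traj},
        ground_truth=truth, tendon_length_mm=lt, fascicle_length_mm=fascicle,
        pennation_rad=pennation, mt_length_mm=lmt)


def _burst_envelope(t: np.ndarray, cycle: float, peak: float,
                    center_frac: float,
                    width_frac: float = BURST_WIDTH_FRAC) -> np.ndarray:
    """Periodic Gaussian activation bursts, one per movement cycle."""
    phase = (t / cycle - center_frac) % 1.0
    phase = np.minimum(phase, 1.0 - phase)          # circular distance
    return ENVELOPE_BASE + (peak - ENVELOPE_BASE) * np.exp(
        -0.5 * (phase / width_frac) ** 2)


def simulate_dynamic_trial(subject: SyntheticSubject, task: str = "hop",
                           seed: int = 0, duration: float = 3.0,
                           fs: float = 125.0,
                           envelope_noise_sigma: float = 0.0,
                           see=None) -> SyntheticTrial:
    """Hopping- or running-like trial forward-simulated with known truth.

    Plantar-flexor muscle-tendon lengths follow periodic stretch-shorten
    waveforms (hop cycle 0.5 s, run cycle 0.7 s) with the dorsi-flexor in
    antiphase; EMG-like envelopes are periodic bursts timed with the stretch.
    The stored net moment is recomputed exactly from the ground-truth
    trajectories; envelope noise (multiplicative log-normal, seeded) corrupts
    only the stored envelopes the model consumes.
    """
    if task not in TASK_CYCLE_S:
        raise ValueError(f"task must be one of {sorted(TASK_CYCLE_S)}")
    if see is None:
        see = subject.see_ss
    cycle = TASK_CYCLE_S[task]
    dt = 1.0 / fs
    n = int(round(duration * fs)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)

    envelopes, mt_lengths, arms = {}, {}, {}
    stretch = 0.5 * (1.0 - np.cos(2 * np.pi * t / cycle))   # 0 -> 1 -> 0
    for m in subject.muscle_params:
        amp = MTU_AMPLITUDE_MM[m] * (1.0 if task == "hop" else 1.3)
        rest_mt = _mt_rest_length(subject, m)
        if m is MuscleId.TA:
            # dorsi-flexor shortens while the plantar-flexors stretch; its
            # burst falls in the opposite half-cycle
            mt_lengths[m] = rest_mt - 0.5 * amp * stretch
            center = 0.75
        else:
            # taut-tendon stretch-shorten cycle: MTU oscillates above rest
            mt_lengths[m] = rest_mt + amp * stretch
            center = BURST_CENTER_FRAC
        envelopes[m] = _burst_envelope(t, cycle, ENVELOPE_PEAK[m], center)
        arms[m] = subject.moment_arms_mm[m] * (
            1.0 + 0.04 * np.sin(2 * np.pi * t / cycle + 0.5))

    activations, trajectories = {}, {}
    for m, p in subject.muscle_params.items():
        activations[m] = activation_dynamics(envelopes[m], p.activation)
        trajectories[m] = solve_equilibrium_trial(
            activations[m], mt_lengths[m], p,
            see[m] if isinstance(see, dict) else see, dt)
    moment = net_joint_moment(trajectories, arms, subject.signs)

    stored_env = {}
    for m, env in envelopes.items():
        if envelope_noise_sigma > 0:
            noise = rng.normal(0.0, envelope_noise_sigma, n)
            env = env * np.exp(noise - 0.5 * envelope_noise_sigma**2)
        stored_env[m] = np.clip(env, 0.0, 1.0)

    series = TrialSeries(time=t, envelopes=stored_env, mt_lengths=mt_lengths,
                         moment_arms=arms, net_moment=moment,
                         signs=dict(subject.signs), task=task)
    return SyntheticTrial(task=task, series=series,
                          activations_true=activations,
                          trajectories_true=trajectories,
                          ground_truth={"seed": seed, "cycle_s": cycle})


def synth_us_sequence(path, size=(64, 64), seed: int = 0,
                      start=None, frame_rate: float = 30.0,
                      mm_per_pixel: float = 0.1):
    """Speckle-textured frame sequence with a junction-like bright feature
    translated along an integer-pixel path.

    ``path`` is a list of per-frame (drow, dcol) integer displacements (one
    fewer than the number of frames).  Returns ``(FrameSequence,
    ground_truth_positions)`` where positions are (n_frames, 2) int.
    """
    path = np.asarray(path, dtype=int)
    if path.ndim != 2 or path.shape[1] != 2:
        raise ValueError("path must be a sequence of (drow, dcol) pairs")
    nrows, ncols = size
    if start is None:
        start = (nrows // 2, ncols // 2)
    positions = np.vstack([start, start + np.cumsum(path, axis=0)])
    if (positions < 0).any() or (positions[:, 0] >= nrows).any() \
            or (positions[:, 1] >= ncols).any():
        raise ValueError("path leaves the frame")

    rng = np.random.default_rng(seed)
    speckle = gaussian_filter(rng.standard_normal(size), sigma=1.0)
    speckle = (speckle - speckle.min()) / (speckle.max() - speckle.min())
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    blob = np.exp(-(((rr - start[0]) ** 2 + (cc - start[1]) ** 2) / (2 * 2.5**2)))
    base = np.clip(0.6 * speckle + 0.8 * blob, 0.0, 1.0)
    frames = [base]
    for disp in np.cumsum(path, axis=0):
        frames.append(np.roll(base, tuple(disp), axis=(0, 1)))
    seq = FrameSequence(frames=frames, frame_rate=frame_rate,
                        mm_per_pixel=mm_per_pixel)
    return seq, positions
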