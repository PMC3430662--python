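"""Calibration of the EMG-driven model against inverse-dynamics moments, and
prediction on novel trials.

Calibration tunes a configurable set of per-subject parameters (per-muscle
maximal isometric force, optimal fibre length and SEE rest-length scales, and
the activation-dynamics shape/pole parameters) by bounded derivative-free
optimization so that the model's net ankle moment matches the
inverse-dynamics reference over one or more trials, summed squared error over
the complete time history.  Prediction then runs the model forward with the
frozen parameters on held-out trials and reports moment agreement and fibre/
SEE behaviour summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .errors import CalibrationError, EquilibriumError
from .hill_model import net_joint_moment, solve_equilibrium_trial
from .metrics import TrialMetrics, trial_summary
from .signals import activation_dynamics
from .ta_characterization import MuscleId

__all__ = ["TrialSeries", "CalibrationSpec", "CalibrationResult",
           "objective", "calibrate", "predict", "run_model_trial"]

#: objective value substituted when the equilibrium solver fails inside an
#: optimizer evaluation
FAILURE_PENALTY = 1e9

#: default bounds per free-parameter family
DEFAULT_BOUNDS = {
    "f_max_scale": (0.5, 2.0),
    "l_opt_scale": (0.85, 1.15),
    "see_rest_scale": (0.9, 1.1),
    "shape_factor": (-3.0, -0.001),
    "gamma1": (-0.95, 0.95),
    "gamma2": (-0.95, 0.95),
}


@dataclass
class TrialSeries:
    """Time-aligned inputs for one trial of the EMG-driven model."""

    time: np.ndarray
    envelopes: dict          # muscle -> normalized EMG envelope in [0, 1]
    mt_lengths: dict         # muscle -> mm series
    moment_arms: dict        # muscle -> mm series
    net_moment: np.ndarray   # inverse-dynamics reference, N·m
    signs: dict              # muscle -> +1 (plantar-flexor) / -1 (dorsi-flexor)
    task: str = ""

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class CalibrationSpec:
    """What to tune, within which bounds, and how hard to search."""

    free_parameters: tuple = ("f_max_scale", "shape_factor")
    bounds: dict = field(default_factory=dict)   # overrides of DEFAULT_BOUNDS
    seed: int = 0
    n_starts: int = 6
    max_evaluations: int = 400   # per start
    per_muscle: tuple = (MuscleId.GL, MuscleId.GM, MuscleId.SOL, MuscleId.TA)

    def parameter_names(self) -> list[str]:
        """Expanded flat parameter list; scale families are per muscle."""
        names = []
        for fam in self.free_parameters:
            if fam.endswith("_scale"):
                names.extend(f"{fam}:{MuscleId(m).value}" for m in self.per_muscle)
            else:
                names.append(fam)
        return names

    def bounds_for(self, name: str) -> tuple[float, float]:
        fam = name.split(":")[0]
        return self.bounds.get(name, self.bounds.get(fam, DEFAULT_BOUNDS[fam]))


@dataclass
class CalibrationResult:
    """Outcome of one calibration run."""

    parameters: dict            # flat name -> fitted value
    objective_value: float
    objective_per_trial: list
    converged: bool
    n_evaluations: int
    base_params: dict           # muscle -> MuscleParams used as the baseline
    spec: CalibrationSpec | None = None


def apply_parameters(base_params: dict, values: dict) -> dict:
    """Return per-muscle MuscleParams with the flat parameter dict applied.

    Scale entries (``f_max_scale:GM`` ...) multiply the base value for that
    muscle; activation entries (``shape_factor``, ``gamma1``, ``gamma2``) are
    set absolutely and shared across muscles.
    """
    out = {}
    for m, p in base_params.items():
        key = MuscleId(m).value
        fm = p.f_max * values.get(f"f_max_scale:{key}", 1.0)
        lo = p.l_opt * values.get(f"l_opt_scale:{key}", 1.0)
        sr = p.see_rest_length * values.get(f"see_rest_scale:{key}", 1.0)
        act = p.activation
        act_updates = {k: values[k] for k in ("shape_factor", "gamma1", "gamma2")
                       if k in values}
        if act_updates:
            act = replace(act, **act_updates)
        out[m] = replace(p, f_max=fm, l_opt=lo, see_rest_length=sr,
                         activation=act)
    return out


def _see_for(see, muscle):
    return see[muscle] if isinstance(see, dict) else see


def run_model_trial(trial: TrialSeries, params: dict, see,
                    min_activation: float = 0.01):
    """Forward-run the model on one trial.

    Returns ``(model_moment, trajectories)``; ``see`` is a single
    :class:`SeeDefinition` or a per-muscle mapping.
    """
    trajectories = {}
    for m, p in params.items():
        act = activation_dynamics(trial.envelopes[m], p.activation,
                                  min_activation=min_activation)
        trajectories[m] = solve_equilibrium_trial(
            act, trial.mt_lengths[m], p, _see_for(see, m), trial.dt)
    moment = net_joint_moment(trajectories, trial.moment_arms, trial.signs)
    return moment, trajectories


def objective(params: dict, trials, see) -> float:
    """Summed squared moment error (N²·m²) across trials and time; an
    equilibrium failure inside the evaluation yields a large finite penalty."""
    total = 0.0
    for trial in trials:
        try:
            moment, _ = run_model_trial(trial, params, see)
        except EquilibriumError:
            return FAILURE_PENALTY
        total += float(np.sum((moment - np.asarray(trial.net_moment)) ** 2))
    return total


def calibrate(spec: CalibrationSpec, trials, see,
              base_params: dict) -> CalibrationResult:
    """Bounded multi-start local minimization of the moment-matching
    objective.

    Starts are drawn from a seeded Latin hypercube over the bounds (plus the
    unit/neutral point), each refined by bounded Powell search; deterministic
    given ``spec.seed``.
    """
    names = spec.parameter_names()
    lo = np.array([spec.bounds_for(n)[0] for n in names])
    hi = np.array([spec.bounds_for(n)[1] for n in names])
    if np.any(hi < lo):
        raise ValueError("invalid bounds: upper < lower")

    def evaluate(x):
        values = dict(zip(names, x))
        return objective(apply_parameters(base_params, values), trials, see)

    # neutral point: scale families at 1, activation params at base values
    any_muscle = next(iter(base_params.values()))
    neutral = []
    for n in names:
        fam = n.split(":")[0]
        if fam.endswith("_scale"):
            v = 1.0
        else:
            v = getattr(any_muscle.activation, fam)
        neutral.append(float(np.clip(v, *spec.bounds_for(n))))
    starts = [np.asarray(neutral)]
    n_random = max(spec.n_starts - 1, 0)
    if n_random and np.any(hi > lo):
        sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
        unit = sampler.random(n_random)
        starts.extend(lo + unit * (hi - lo))

    best_x, best_f, evals, any_ok = None, np.inf, 0, False
    for x0 in starts:
        if np.all(hi == lo):
            res_x, res_f, nfev, ok = lo.copy(), evaluate(lo), 1, True
        else:
            res = optimize.minimize(
                evaluate, x0, method="Powell",
                bounds=list(zip(lo, hi)),
                options={"maxfev": spec.max_evaluations, "xtol": 1e-6,
                         "ftol": 1e-8})
            res_x, res_f, nfev, ok = res.x, float(res.fun), res.nfev, True
        evals += nfev
        if res_f < FAILURE_PENALTY:
            any_ok = True
        if res_f < best_f:
            best_f, best_x = res_f, np.clip(res_x, lo, hi)
    if not any_ok or best_x is None:
        raise CalibrationError(
            "all calibration starts failed the equilibrium solve")

    values = dict(zip(names, (float(v) for v in best_x)))
    fitted = apply_parameters(base_params, values)
    per_trial = []
    for trial in trials:
        try:
            moment, _ = run_model_trial(trial, fitted, see)
            per_trial.append(float(np.sum(
                (moment - np.asarray(trial.net_moment)) ** 2)))
        except EquilibriumError:
            per_trial.append(FAILURE_PENALTY)
    return CalibrationResult(parameters=values, objective_value=best_f,
                             objective_per_trial=per_trial,
                             converged=best_f < FAILURE_PENALTY,
                             n_evaluations=evals, base_params=base_params,
                             spec=spec)


@dataclass
class PredictionOutput:
    """Forward model run on one novel trial with frozen parameters."""

    moment: np.ndarray
    trajectories: dict
    metrics: TrialMetrics


def predict(result: CalibrationResult, novel_trials, see) -> list:
    """Run the calibrated model on held-out trials.

    Returns one :class:`PredictionOutput` per trial with the predicted moment
    series, per-muscle trajectories and the standard per-trial summary
    (R², RMS error, peak moment/forces, fibre and SEE variations).
    """
    fitted = apply_parameters(result.base_params, result.parameters)
    outputs = []
    for trial in novel_trials:
        moment, trajectories = run_model_trial(trial, fitted, see)
        metrics = trial_summary(trajectories, moment,
                                reference_moment=trial.net_moment)
        outputs.append(PredictionOutput(moment=moment,
                                        trajectories=trajectories,
                                        metrics=metrics))
    return outputs
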