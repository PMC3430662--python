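"""Trial-level agreement metrics and trajectory summaries.

R² is the coefficient of determination of the model moment against the
inverse-dynamics reference (1 minus the ratio of residual to total sum of
squares, computed over the complete time history; negative values are
reported, not clipped).  The RMS error is the root mean squared moment
difference over the same history.  Trajectory summaries report maxima and
max-minus-min variations of fibre length, fibre velocity and SEE length —
the quantities through which SEE compliance reshapes fibre behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMetricError

__all__ = ["TrialMetrics", "r_squared", "rms_error", "trial_summary",
           "percent_increase"]


def r_squared(reference, model) -> float:
    """Coefficient of determination of ``model`` against ``reference``."""
    ref = np.asarray(reference, dtype=float)
    mod = np.asarray(model, dtype=float)
    if ref.shape != mod.shape or ref.size < 2:
        raise ValueError("series must be aligned with length >= 2")
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined for a constant reference")
    ss_res = float(np.sum((ref - mod) ** 2))
    return 1.0 - ss_res / ss_tot


def rms_error(reference, model) -> float:
    """Root mean squared difference between the two series."""
    ref = np.asarray(reference, dtype=float)
    mod = np.asarray(model, dtype=float)
    if ref.shape != mod.shape or ref.size < 1:
        raise ValueError("series must be aligned with length >= 1")
    return float(np.sqrt(np.mean((ref - mod) ** 2)))


def percent_increase(baseline: float, value: float) -> float:
    """Relative increase of ``value`` over ``baseline``, in percent."""
    if baseline == 0:
        raise ZeroDivisionError("baseline must be nonzero")
    return (value - baseline) / baseline * 100.0


@dataclass
class TrialMetrics:
    """Per-trial model outputs analysed for each prediction trial."""

    r_squared: float | None
    rms_error: float | None
    max_moment: float
    min_moment: float
    max_force: dict = field(default_factory=dict)            # N per muscle
    fibre_length_variation: dict = field(default_factory=dict)   # mm
    fibre_velocity_variation: dict = field(default_factory=dict)  # mm/s
    see_length_variation: dict = field(default_factory=dict)      # mm


def trial_summary(trajectories: dict, model_moment,
                  reference_moment=None) -> TrialMetrics:
    """Summarize one trial: moment extrema, per-muscle peak force and
    max-minus-min variation of fibre length, fibre velocity and SEE length."""
    moment = np.asarray(model_moment, dtype=float)
    if moment.size == 0:
        raise ValueError("empty moment series")
    r2 = rmse = None
    if reference_moment is not None:
        r2 = r_squared(reference_moment, moment)
        rmse = rms_error(reference_moment, moment)
    out = TrialMetrics(r_squared=r2, rms_error=rmse,
                       max_moment=float(moment.max()),
                       min_moment=float(moment.min()))
    for m, traj in trajectories.items():
        out.max_force[m] = float(np.max(traj.see_force))
        out.fibre_length_variation[m] = float(np.ptp(traj.fibre_length))
        out.fibre_velocity_variation[m] = float(np.ptp(traj.fibre_velocity))
        out.see_length_variation[m] = float(np.ptp(traj.see_length))
    return out
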