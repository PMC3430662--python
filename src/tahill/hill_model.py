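"""Hill-type muscle-tendon contraction dynamics with a swappable series
elastic element (SEE).

The muscle fibre is a contractile element (force-length-velocity) in parallel
with a passive elastic element; the SEE in series with it represents the
tendon-aponeurosis complex and is defined either by the classic generic
in-vitro tendon curve (exponential toe region turning linear, normalized so
force equals the maximal isometric force at a configurable strain) or by a
subject-specific quadratic T-A curve measured by ultrasound.  At every time
instant the fibre length is found such that the fibre force projected along
the tendon axis equals the SEE force; the SEE force times the muscle-tendon
moment arm gives the muscle's contribution to the joint moment.

Units: lengths mm, velocities mm/s, forces N, moments N·m, angles radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import EquilibriumError
from .signals import ActivationParams
from .ta_characterization import ForceStrainCurve, MuscleId

__all__ = [
    "SeeKind", "SeeDefinition", "MuscleParams", "MuscleTrajectory",
    "see_force", "fibre_force", "active_force_length", "passive_force_length",
    "force_velocity", "solve_equilibrium_trial", "net_joint_moment",
]

# fibre curve-shape constants (the field-standard forms; all config-exposed
# through the function arguments below)
FL_WIDTH = 0.45          # Gaussian width of the active force-length bump
KPE = 4.0                # passive exponential shape
PASSIVE_STRAIN_AT_FMAX = 0.6
AF = 0.25                # Hill force-velocity curvature
FLEN_MAX = 1.4           # eccentric force plateau
# eccentric-branch scale chosen so the slope at zero velocity matches the
# concentric branch slope (1 + 1/AF)
_ECC_SCALE = (FLEN_MAX - 1.0) / (1.0 + 1.0 / AF)

# generic SEE curve constants (exponential toe then linear)
GEN_FTOE = 0.33
GEN_KTOE = 3.0
GEN_EPS_TOE_FRAC = 0.609   # toe-region end as a fraction of strain at F_max
GEN_KLIN_NUM = 1.712       # linear stiffness numerator (per strain at F_max)


class SeeKind(str, Enum):
    GENERIC = "generic"
    SS_TA = "ss_ta"


@dataclass(frozen=True)
class SeeDefinition:
    """Series-elastic-element definition: generic curve or subject-specific
    T-A quadratic."""

    kind: SeeKind
    curve: ForceStrainCurve | None = None
    strain_at_fmax: float = 0.033

    def __post_init__(self) -> None:
        if SeeKind(self.kind) is SeeKind.SS_TA and self.curve is None:
            raise ValueError("ss_ta SEE definition requires a fitted curve")
        if self.strain_at_fmax <= 0:
            raise ValueError("strain_at_fmax must be > 0")

    def force_norm(self, strain):
        """Normalized SEE force at the given strain (slack -> 0)."""
        return see_force(self, strain)

    def scalar_force(self):
        """Fast float->float closure used by the per-step equilibrium solver."""
        if SeeKind(self.kind) is SeeKind.GENERIC:
            e0 = self.strain_at_fmax
            eps_toe = GEN_EPS_TOE_FRAC * e0
            klin = GEN_KLIN_NUM / e0
            denom = math.expm1(GEN_KTOE)
            raw_at_e0 = GEN_FTOE + klin * (e0 - eps_toe)
            scale = 1.0 / raw_at_e0

            def f(eps: float) -> float:
                if eps <= 0.0:
                    return 0.0
                if eps < eps_toe:
                    raw = GEN_FTOE * math.expm1(GEN_KTOE * eps / eps_toe) / denom
                else:
                    raw = GEN_FTOE + klin * (eps - eps_toe)
                return raw * scale

            return f
        c2, c1 = self.curve.c2, self.curve.c1
        eps_max = self.curve.eps_max
        f_at_max = c2 * eps_max**2 + c1 * eps_max
        slope = 2.0 * c2 * eps_max + c1
        clamp = self.curve.extrapolation == "clamp"

        def f(eps: float) -> float:
            if eps <= 0.0:
                return 0.0
            if eps <= eps_max:
                return c2 * eps * eps + c1 * eps
            if clamp:
                return f_at_max
            return f_at_max + slope * (eps - eps_max)

        return f


def see_force(defn: SeeDefinition, strain):
    """Vectorized normalized SEE force; see :meth:`SeeDefinition.scalar_force`
    for the curve definition."""
    eps = np.asarray(strain, dtype=float)
    if SeeKind(defn.kind) is SeeKind.SS_TA:
        out = np.asarray(defn.curve.force(eps))
    else:
        e0 = defn.strain_at_fmax
        eps_toe = GEN_EPS_TOE_FRAC * e0
        klin = GEN_KLIN_NUM / e0
        scale = 1.0 / (GEN_FTOE + klin * (e0 - eps_toe))
        toe = GEN_FTOE * np.expm1(GEN_KTOE * np.minimum(eps, eps_toe) / eps_toe) \
            / np.expm1(GEN_KTOE)
        lin = GEN_FTOE + klin * (eps - eps_toe)
        out = scale * np.where(eps < eps_toe, toe, lin)
        out = np.where(eps <= 0.0, 0.0, out)
    return out if out.ndim else float(out)


def active_force_length(norm_length, width: float = FL_WIDTH):
    """Gaussian active force-length curve, 1 at optimal length."""
    l = np.asarray(norm_length, dtype=float)
    out = np.exp(-((l - 1.0) ** 2) / width)
    return out if out.ndim else float(out)


def passive_force_length(norm_length, kpe: float = KPE,
                         strain_at_fmax: float = PASSIVE_STRAIN_AT_FMAX):
    """Exponential passive fibre curve: zero up to optimal length, reaching 1
    at ``1 + strain_at_fmax``."""
    l = np.asarray(norm_length, dtype=float)
    out = np.where(l > 1.0,
                   np.expm1(kpe * (l - 1.0) / strain_at_fmax) / np.expm1(kpe),
                   0.0)
    return out if out.ndim else float(out)


def force_velocity(norm_velocity, af: float = AF, flen_max: float = FLEN_MAX):
    """Hill force-velocity curve; velocity normalized to the maximal
    shortening velocity (negative = shortening)."""
    v = np.asarray(norm_velocity, dtype=float)
    conc = np.where(v <= -1.0, 0.0, (1.0 + v) / (1.0 - v / af))
    s = (flen_max - 1.0) / (1.0 + 1.0 / af)
    ecc = (flen_max * v + s) / (v + s)
    out = np.where(v < 0.0, conc, ecc)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MuscleParams:
    """Hill-model parameters for one muscle-tendon unit."""

    muscle_id: MuscleId
    f_max: float              # maximal isometric force, N
    l_opt: float              # optimal fibre length, mm
    see_rest_length: float    # SEE rest length, mm (tendon slack length for
    #                           the generic condition, tendon+aponeurosis rest
    #                           length for the subject-specific condition)
    pennation_opt: float      # pennation at optimal fibre length, rad
    activation: ActivationParams = field(default_factory=ActivationParams)
    v_max_factor: float = 10.0   # maximal shortening velocity, l_opt per second
    damping: float = 0.1         # parallel damping, fraction of f_max per unit
    #                              normalized velocity (stabilizes the solve)

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.l_opt <= 0 or self.see_rest_length <= 0:
            raise ValueError("f_max, l_opt and see_rest_length must be > 0")
        if not (0 <= self.pennation_opt < np.pi / 2):
            raise ValueError("pennation_opt must lie in [0, pi/2)")


def fibre_force(activation, norm_fibre_length, norm_fibre_velocity,
                params: MuscleParams):
    """Fibre force along the fibre axis: active (a·f_l·f_v) plus passive,
    scaled by maximal isometric force.  Damping is added separately by the
    equilibrium solver."""
    a = np.asarray(activation, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1.0 + 1e-12):
        raise ValueError("activation must lie in [0, 1]")
    out = params.f_max * (
        a * active_force_length(norm_fibre_length)
        * force_velocity(norm_fibre_velocity)
        + passive_force_length(norm_fibre_length))
    return out if np.ndim(out) else float(out)


@dataclass
class MuscleTrajectory:
    """Solved per-time-step state of one muscle over a trial."""

    muscle_id: MuscleId
    dt: float
    fibre_length: np.ndarray     # mm
    fibre_velocity: np.ndarray   # mm/s
    pennation: np.ndarray        # rad
    see_length: np.ndarray       # mm
    see_strain: np.ndarray
    fibre_force: np.ndarray      # N, along the fibre (incl. damping)
    see_force: np.ndarray        # N, along the tendon axis
    residual: np.ndarray         # N, |fibre force along tendon - SEE force|
    moment_contribution: np.ndarray | None = None  # N·m


def _illinois(f, a, b, fa, fb, xtol: float, max_iter: int = 120) -> float:
    """Bisection-safeguarded secant (Illinois regula falsi) on a bracket with
    a sign change."""
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    side = 0
    for _ in range(max_iter):
        x = b - fb * (b - a) / (fb - fa)
        if not (min(a, b) < x < max(a, b)):
            x = 0.5 * (a + b)
        fx = f(x)
        if fx == 0.0 or abs(b - a) < xtol:
            return x
        if (fx > 0.0) == (fb > 0.0):
            b, fb = x, fx
            if side == -1:
                fa *= 0.5
            side = -1
        else:
            a, fa = x, fx
            if side == 1:
                fb *= 0.5
            side = 1
    return 0.5 * (a + b)


def solve_equilibrium_trial(activation, mt_length, params: MuscleParams,
                            see: SeeDefinition, dt: float,
                            bracket=(0.3, 1.8), residual_tol: float = 0.1,
                            xtol: float = 1e-10) -> MuscleTrajectory:
    """Solve the fibre/SEE force balance at every time step of a trial.

    At each step the fibre length is the root of ``fibre_force·cos(pennation)
    - SEE_force``; the fibre velocity enters implicitly through a backward
    finite difference, pennation follows the constant-thickness model
    ``l_fibre·sin(pennation) = l_opt·sin(pennation_opt)``, and the SEE length
    is the muscle-tendon length minus the fibre projection.  The first step is
    solved statically (zero velocity).

    Raises
    ------
    EquilibriumError
        If the residual has no sign change in the fibre-length bracket at some
        step, or a step's residual exceeds ``residual_tol``.
    """
    a_series = np.asarray(activation, dtype=float)
    lmt_series = np.asarray(mt_length, dtype=float)
    if a_series.shape != lmt_series.shape:
        raise ValueError("activation and mt_length series must be aligned")
    n = a_series.size
    l_opt = params.l_opt
    h = l_opt * math.sin(params.pennation_opt)   # conserved muscle thickness
    vmax = params.v_max_factor * l_opt           # mm/s
    see_rest = params.see_rest_length
    fmax = params.f_max
    damping = params.damping
    seefn = see.scalar_force()
    lo_g, hi_g = bracket[0] * l_opt, bracket[1] * l_opt
    inv_width = 1.0 / FL_WIDTH
    kpe_scale = KPE / PASSIVE_STRAIN_AT_FMAX
    expm1_kpe = math.expm1(KPE)
    ecc_s = _ECC_SCALE

    out = {k: np.empty(n) for k in
           ("fibre_length", "fibre_velocity", "pennation", "see_length",
            "see_strain", "fibre_force", "see_force", "residual")}
    lf_prev = l_opt

    for t in range(n):
        a = min(max(float(a_series[t]), 0.0), 1.0)
        lmt = float(lmt_series[t])
        first = t == 0
        lfp = lf_prev

        def resid(lf: float, _a=a, _lmt=lmt, _first=first, _lfp=lfp) -> float:
            s = h / lf
            if s > 0.999:
                s = 0.999
            cosp = math.sqrt(1.0 - s * s)
            strain = (_lmt - lf * cosp - see_rest) / see_rest
            fsee = fmax * seefn(strain)
            vn = 0.0 if _first else (lf - _lfp) / (dt * vmax)
            ln = lf / l_opt
            fa_ = math.exp(-((ln - 1.0) ** 2) * inv_width)
            fp_ = math.expm1(kpe_scale * (ln - 1.0)) / expm1_kpe if ln > 1.0 else 0.0
            if vn >= 0.0:
                fv_ = (FLEN_MAX * vn + ecc_s) / (vn + ecc_s)
            elif vn <= -1.0:
                fv_ = 0.0
            else:
                fv_ = (1.0 + vn) / (1.0 - vn / AF)
            return fmax * (_a * fa_ * fv_ + fp_ + damping * vn) * cosp - fsee

        # warm start: the solution moves little between steps, so try a
        # narrow bracket around the previous fibre length first
        lf = None
        if not first:
            a_loc = max(lo_g, lfp - 1.5)
            b_loc = min(hi_g, lfp + 1.5)
            if a_loc < b_loc:
                fa_loc, fb_loc = resid(a_loc), resid(b_loc)
                if (fa_loc < 0.0) != (fb_loc < 0.0):
                    lf = _illinois(resid, a_loc, b_loc, fa_loc, fb_loc, xtol)
        if lf is None:
            # SEE slack over the whole bracket (strain is largest at the
            # shortest fibre): admissible only for a force-free fibre, which
            # then rests at its previous length capped at optimum
            strain_lo = (lmt - lo_g * math.sqrt(1 - min(h / lo_g, 0.999) ** 2)
                         - see_rest) / see_rest
            if strain_lo <= 0.0 and a * fmax <= residual_tol:
                lf = min(lfp, l_opt)
            else:
                flo, fhi = resid(lo_g), resid(hi_g)
                if flo == 0.0:
                    lf = lo_g
                elif fhi == 0.0:
                    lf = hi_g
                elif (flo < 0.0) != (fhi < 0.0):
                    lf = _illinois(resid, lo_g, hi_g, flo, fhi, xtol)
                elif flo > 0.0:
                    raise EquilibriumError(
                        f"no equilibrium: residual positive across bracket "
                        f"at step {t}", step=t, bracket=(lo_g, hi_g))
                else:
                    raise EquilibriumError(
                        f"no sign change in fibre-length bracket at step {t} "
                        f"(residuals {flo:.3g}, {fhi:.3g} N)", step=t,
                        bracket=(lo_g, hi_g))

        s = min(h / lf, 0.999)
        cosp = math.sqrt(1.0 - s * s)
        pen = math.asin(s)
        see_len = lmt - lf * cosp
        strain = (see_len - see_rest) / see_rest
        fsee = fmax * seefn(strain)
        v = 0.0 if first else (lf - lfp) / dt
        res = abs(resid(lf))
        if res > residual_tol:
            raise EquilibriumError(
                f"equilibrium residual {res:.3g} N exceeds {residual_tol} N "
                f"at step {t}", step=t, bracket=(lo_g, hi_g))
        out["fibre_length"][t] = lf
        out["fibre_velocity"][t] = v
        out["pennation"][t] = pen
        out["see_length"][t] = see_len
        out["see_strain"][t] = strain
        out["see_force"][t] = fsee
        # total fibre-axis force (incl. damping): resid = f_fib*cosp - f_see
        out["fibre_force"][t] = (fsee + resid(lf)) / cosp
        out["residual"][t] = res
        lf_prev = lf

    return MuscleTrajectory(muscle_id=params.muscle_id, dt=dt, **out)


def net_joint_moment(trajectories: dict, moment_arms: dict,
                     signs: dict) -> np.ndarray:
    """Net joint moment from per-muscle SEE forces and moment arms.

    ``moment = sum_m sign_m * F_see_m(t) * arm_m(t) / 1000`` with arms in mm
    and forces in N.  Plantar-flexors and the dorsi-flexor carry opposite
    signs.
    """
    if set(trajectories) != set(moment_arms):
        raise ValueError("trajectories and moment arms must cover the same muscles")
    total = None
    for m, traj in trajectories.items():
        arm = np.asarray(moment_arms[m], dtype=float)
        force = np.asarray(traj.see_force if hasattr(traj, "see_force") else traj,
                           dtype=float)
        if arm.shape != force.shape:
            raise ValueError(f"misaligned series for muscle {m}")
        contrib = float(signs[m]) * force * arm / 1000.0
        if hasattr(traj, "moment_contribution"):
            traj.moment_contribution = contrib
        total = contrib if total is None else total + contrib
    if total is None:
        raise ValueError("no muscles supplied")
    return total
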