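"""Subject-specific tendon and aponeurosis force-strain characterization.

During an isometric plantar-flexion ramp the tendon and the aponeurosis of a
pennate muscle stretch while the joint moment rises.  With the muscle-tendon
junction and fascicle landmarks tracked by ultrasound, the tendon and
aponeurosis strains can be paired with the normalized joint moment to estimate
each tissue's force-strain relationship in vivo.  The two tissues act as
springs in series, so a single equivalent tendon-aponeurosis (T-A) element can
be derived from the pair of curves and the rest-length ratio between them;
that equivalent element is what the Hill-type model consumes as its series
elastic element.

Conventions: lengths in millimetres, angles in radians, strains and forces
dimensionless (force normalized to the task or muscle maximum, in [0, 1]).
All quadratic curves are constrained through the origin: zero strain carries
zero force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import (
    DegenerateTrialError,
    InconsistentGeometryError,
    InvalidGeometryError,
    MonotoneViolationError,
    RankDeficiencyError,
)

__all__ = [
    "MuscleId",
    "RestGeometry",
    "ForceStrainCurve",
    "StrainSample",
    "tendon_strain",
    "aponeurosis_length",
    "aponeurosis_strain",
    "normalized_force",
    "fit_force_strain",
    "ta_ratio",
    "combine_ta_curve",
    "characterize_ramp",
]

#: Smallest strain retained by the fit; more negative samples are measurement
#: artefacts and are dropped with a warning.
MIN_STRAIN = -0.05


class MuscleId(str, Enum):
    """Ankle plantar-flexors and the dorsi-flexor tracked by the model."""

    GL = "GL"   # lateral head of gastrocnemius
    GM = "GM"   # medial head of gastrocnemius
    SOL = "SOL"  # soleus
    TA = "TA"   # tibialis anterior


@dataclass(frozen=True)
class RestGeometry:
    """Rest-position muscle-tendon geometry measured by ultrasound.

    The tibialis anterior carries only a literature ratio; its rest lengths
    may be absent (``None``).
    """

    muscle_id: MuscleId
    fascicle_length_rest: float | None = None  # mm
    pennation_rest: float | None = None        # rad
    tendon_length_rest: float | None = None    # mm
    aponeurosis_length_rest: float | None = None  # mm
    ratio: float | None = None  # tendon / (tendon + aponeurosis), in (0, 1)

    def __post_init__(self) -> None:
        for name in ("fascicle_length_rest", "tendon_length_rest",
                     "aponeurosis_length_rest"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {v}")
        if self.pennation_rest is not None and not (
                0 <= self.pennation_rest < np.pi / 2):
            raise InvalidGeometryError(
                f"pennation_rest must lie in [0, pi/2), got {self.pennation_rest}")
        if self.tendon_length_rest is not None and self.aponeurosis_length_rest is not None:
            derived = ta_ratio(self.tendon_length_rest, self.aponeurosis_length_rest)
            if self.ratio is None:
                object.__setattr__(self, "ratio", derived)
            elif abs(self.ratio - derived) > 1e-9:
                raise InvalidGeometryError(
                    f"stored ratio {self.ratio} disagrees with lengths-derived "
                    f"ratio {derived}")
        if self.ratio is not None and not (0 < self.ratio < 1):
            raise InvalidGeometryError(f"ratio must lie in (0, 1), got {self.ratio}")

    @property
    def mt_length_rest(self) -> float:
        """Rest muscle-tendon length implied by the series-path geometric model."""
        if None in (self.tendon_length_rest, self.aponeurosis_length_rest,
                    self.fascicle_length_rest, self.pennation_rest):
            raise InvalidGeometryError(
                f"{self.muscle_id}: rest lengths absent, mt rest length undefined")
        return (self.tendon_length_rest + self.aponeurosis_length_rest
                + self.fascicle_length_rest * np.cos(self.pennation_rest))


class CurveKind(str, Enum):
    TENDON = "tendon"
    APONEUROSIS = "aponeurosis"
    TA_COMBINED = "ta_combined"
    GENERIC = "generic"


@dataclass(frozen=True)
class ForceStrainCurve:
    """Quadratic normalized-force vs strain relationship through the origin.

    ``force(eps) = c2*eps**2 + c1*eps`` on ``[0, eps_max]``; beyond the
    measured range the curve is continued either by its tangent at ``eps_max``
    (default, keeps the curve monotone) or clamped at the end value.
    """

    kind: CurveKind
    c2: float
    c1: float
    eps_max: float
    extrapolation: str = "linear_tangent"  # or "clamp"

    def __post_init__(self) -> None:
        if self.eps_max <= 0:
            raise MonotoneViolationError(f"eps_max must be > 0, got {self.eps_max}")
        if self.extrapolation not in ("linear_tangent", "clamp"):
            raise ValueError(f"unknown extrapolation rule {self.extrapolation!r}")
        # strictly increasing on [0, eps_max]: derivative 2*c2*eps + c1 is
        # linear in eps, so checking both endpoints suffices
        if self.c1 < 0 or self.c1 + 2 * self.c2 * self.eps_max <= 0:
            raise MonotoneViolationError(
                f"curve not strictly increasing on [0, {self.eps_max}]: "
                f"coefficients ({self.c2}, {self.c1})")

    @property
    def coefficients(self) -> tuple[float, float, float]:
        """(c2, c1, c0) with c0 fixed at 0 by construction."""
        return (self.c2, self.c1, 0.0)

    def force(self, strain):
        """Normalized force at the given strain (array or scalar); slack -> 0."""
        eps = np.asarray(strain, dtype=float)
        fmax_slope = 2.0 * self.c2 * self.eps_max + self.c1
        f_at_max = self.c2 * self.eps_max**2 + self.c1 * self.eps_max
        inside = self.c2 * np.minimum(eps, self.eps_max) ** 2 \
            + self.c1 * np.minimum(eps, self.eps_max)
        if self.extrapolation == "linear_tangent":
            beyond = f_at_max + fmax_slope * (eps - self.eps_max)
        else:
            beyond = np.full_like(inside, f_at_max)
        out = np.where(eps > self.eps_max, beyond, inside)
        out = np.where(eps <= 0.0, 0.0, out)
        return out if out.ndim else float(out)

    def strain_at(self, force):
        """Invert force -> strain; analytic quadratic root with tangent branch.

        Well-defined for force >= 0; the root is verified and refined by
        bisection if the closed form drifts beyond 1e-10 in force.
        """
        f = np.asarray(force, dtype=float)
        if np.any(f < -1e-12):
            raise ValueError("cannot invert a negative normalized force")
        f = np.maximum(f, 0.0)
        f_at_max = self.c2 * self.eps_max**2 + self.c1 * self.eps_max
        slope = 2.0 * self.c2 * self.eps_max + self.c1
        if abs(self.c2) < 1e-14:
            eps = f / self.c1
        else:
            disc = self.c1**2 + 4.0 * self.c2 * f
            eps = np.where(
                disc >= 0,
                (-self.c1 + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * self.c2),
                np.nan,
            )
        if self.extrapolation == "linear_tangent":
            eps = np.where(f > f_at_max, self.eps_max + (f - f_at_max) / slope, eps)
        elif np.any(f > f_at_max + 1e-10):
            raise ValueError(
                "force exceeds curve maximum and extrapolation is 'clamp'")
        # safety net: refine any point whose residual exceeds tolerance
        bad = ~np.isfinite(eps) | (np.abs(np.asarray(self.force(eps)) - f) > 1e-10)
        if np.any(bad):
            from scipy.optimize import brentq

            flat = np.atleast_1d(eps).astype(float)
            fflat = np.atleast_1d(f)
            badf = np.atleast_1d(bad)
            hi = max(self.eps_max * 10.0, 1.0)
            for i in np.nonzero(badf)[0]:
                flat[i] = brentq(lambda e: self.force(e) - fflat[i], 0.0, hi,
                                 xtol=1e-14)
            eps = flat.reshape(np.shape(eps))
        return eps if np.ndim(eps) else float(eps)


@dataclass(frozen=True)
class StrainSample:
    """One force level of an isometric ramp with its paired tissue strains."""

    normalized_force: float
    tendon_strain: float | None = None
    aponeurosis_strain: float | None = None
    ta_strain: float | None = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.normalized_force <= 1.0 + 1e-9):
            raise ValueError(
                f"normalized_force must lie in [0, 1], got {self.normalized_force}")


def tendon_strain(tendon_length, tendon_length_rest: float):
    """Engineering strain of the free tendon relative to its rest length."""
    if tendon_length_rest <= 0:
        raise InvalidGeometryError(
            f"tendon rest length must be > 0, got {tendon_length_rest}")
    lt = np.asarray(tendon_length, dtype=float)
    out = (lt - tendon_length_rest) / tendon_length_rest
    return out if out.ndim else float(out)


def aponeurosis_length(mt_length, tendon_length, fascicle_length, pennation):
    """Aponeurosis length from the series muscle-tendon path geometry.

    The muscle-tendon unit is modelled as free tendon + aponeurosis in line,
    with the fascicle contributing its projection on that line:
    ``L_a = L_mt - L_t - L_f * cos(alpha)``.
    """
    mt = np.asarray(mt_length, dtype=float)
    pen = np.asarray(pennation, dtype=float)
    if np.any(~np.isfinite(mt)) or np.any(~np.isfinite(pen)):
        raise InvalidGeometryError("non-finite geometry input")
    if np.any(pen < 0) or np.any(pen >= np.pi / 2):
        raise InvalidGeometryError("pennation must lie in [0, pi/2)")
    la = mt - np.asarray(tendon_length, float) \
        - np.asarray(fascicle_length, float) * np.cos(pen)
    bad = np.nonzero(np.atleast_1d(la) <= 0)[0]
    if bad.size:
        raise InconsistentGeometryError(
            f"nonpositive aponeurosis length at time index {bad[0]} "
            f"({np.atleast_1d(la)[bad[0]]:.3f} mm)")
    return la if la.ndim else float(la)


def aponeurosis_strain(aponeurosis_length_series, aponeurosis_length_rest: float):
    """Engineering strain of the aponeurosis relative to its rest length."""
    if aponeurosis_length_rest <= 0:
        raise InvalidGeometryError(
            f"aponeurosis rest length must be > 0, got {aponeurosis_length_rest}")
    la = np.asarray(aponeurosis_length_series, dtype=float)
    out = (la - aponeurosis_length_rest) / aponeurosis_length_rest
    return out if out.ndim else float(out)


def normalized_force(moment):
    """Joint moment normalized by its task maximum (relative moment
    contribution and moment arm assumed constant over the isometric ramp)."""
    m = np.asarray(moment, dtype=float)
    peak = m.max() if m.size else 0.0
    if not np.isfinite(peak) or peak <= 0:
        raise DegenerateTrialError(
            f"moment series has nonpositive maximum ({peak}); cannot normalize")
    return m / peak


def fit_force_strain(samples, which: CurveKind | str,
                     extrapolation: str = "linear_tangent") -> ForceStrainCurve:
    """Least-squares quadratic of normalized force against strain, through the
    origin.

    Parameters
    ----------
    samples : sequence of StrainSample
        Must hold >= 5 usable samples spanning the normalized-force range.
    which : CurveKind
        Selects which strain field of the samples is fitted.

    Raises
    ------
    RankDeficiencyError
        If the strains do not constrain both coefficients.
    MonotoneViolationError
        If the fitted quadratic is not strictly increasing on the observed
        strain range.
    """
    which = CurveKind(which)
    attr = {
        CurveKind.TENDON: "tendon_strain",
        CurveKind.APONEUROSIS: "aponeurosis_strain",
        CurveKind.TA_COMBINED: "ta_strain",
    }[which]
    eps, f = [], []
    for s in samples:
        e = getattr(s, attr)
        if e is None:
            continue
        if e < MIN_STRAIN:
            warnings.warn(
                f"dropping sample with strain {e:.4f} < {MIN_STRAIN}",
                stacklevel=2)
            continue
        eps.append(e)
        f.append(s.normalized_force)
    eps = np.asarray(eps, float)
    f = np.asarray(f, float)
    if eps.size < 5:
        raise ValueError(f"need >= 5 usable samples, got {eps.size}")
    design = np.column_stack([eps**2, eps])
    if np.linalg.matrix_rank(design, tol=1e-12 * max(1.0, abs(eps).max())**2) < 2:
        raise RankDeficiencyError(
            "strain samples are rank-deficient (e.g. all zero strain); "
            "cannot fit a quadratic")
    coef, *_ = np.linalg.lstsq(design, f, rcond=None)
    eps_max = float(eps.max())
    try:
        return ForceStrainCurve(kind=which, c2=float(coef[0]), c1=float(coef[1]),
                                eps_max=eps_max, extrapolation=extrapolation)
    except MonotoneViolationError as exc:
        raise MonotoneViolationError(
            f"fitted {which.value} curve is non-monotone on [0, {eps_max:.4f}]"
        ) from exc


def ta_ratio(tendon_length_rest: float, aponeurosis_length_rest: float) -> float:
    """Rest-length ratio of the tendon to the whole T-A complex,
    ``L_t0 / (L_t0 + L_a0)``."""
    if tendon_length_rest <= 0 or aponeurosis_length_rest <= 0:
        raise InvalidGeometryError(
            "rest lengths must be > 0, got "
            f"({tendon_length_rest}, {aponeurosis_length_rest})")
    return tendon_length_rest / (tendon_length_rest + aponeurosis_length_rest)


def combine_ta_curve(tendon_curve: ForceStrainCurve,
                     apo_curve: ForceStrainCurve,
                     ratio: float,
                     force_grid=None) -> ForceStrainCurve:
    """Combine tendon and aponeurosis curves into one series T-A element.

    Two springs in series carry the same force; their elongations add.  At
    each force level F the complex strain is the rest-length-weighted average
    ``eps_TA(F) = r*eps_t(F) + (1-r)*eps_a(F)`` with r the tendon share of the
    rest length.  A fresh quadratic through the origin is fitted to those
    points.
    """
    if not (0 < ratio < 1):
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    if force_grid is None:
        force_grid = np.linspace(0.0, 1.0, 21)
    force_grid = np.asarray(force_grid, float)
    if force_grid.min() < -1e-12 or force_grid.max() > 1.0 + 1e-12:
        raise ValueError("force grid must lie within [0, 1]")
    eps_t = np.asarray(tendon_curve.strain_at(force_grid), float)
    eps_a = np.asarray(apo_curve.strain_at(force_grid), float)
    eps_ta = ratio * eps_t + (1.0 - ratio) * eps_a
    samples = [StrainSample(normalized_force=float(fv), ta_strain=float(ev))
               for fv, ev in zip(force_grid, eps_ta)]
    return fit_force_strain(samples, CurveKind.TA_COMBINED)


@dataclass
class CharacterizationResult:
    """Curves estimated from one isometric ramp, plus the raw samples."""

    tendon: ForceStrainCurve
    aponeurosis: ForceStrainCurve
    ta_combined: ForceStrainCurve
    ratio: float
    samples: list = field(default_factory=list)


def characterize_ramp(time_s, moment_Nm, tendon_length_mm, mt_length_mm,
                      fascicle_length_mm, pennation_rad,
                      rest: RestGeometry) -> CharacterizationResult:
    """Full characterization of one isometric ramp trial.

    Turns the tracked tendon length, the series-path aponeurosis length and
    the normalized joint moment into tendon, aponeurosis and combined T-A
    force-strain curves for the imaged muscle.
    """
    eps_t = tendon_strain(tendon_length_mm, rest.tendon_length_rest)
    la = aponeurosis_length(mt_length_mm, tendon_length_mm,
                            fascicle_length_mm, pennation_rad)
    eps_a = aponeurosis_strain(la, rest.aponeurosis_length_rest)
    fnorm = normalized_force(moment_Nm)
    samples = [
        StrainSample(normalized_force=float(np.clip(fv, 0.0, 1.0)),
                     tendon_strain=float(et), aponeurosis_strain=float(ea))
        for fv, et, ea in zip(fnorm, eps_t, eps_a)
    ]
    tendon_curve = fit_force_strain(samples, CurveKind.TENDON)
    apo_curve = fit_force_strain(samples, CurveKind.APONEUROSIS)
    ta = combine_ta_curve(tendon_curve, apo_curve, rest.ratio)
    return CharacterizationResult(tendon=tendon_curve, aponeurosis=apo_curve,
                                  ta_combined=ta, ratio=rest.ratio,
                                  samples=samples)
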