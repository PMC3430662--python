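"""EMG conditioning and EMG-to-activation dynamics.

Raw surface EMG is band-pass filtered, rectified, low-pass filtered with a
zero-lag Butterworth filter and normalized to the subject's maximal envelope,
yielding a normalized excitation in [0, 1].  Excitation is turned into muscle
activation by a second-order recursive filter representing electromechanical
delay and twitch dynamics, followed by a nonlinear shaping function that
models the curved EMG-to-force relationship at low activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["ActivationParams", "process_emg", "activation_dynamics",
           "resample_series"]


@dataclass(frozen=True)
class ActivationParams:
    """Per-muscle EMG-to-activation parameters.

    The recursive filter is ``u_t = alpha*e_{t-d} - beta1*u_{t-1} -
    beta2*u_{t-2}`` with ``beta1 = gamma1 + gamma2``, ``beta2 =
    gamma1*gamma2`` and ``alpha = 1 + beta1 + beta2`` (unit steady-state
    gain).  ``shape_factor`` A in [-3, 0) bends the excitation-activation
    relation; A -> 0 recovers the identity.
    """

    emd_frames: int = 5          # electromechanical delay, samples (40 ms @ 125 Hz)
    gamma1: float = -0.5
    gamma2: float = -0.3
    shape_factor: float = -1.5   # A

    def __post_init__(self) -> None:
        if not (abs(self.gamma1) < 1 and abs(self.gamma2) < 1):
            raise ValueError(
                f"filter poles must satisfy |gamma|<1, got "
                f"({self.gamma1}, {self.gamma2})")
        if not (-3.0 <= self.shape_factor < 0) and self.shape_factor != 0.0:
            raise ValueError(
                f"shape_factor must lie in [-3, 0) (or exactly 0 for the "
                f"linear limit), got {self.shape_factor}")
        if self.emd_frames < 0:
            raise ValueError("electromechanical delay must be >= 0 samples")

    @property
    def beta1(self) -> float:
        return self.gamma1 + self.gamma2

    @property
    def beta2(self) -> float:
        return self.gamma1 * self.gamma2

    @property
    def alpha(self) -> float:
        # unit steady-state gain: alpha - beta1 - beta2 = 1 would hold for the
        # recursion u = alpha e - b1 u - b2 u only if gains subtract; with the
        # sign convention above the DC condition is alpha = 1 + b1 + b2.
        return 1.0 + self.beta1 + self.beta2


def process_emg(raw, fs: float, normalization_max: float,
                band=(10.0, 500.0), lowpass_hz: float = 6.0,
                order: int = 4) -> np.ndarray:
    """Band-pass, rectify, zero-lag low-pass and normalize a raw EMG trace.

    Parameters
    ----------
    raw : array
        Raw EMG samples (mV or arbitrary units), uniformly sampled.
    fs : float
        Sampling rate, Hz.  Must support the 10-500 Hz band (fs >= 1000).
    normalization_max : float
        Per-muscle maximal envelope value across all of the subject's trials.

    Returns
    -------
    Envelope in [0, 1] at the native sampling rate.
    """
    if normalization_max <= 0:
        raise ValueError(f"normalization_max must be > 0, got {normalization_max}")
    if fs < 2.0 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz cannot represent the {band} Hz band")
    x = np.asarray(raw, dtype=float)
    sos_bp = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos_bp, x)
    x = np.abs(x)
    sos_lp = sps.butter(order, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos_lp, x)
    return np.clip(env / normalization_max, 0.0, 1.0)


def activation_dynamics(envelope, params: ActivationParams,
                        min_activation: float = 0.01) -> np.ndarray:
    """Normalized excitation to muscle activation.

    Applies the delayed second-order recursion followed by the exponential
    shaping ``a = (exp(A*u) - 1)/(exp(A) - 1)``; set ``min_activation=0`` to
    inspect the unfloored output.
    """
    e = np.asarray(envelope, dtype=float)
    b1, b2, alpha = params.beta1, params.beta2, params.alpha
    d = params.emd_frames
    n = e.size
    u = np.zeros(n)
    for t in range(n):
        drive = alpha * e[t - d] if t >= d else 0.0
        u1 = u[t - 1] if t >= 1 else 0.0
        u2 = u[t - 2] if t >= 2 else 0.0
        u[t] = drive - b1 * u1 - b2 * u2
    a = shape_activation(u, params.shape_factor)
    if min_activation > 0:
        a = np.maximum(a, min_activation)
    return a


def shape_activation(u, shape_factor: float):
    """Nonlinear excitation-to-activation shaping; fixes 0 and 1, linear as
    the shape factor tends to 0."""
    u = np.asarray(u, dtype=float)
    if abs(shape_factor) < 1e-8:
        return u.copy()
    return np.expm1(shape_factor * u) / np.expm1(shape_factor)


def resample_series(time_s, values, target_fs: float):
    """Linear resampling onto a uniform grid at ``target_fs`` spanning the
    original time range.  Returns ``(new_time, new_values)``."""
    t = np.asarray(time_s, float)
    v = np.asarray(values, float)
    n = int(np.floor((t[-1] - t[0]) * target_fs)) + 1
    new_t = t[0] + np.arange(n) / target_fs
    return new_t, np.interp(new_t, t, v)
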