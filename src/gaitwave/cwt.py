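"""Order-1 Derivative-of-Gaussian CWT used as a smoothed differentiator.

Correlating a signal with dilated copies of the first derivative of a
Gaussian (gaus1) is equivalent to differentiating a Gaussian-smoothed copy
of the signal: in the small-scale limit the transform converges to the
plain first derivative, while larger scales trade temporal resolution for
noise suppression.  This module provides the transform itself, an exactly
calibrated derivative (unit ramp in -> unit slope out), and the
conventional scale <-> pseudo-frequency conversion for gaus1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .signal import Signal

__all__ = [
    "DEFAULT_CENTER_FREQUENCY",
    "WaveletSpec",
    "dog1",
    "cwt_at_scale",
    "smoothed_derivative",
    "scale_to_frequency",
    "frequency_to_scale",
]

#: Central-frequency constant of the gaus1 wavelet in cycles per unit of
#: dimensionless wavelet time.  This is the conventional table value (the
#: frequency of the best-fitting sinusoid, not the analytic spectral peak
#: 1/(2*pi) ~ 0.159); pseudo-frequency at scale a is fs * fc / a.
DEFAULT_CENTER_FREQUENCY = 0.2

# Unit-energy amplitude: integral of (C t exp(-t^2/2))^2 over R equals
# C^2 sqrt(pi)/2, so C = sqrt(2)/pi^(1/4).
_DOG1_AMPLITUDE = math.sqrt(2.0) / math.pi ** 0.25

#: Kernel support half-width in units of scale; |dog1| < 4e-6 of its peak
#: beyond 5 sigma, so truncation there is numerically inert.
SUPPORT_RADIUS = 5.0


def dog1(t):
    """First-derivative-of-Gaussian mother wavelet, unit L2 norm.

    psi(t) = -C * t * exp(-t^2 / 2) with C = sqrt(2) / pi^(1/4).  Odd,
    zero-mean, fast decay; the sign makes correlation with the *reversed*
    kernel a positive multiple of the smoothed derivative (the public
    transforms below take care of that calibration).
    """
    t = np.asarray(t, dtype=float)
    return -_DOG1_AMPLITUDE * t * np.exp(-0.5 * t * t)


@dataclass(frozen=True)
class WaveletSpec:
    """Dilation and calibration parameters of the analysis wavelet.

    ``order`` is fixed at 1 (gaus1) in this package; ``norm_constant`` is an
    extra multiplicative constant applied to the kernel (1 by default) and
    ``fc`` the central-frequency constant used for scale <-> frequency
    conversion.
    """

    scale: float
    order: int = 1
    norm_constant: float = 1.0
    fc: float = DEFAULT_CENTER_FREQUENCY

    def __post_init__(self) -> None:
        if self.order != 1:
            raise ValueError("only the order-1 Derivative of Gaussian is supported")
        if not self.scale >= 1:
            raise ValueError(f"scale must be >= 1, got {self.scale!r}")
        if not self.norm_constant > 0:
            raise ValueError("norm_constant must be positive")
        if not self.fc > 0:
            raise ValueError("fc must be positive")


@lru_cache(maxsize=512)
def _kernel(scale: float) -> np.ndarray:
    """Sampled, 1/sqrt(scale)-normalized wavelet on +-SUPPORT_RADIUS*scale."""
    half = int(math.ceil(SUPPORT_RADIUS * scale))
    k = np.arange(-half, half + 1, dtype=float)
    return dog1(k / scale) / math.sqrt(scale)


@lru_cache(maxsize=512)
def _ramp_gain(scale: float) -> float:
    """Interior response of the sign-calibrated transform to a unit-slope-
    per-sample ramp; exact for any linear-phase kernel, positive."""
    w = _kernel(scale)
    half = w.size // 2
    k = np.arange(-half, half + 1, dtype=float)
    return float(-np.dot(k, w))


def cwt_at_scale(sig: Signal, spec: WaveletSpec) -> Signal:
    """Single-scale CWT of ``sig`` with the gaus1 wavelet.

    Discrete correlation with the scaled, 1/sqrt(a)-normalized wavelet,
    sign-calibrated so the output is a positive multiple of the smoothed
    derivative dy/dt.  Boundaries use symmetric signal extension to avoid
    wrap-around artifacts near trial edges.

    Raises
    ------
    ValueError
        If the wavelet support exceeds the signal length (insufficient
        signal duration for this scale).
    """
    w = _kernel(spec.scale)
    if w.size > len(sig):
        raise ValueError(
            f"insufficient signal duration: scale {spec.scale} needs a "
            f"{w.size}-sample wavelet support but the signal has {len(sig)} samples"
        )
    if spec.norm_constant != 1.0:
        w = w * spec.norm_constant
    out = -ndimage.correlate1d(sig.samples, w, mode="reflect")
    return Signal(out, sig.fs, sig.t0)


def smoothed_derivative(sig: Signal, scale: float) -> Signal:
    """Gaussian-smoothed first derivative of ``sig`` in signal-units/s.

    The raw transform is rescaled by its exact interior response to a unit
    ramp, so a ramp of slope c returns c away from the boundaries and, for
    smooth inputs, the output converges to dy/dt as the scale decreases.
    """
    spec = WaveletSpec(scale=scale)
    raw = cwt_at_scale(sig, spec)
    gain = _ramp_gain(spec.scale) / sig.fs
    return Signal(raw.samples / gain, sig.fs, sig.t0)


def scale_to_frequency(scale: float, fs: float, fc: float = DEFAULT_CENTER_FREQUENCY) -> float:
    """Pseudo-frequency (Hz) of the gaus1 wavelet at ``scale``: fs * fc / scale."""
    if not (scale > 0 and fs > 0 and fc > 0):
        raise ValueError("scale, fs and fc must all be positive")
    return fs * fc / scale


def frequency_to_scale(f: float, fs: float, fc: float = DEFAULT_CENTER_FREQUENCY) -> float:
    """Scale whose pseudo-frequency is ``f`` Hz: fs * fc / f (inverse of
    :func:`scale_to_frequency`, round-trips to machine precision)."""
    if not (f > 0 and fs > 0 and fc > 0):
        raise ValueError("f, fs and fc must all be positive")
    return fs * fc / f
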