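"""Stimulus waveforms and the stochastic current used in every protocol.

All deterministic stimuli are pure functions of time; each protocol object
also knows how to describe itself to the compiled integration kernel
(kind code + parameter vector).  The additive white-noise current
I_noise = D dW is handled separately by the integrator as an Euler-Maruyama
increment on V: (D / C) sqrt(dt) * N(0, 1) per step, so with C = 1 the
numerical value of D matches the intensity used in the reference protocols.
The discretization convention is isolated in :func:`noise_increment`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "ZapSpec", "NoiseSpec",
    "Constant", "SquarePulse", "Ramp", "Zap", "Sine",
    "zap_current", "ramp_current", "square_pulse", "sine_current",
    "noise_increment", "protocol_from_dict",
]


@dataclass
class ZapSpec:
    """Swept-sine (ZAP) stimulus: I = Istim sin(2 pi f(t) t) with
    f(t) = fmin + (fmax - fmin) t / T, t and T in seconds.

    The phase is the literal product 2 pi f(t) t (so the instantaneous
    frequency runs ahead of f(t)); the impedance pipeline is insensitive to
    the chirp convention because it forms an FFT ratio on an absolute
    frequency axis.
    """

    Istim: float = 0.01   # uA/cm^2
    fmin: float = 0.0     # Hz
    fmax: float = 20.0    # Hz
    T: float = 20.0       # s

    def __post_init__(self) -> None:
        if self.Istim <= 0:
            raise ValueError("Istim must be positive")
        if not (0 <= self.fmin < self.fmax):
            raise ValueError("need 0 <= fmin < fmax")
        if self.T <= 0:
            raise ValueError("sweep duration must be positive")


@dataclass
class NoiseSpec:
    """Additive white-noise current: intensity D (uA ms^1/2 / cm^2 under the
    Euler-Maruyama reading) and RNG seed."""

    D: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("noise intensity D must be non-negative")


def zap_current(t, z: ZapSpec):
    """ZAP current at time ``t`` in **ms** (vectorized); 0 outside [0, T]."""
    t = np.asarray(t, dtype=float)
    ts = t / 1000.0
    f = z.fmin + (z.fmax - z.fmin) * ts / z.T
    out = z.Istim * np.sin(2.0 * np.pi * f * ts)
    return np.where((ts < 0.0) | (ts > z.T), 0.0, out)


def ramp_current(t, rate: float, onset: float = 0.0):
    """Linear current ramp: 0 before ``onset`` (ms), then rate * (t - onset).

    ``rate`` is in uA/cm^2 per ms (the reference fast/slow ramps are
    1 uA per 100 ms -> 0.01, and 0.3 uA per 100 ms -> 0.003).  Never capped:
    in the first-spike protocols the spike fires long before saturation
    would matter.
    """
    if rate <= 0:
        raise ValueError("ramp rate must be positive")
    t = np.asarray(t, dtype=float)
    return np.where(t < onset, 0.0, rate * (t - onset))


def square_pulse(t, amplitude: float, onset: float, duration: float):
    """Square current pulse on the half-open window [onset, onset+duration) ms."""
    if duration <= 0:
        raise ValueError("pulse duration must be positive")
    t = np.asarray(t, dtype=float)
    return np.where((t >= onset) & (t < onset + duration), amplitude, 0.0)


def sine_current(t, amplitude: float, f1: float, onset: float = 0.0):
    """Single-frequency sinusoid a sin(2 pi f1 t), f1 in Hz, t in ms."""
    t = np.asarray(t, dtype=float)
    out = amplitude * np.sin(2.0 * np.pi * f1 * (t - onset) / 1000.0)
    return np.where(t < onset, 0.0, out)


def noise_increment(ns: NoiseSpec, dt: float, rng: np.random.Generator,
                    C: float = 1.0, size=None):
    """Euler-Maruyama voltage increment(s) for one step of length ``dt`` ms:
    (D / C) sqrt(dt) * N(0, 1).  Reproducible given the generator state."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if ns.D == 0.0:
        return np.zeros(size) if size is not None else 0.0
    return ns.D / C * np.sqrt(dt) * rng.standard_normal(size)


# --- protocol objects understood by the integrator -------------------------

@dataclass
class Constant:
    amplitude: float = 0.0

    kind = _kernels.CONSTANT

    def kernel_params(self) -> np.ndarray:
        return np.array([self.amplitude, 0.0, 0.0, 0.0])

    def __call__(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.amplitude)


@dataclass
class SquarePulse:
    amplitude: float
    onset: float
    duration: float

    kind = _kernels.SQUARE

    def kernel_params(self) -> np.ndarray:
        return np.array([self.amplitude, self.onset, self.duration, 0.0])

    def __call__(self, t):
        return square_pulse(t, self.amplitude, self.onset, self.duration)


@dataclass
class Ramp:
    rate: float           # uA/cm^2 per ms
    onset: float = 0.0

    kind = _kernels.RAMP

    def kernel_params(self) -> np.ndarray:
        return np.array([self.rate, self.onset, 0.0, 0.0])

    def __call__(self, t):
        return ramp_current(t, self.rate, self.onset)


@dataclass
class Zap:
    spec: ZapSpec

    kind = _kernels.ZAP

    def kernel_params(self) -> np.ndarray:
        z = self.spec
        return np.array([z.Istim, z.fmin, z.fmax, z.T * 1000.0])

    def __call__(self, t):
        return zap_current(t, self.spec)


@dataclass
class Sine:
    amplitude: float
    f1: float             # Hz
    onset: float = 0.0

    kind = _kernels.SINE

    def kernel_params(self) -> np.ndarray:
        return np.array([self.amplitude, self.f1, self.onset, 0.0])

    def __call__(self, t):
        return sine_current(t, self.amplitude, self.f1, self.onset)


def protocol_from_dict(d: dict):
    """Build a protocol from a flat config mapping with a ``kind`` key."""
    d = dict(d)
    kind = d.pop("kind")
    table = {
        "constant": Constant,
        "square_pulse": SquarePulse,
        "ramp": Ramp,
        "sine": Sine,
    }
    if kind == "zap":
        return Zap(ZapSpec(**d))
    try:
        cls = table[kind]
    except KeyError:
        raise ValueError(f"unknown stimulus kind {kind!r}") from None
    return cls(**d)
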