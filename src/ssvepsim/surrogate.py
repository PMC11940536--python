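"""Synthetic SSVEP surrogates: stimulus-locked sinusoids plus 1/f noise.

An SSVEP recorded during flicker stimulation is phase-locked to the
stimulus: its spectrum carries narrow peaks at the stimulus frequency f0
and its harmonics riding on broadband background activity.  The surrogate
reproduces exactly that band-energy structure — a sum of harmonic
sinusoids with random phases plus coloured (1/f^β) noise of controlled
total power — so weight identification, spectrum fitting and the demo
decoding pipeline can run without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries

__all__ = ["SurrogateSpec", "generate_surrogate"]


@dataclass(frozen=True)
class SurrogateSpec:
    """Stimulus-locked surrogate signal specification.

    ``harmonic_amps`` are the amplitudes (mV) of f0, 2·f0, 3·f0.  The noise
    component has power-law PSD ∝ 1/f^β with total variance
    ``noise_power`` (mV²).  The sampling rate must resolve the third
    harmonic (fs > 2·3·f0).
    """

    f0: float = 10.0
    harmonic_amps: tuple[float, ...] = (1.0, 0.5, 0.25)
    noise_exponent: float = 1.0
    noise_power: float = 0.3
    duration: float = 4.0
    fs: float = 1024.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.f0 > 0):
            raise ValueError("stimulus frequency must be positive")
        if self.fs <= 2 * len(self.harmonic_amps) * self.f0:
            raise ValueError(
                f"fs = {self.fs} cannot resolve harmonic "
                f"{len(self.harmonic_amps)}·f0 = {len(self.harmonic_amps) * self.f0} Hz"
            )
        if self.noise_power < 0:
            raise ValueError("noise_power must be nonnegative")


def _colored_noise(n: int, beta: float, power: float, fs: float, rng) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD ∝ 1/f^β and variance ``power``."""
    if power == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    shaped = np.fft.irfft(spec * shape, n=n)
    std = shaped.std()
    if std > 0:
        shaped *= np.sqrt(power) / std
    return shaped


def generate_surrogate(spec: SurrogateSpec) -> TimeSeries:
    """Deterministic (per seed) surrogate SSVEP time series."""
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration * spec.fs)
    t = np.arange(n) / spec.fs
    v = np.zeros(n)
    for k, amp in enumerate(spec.harmonic_amps, start=1):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        v += amp * np.sin(2.0 * np.pi * k * spec.f0 * t + phase)
    v += _colored_noise(n, spec.noise_exponent, spec.noise_power, spec.fs, rng)
    return TimeSeries(fs=spec.fs, values=v)
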