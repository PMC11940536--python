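"""Bidirectionally coupled occipital–parietal multi-dynamic model.

The two regions exchange firing-rate signals through their pyramidal
populations: a region's output potential is de-meaned (subtracting its
running mean over the simulation so far), passed through the static
sigmoid, scaled by a coupling gain (o_p: occipital→parietal, p_o:
parietal→occipital), convolved with a cross-regional encoder — a weighted
parallel bank of excitatory kernels — and added to the other region's
external input at the same summing junction as the noise drive.

With both gains zero the two regions factorise exactly into independent
single-region simulations (each region draws its noise from its own
sub-stream of the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import SigmoidParams, SimulationConfig, SimulationDiverged, TimeSeries, sigmoid
from .region import (
    KernelBank,
    OscillatorWeights,
    RegionParams,
    RegionState,
    _RegionIntegrator,
    region_output,
)

__all__ = [
    "CouplingParams",
    "CoupledModelSpec",
    "CoupledOutput",
    "coupling_signal",
    "simulate_coupled",
    "region_seeds",
]


@dataclass(frozen=True)
class CouplingParams:
    """Coupling gains and the cross-regional encoder settings.

    ``encoder_bank``/``encoder_weights`` default to None, meaning each
    direction reuses the source region's own excitatory kernel bank and
    oscillator weights.  ``delay_steps`` is an optional integer conduction
    delay between regions (default 0: instantaneous).
    """

    o_p: float = 0.0
    p_o: float = 0.0
    encoder_bank: KernelBank | None = None
    encoder_weights: OscillatorWeights | None = None
    delay_steps: int = 0

    def __post_init__(self) -> None:
        if self.o_p < 0 or self.p_o < 0:
            raise ValueError("coupling gains must be nonnegative")
        if self.delay_steps < 0:
            raise ValueError("delay_steps must be nonnegative")


@dataclass(frozen=True)
class CoupledModelSpec:
    """Two regions, their coupling, and shared integration settings."""

    occipital: RegionParams = field(default_factory=RegionParams)
    parietal: RegionParams = field(default_factory=RegionParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    cfg: SimulationConfig = field(default_factory=SimulationConfig)


@dataclass
class CoupledOutput:
    """Post-burn-in outputs of both regions (equal length, shared fs)."""

    occipital: TimeSeries
    parietal: TimeSeries

    def __post_init__(self) -> None:
        if len(self.occipital) != len(self.parietal) or self.occipital.fs != self.parietal.fs:
            raise ValueError("regional outputs must share length and sampling rate")


def coupling_signal(
    source_state: RegionState,
    weights: OscillatorWeights,
    gain: float,
    sig: SigmoidParams,
    history_mean: float,
) -> float:
    """Firing-rate drive projected from one region to the other.

    The source's output potential x = Σ w·y1 − Σ w·y2 is first converted to
    a mean spike density through the sigmoid, then de-meaned against the
    running mean of that spike density over the simulation so far, and
    scaled by the coupling gain: ``gain · (S(x) − history_mean)``.  The
    de-meaning makes the projected drive zero-mean, so coupling injects the
    source's oscillation without shifting the target's operating point.
    """
    if gain < 0:
        raise ValueError("coupling gain must be nonnegative")
    x = region_output(source_state, weights)
    return gain * (sigmoid(x, sig) - history_mean)


class _Encoder:
    """Weighted parallel excitatory kernel bank in the coupling path."""

    def __init__(self, bank: KernelBank, weights: OscillatorWeights, dt: float):
        self.dt = dt
        G = np.array([k.G for k in bank.exc])
        W = np.array([k.omega for k in bank.exc])
        self._GW, self._W, self._W2 = G * W, W, W * W
        self._w = weights.as_array()
        self.y = np.zeros(3)
        self.yd = np.zeros(3)

    def step(self, drive: float) -> float:
        ydd = self._GW * drive - 2.0 * self._W * self.yd - self._W2 * self.y
        self.y = self.y + self.dt * self.yd
        self.yd = self.yd + self.dt * ydd
        return float(self._w @ self.y)


class _RunningMean:
    """Streaming mean so the de-mean operation stays causal."""

    def __init__(self) -> None:
        self.n = 0
        self.mean = 0.0

    def update(self, x: float) -> float:
        self.n += 1
        self.mean += (x - self.mean) / self.n
        return self.mean


def region_seeds(seed: int) -> tuple[np.random.SeedSequence, np.random.SeedSequence]:
    """Independent child seeds for (occipital, parietal) noise streams."""
    occ, par = np.random.SeedSequence(seed).spawn(2)
    return occ, par


def simulate_coupled(
    spec: CoupledModelSpec,
    seed: int | None = None,
    rngs: tuple[np.random.Generator, np.random.Generator] | None = None,
    acausal_demean: bool = False,
) -> CoupledOutput:
    """Simulate both regions in lockstep and return their outputs.

    Per step, each region's coupling signal (gain · S(RM(y_out))) drives a
    cross-regional encoder whose output is added to the other region's
    external input rate.  Noise streams are independent per region, derived
    from ``seed`` (default: the spec's config seed) by seed-sequence
    spawning; ``rngs`` overrides them for explicit bookkeeping.

    ``acausal_demean=True`` replaces the causal running mean with a two-pass
    scheme: a first pass records each region's whole-signal output mean with
    coupling computed causally, then the simulation is repeated de-meaning
    against those fixed means (post-hoc replication mode).
    """
    cfg = spec.cfg
    if rngs is None:
        occ_ss, par_ss = region_seeds(cfg.seed if seed is None else seed)
        rngs = (np.random.default_rng(occ_ss), np.random.default_rng(par_ss))
    noise = (
        rngs[0].normal(spec.occipital.noise.mu, spec.occipital.noise.sigma, cfg.n_steps),
        rngs[1].normal(spec.parietal.noise.mu, spec.parietal.noise.sigma, cfg.n_steps),
    )

    if acausal_demean:
        # first pass fixes each region's whole-run output mean; the second
        # pass de-means against those constants with identical noise
        first = _run_coupled(spec, noise, fixed_means=None)
        means = (
            float(np.mean(sigmoid(first[0], spec.occipital.sigmoid))),
            float(np.mean(sigmoid(first[1], spec.parietal.sigmoid))),
        )
        occ, par = _run_coupled(spec, noise, fixed_means=means)
    else:
        occ, par = _run_coupled(spec, noise, fixed_means=None)
    return CoupledOutput(
        occipital=TimeSeries(fs=cfg.fs, values=occ),
        parietal=TimeSeries(fs=cfg.fs, values=par),
    )


def _run_coupled(spec, noise, fixed_means):
    cfg = spec.cfg
    dt, n_steps, n_burn = cfg.dt, cfg.n_steps, cfg.n_burn
    regions = (
        _RegionIntegrator(spec.occipital, dt, "occipital"),
        _RegionIntegrator(spec.parietal, dt, "parietal"),
    )
    gains = (spec.coupling.o_p, spec.coupling.p_o)  # gain applied to each source
    banks = (
        spec.coupling.encoder_bank or spec.occipital.bank,
        spec.coupling.encoder_bank or spec.parietal.bank,
    )
    enc_w = (
        spec.coupling.encoder_weights or spec.occipital.weights,
        spec.coupling.encoder_weights or spec.parietal.weights,
    )
    encoders = (_Encoder(banks[0], enc_w[0], dt), _Encoder(banks[1], enc_w[1], dt))
    means = (_RunningMean(), _RunningMean())
    delay = spec.coupling.delay_steps
    # per-direction delay line of encoder outputs (index 0: occ→par drive)
    buffers = (np.zeros(delay + 1), np.zeros(delay + 1))

    outs = (np.empty(n_steps - n_burn), np.empty(n_steps - n_burn))
    # divergence is raised explicitly; silence the intermediate overflow
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(n_steps):
            slot = step % (delay + 1)
            # coupling drives from pre-update source states
            for i, region in enumerate(regions):
                s = sigmoid(region.output, region.params.sigmoid)
                if fixed_means is None:
                    mean = means[i].update(s)
                else:
                    mean = fixed_means[i]
                c = gains[i] * (s - mean)
                buffers[i][slot] = encoders[i].step(c)
            # each region receives the other's (possibly delayed) encoded signal
            tap = (step - delay) % (delay + 1)
            for i, region in enumerate(regions):
                incoming = buffers[1 - i][tap] if step >= delay else 0.0
                e = region.step(step, noise[i][step] + incoming)
                if step >= n_burn:
                    outs[i][step - n_burn] = e
    return outs
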