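"""Traditional single-region neural mass model (Jansen–Rit lineage).

A cortical region is modelled as three interacting neuronal subpopulations
— pyramidal cells, excitatory interneurons and inhibitory interneurons —
each described by its average membrane potential.  Two transformations
define the dynamics:

* a static sigmoid ``S(v)`` converting mean membrane potential to mean
  firing rate at the soma, and
* a synaptic impulse response ``h(t) = G·ω·t·e^{−ωt}`` converting
  presynaptic firing rate to a postsynaptic potential, realised as a
  second-order ODE per subpopulation.

The EEG-like output is ``E(t) = y1(t) − y2(t)``, the difference between the
excitatory and inhibitory interneuron potentials impinging on the pyramidal
population.  External drive enters as Gaussian white noise
``n(t) ~ N(μ, σ²)`` drawn independently at each integration step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SigmoidParams",
    "SynapticKernel",
    "ConnectivityConstants",
    "NoiseSpec",
    "SubpopulationState",
    "SimulationConfig",
    "TimeSeries",
    "SimulationDiverged",
    "sigmoid",
    "impulse_response",
    "region_derivatives",
    "simulate_traditional",
    "default_excitatory_kernel",
    "default_inhibitory_kernel",
]


class SimulationDiverged(RuntimeError):
    """Raised when the fixed-step integration produces non-finite state."""

    def __init__(self, step: int, time: float, context: str = "region"):
        self.step = step
        self.time = time
        super().__init__(
            f"simulation diverged in {context} at step {step} (t = {time:.6f} s); "
            "check gains, time constants and noise variance"
        )


@dataclass(frozen=True)
class SigmoidParams:
    """Potential-to-rate sigmoid S(v) = 2·e0 / (1 + exp(r·(v0 − v))).

    Parameters
    ----------
    e0
        Half-maximum firing rate (s⁻¹); the asymptotic maximum is 2·e0.
    v0
        Membrane potential at which the firing rate equals e0 (mV).
    r
        Steepness of the sigmoid (mV⁻¹).
    """

    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56

    def __post_init__(self) -> None:
        if not (self.e0 > 0):
            raise ValueError(f"e0 must be positive, got {self.e0}")
        if not (self.r > 0):
            raise ValueError(f"r must be positive, got {self.r}")


@dataclass(frozen=True)
class SynapticKernel:
    """Second-order synaptic response h(t) = G·ω·t·e^{−ωt} for t ≥ 0.

    ``G`` is the average synaptic gain (mV) and ``omega`` the inverse time
    constant (s⁻¹).  ``polarity`` is informational; the waveform is the
    same for excitatory and inhibitory synapses, only the wiring differs.
    """

    G: float
    omega: float
    polarity: str = "excitatory"

    def __post_init__(self) -> None:
        if not (self.G > 0):
            raise ValueError(f"synaptic gain G must be positive, got {self.G}")
        if not (self.omega > 0):
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def default_excitatory_kernel() -> SynapticKernel:
    """Standard excitatory kernel: Ge = 3.25 mV, ωe = 100 s⁻¹."""
    return SynapticKernel(G=3.25, omega=100.0, polarity="excitatory")


def default_inhibitory_kernel() -> SynapticKernel:
    """Standard inhibitory kernel: Gi = 22 mV, ωi = 50 s⁻¹."""
    return SynapticKernel(G=22.0, omega=50.0, polarity="inhibitory")


@dataclass(frozen=True)
class ConnectivityConstants:
    """Dimensionless synaptic connectivity coefficients C1..C4.

    Defaults follow the standard convention C = 135 with C1 = C,
    C2 = 0.8·C, C3 = C4 = 0.25·C, which places the uncoupled region in the
    alpha-oscillation regime for moderate input rates.
    """

    C1: float = 135.0
    C2: float = 108.0
    C3: float = 33.75
    C4: float = 33.75

    def __post_init__(self) -> None:
        for name in ("C1", "C2", "C3", "C4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class NoiseSpec:
    """External Gaussian white-noise drive N(mu, sigma2), in firing-rate units."""

    mu: float = 220.0
    sigma2: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be nonnegative, got {self.sigma2}")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)


@dataclass
class SubpopulationState:
    """Postsynaptic potential y (mV) and its first derivative ydot (mV/s)."""

    y: float = 0.0
    ydot: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Fixed-step integration settings.

    ``dt`` doubles as the output sampling step; the default 4/4096 s is the
    sampling time used throughout the simulations.  ``burn_in`` seconds are
    simulated and discarded so spectra are computed on the stationary part.
    """

    dt: float = 4.0 / 4096.0
    duration: float = 4.0
    burn_in: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if not (self.duration > self.burn_in >= 0):
            raise ValueError("need duration > burn_in >= 0")

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @property
    def n_burn(self) -> int:
        return round(self.burn_in / self.dt)

    @property
    def n_out(self) -> int:
        return round((self.duration - self.burn_in) / self.dt)


@dataclass
class TimeSeries:
    """A uniformly sampled signal: sampling rate ``fs`` (Hz) and amplitudes (mV)."""

    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs

    def __len__(self) -> int:
        return len(self.values)


def sigmoid(v, p: SigmoidParams):
    """Mean firing rate (s⁻¹) for membrane potential ``v`` (mV).

    S(v) = 2·e0 / (1 + exp(r·(v0 − v))); strictly increasing, bounded in
    (0, 2·e0).  Scalar or array ``v``.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    out = 2.0 * p.e0 * expit(p.r * (v - p.v0))
    return float(out) if out.ndim == 0 else out


def impulse_response(k: SynapticKernel, t):
    """Evaluate h(t) = u(t)·G·ω·t·e^{−ωt}; zero for t < 0.

    The response peaks at t = 1/ω with value G/e and integrates to G/ω.
    """
    t = np.asarray(t, dtype=float)
    tc = np.clip(t, 0.0, None)
    h = k.G * k.omega * tc * np.exp(-k.omega * tc)
    return float(h) if h.ndim == 0 else h


def region_derivatives(
    state: np.ndarray,
    input_rate: float,
    sig: SigmoidParams,
    exc: SynapticKernel,
    inh: SynapticKernel,
    conn: ConnectivityConstants,
) -> np.ndarray:
    """Right-hand side of the traditional model's six first-order ODEs.

    ``state`` is (y0, y1, y2, y3, y4, y5): potentials of the pyramidal,
    excitatory-interneuron and inhibitory-interneuron subpopulations and
    their derivatives.  Each subpopulation obeys
    ÿ = G·ω·x − 2ω·ẏ − ω²·y with presynaptic drive x:

    * pyramidal: S(y1 − y2)
    * excitatory interneurons: input_rate + C2·S(C1·y0)
    * inhibitory interneurons: C4·S(C3·y0)
    """
    y0, y1, y2, y3, y4, y5 = state
    d0 = sigmoid(y1 - y2, sig)
    d1 = input_rate + conn.C2 * sigmoid(conn.C1 * y0, sig)
    d2 = conn.C4 * sigmoid(conn.C3 * y0, sig)
    Gwe = exc.G * exc.omega
    Gwi = inh.G * inh.omega
    return np.array(
        [
            y3,
            y4,
            y5,
            Gwe * d0 - 2.0 * exc.omega * y3 - (exc.omega * exc.omega) * y0,
            Gwe * d1 - 2.0 * exc.omega * y4 - (exc.omega * exc.omega) * y1,
            Gwi * d2 - 2.0 * inh.omega * y5 - (inh.omega * inh.omega) * y2,
        ]
    )


def simulate_traditional(
    noise: NoiseSpec,
    cfg: SimulationConfig,
    sig: SigmoidParams | None = None,
    exc: SynapticKernel | None = None,
    inh: SynapticKernel | None = None,
    conn: ConnectivityConstants | None = None,
    external_drive: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Integrate the traditional model and return E(t) = y1 − y2 after burn-in.

    Fixed-step explicit Euler at ``cfg.dt``; the external input at each step
    is an independent draw from N(mu, sigma2) (plus ``external_drive`` if
    given, sampled at 1/dt over the whole simulated interval).  The same
    seed always yields the same output.
    """
    sig = sig or SigmoidParams()
    exc = exc or default_excitatory_kernel()
    inh = inh or default_inhibitory_kernel()
    conn = conn or ConnectivityConstants()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_steps, n_burn = cfg.n_steps, cfg.n_burn
    dt = cfg.dt
    noise_draws = rng.normal(noise.mu, noise.sigma, n_steps)
    if external_drive is not None:
        ext = np.asarray(external_drive, dtype=float)
        if len(ext) != n_steps:
            raise ValueError(
                f"external_drive must have {n_steps} samples, got {len(ext)}"
            )
        noise_draws = noise_draws + ext

    # Precomputed products keep the per-branch arithmetic identical to the
    # multi-branch integrator, so the degenerate-bank check is exact.
    Gwe, Gwi = exc.G * exc.omega, inh.G * inh.omega
    we2, wi2 = exc.omega * exc.omega, inh.omega * inh.omega
    we, wi = exc.omega, inh.omega

    y = np.zeros(3)
    yd = np.zeros(3)
    out = np.empty(n_steps - n_burn)
    # overflow in a diverging run surfaces as SimulationDiverged, not a warning
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(n_steps):
            d0 = sigmoid(y[1] - y[2], sig)
            d1 = noise_draws[step] + conn.C2 * sigmoid(conn.C1 * y[0], sig)
            d2 = conn.C4 * sigmoid(conn.C3 * y[0], sig)
            ydd0 = Gwe * d0 - 2.0 * we * yd[0] - we2 * y[0]
            ydd1 = Gwe * d1 - 2.0 * we * yd[1] - we2 * y[1]
            ydd2 = Gwi * d2 - 2.0 * wi * yd[2] - wi2 * y[2]
            y = y + dt * yd
            yd = yd + dt * np.array([ydd0, ydd1, ydd2])
            e = y[1] - y[2]
            if not math.isfinite(e):
                raise SimulationDiverged(step, step * dt, "traditional region")
            if step >= n_burn:
                out[step - n_burn] = e
    return TimeSeries(fs=cfg.fs, values=out)
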