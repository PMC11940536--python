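"""Particle swarm optimisation of the coupled model against a target spectrum.

The free parameters θ (by default the two coupling gains and each region's
noise mean and variance) are fitted by minimising the mean squared error
between the model's occipital power spectrum and a target spectrum on a
shared frequency grid.  The swarm follows the classic inertia formulation:

    V ← k·V + c1·r1·(pbest − X) + c2·r2·(gbest − X),   X ← X + V

with fresh uniform r1, r2 per particle and dimension, positions clipped to
their bounds (the offending velocity component is zeroed), and personal /
global bests tracked by objective value.  Default swarm settings: 50
particles, 70 iterations, inertia 0.5, cognitive and social factors 1.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .coupled import CoupledModelSpec, simulate_coupled
from .core import NoiseSpec
from .spectral import Spectrum, compute_psd

__all__ = [
    "PSOConfig",
    "SwarmState",
    "FitResult",
    "DEFAULT_BOUNDS",
    "PARAMETER_NAMES",
    "spectrum_mse",
    "init_swarm",
    "pso_step",
    "minimize",
    "fit_model",
]

logger = logging.getLogger(__name__)

PARAMETER_NAMES = ("o_p", "p_o", "mu_o", "sigma2_o", "mu_p", "sigma2_p")

#: Search bounds per dimension.  The noise-mean bounds [22, 2200] and
#: variance bounds [2, 20000] are the stated search ranges; coupling-gain
#: bounds are unprinted and default to [0, 2000], covering all fitted values.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "o_p": (0.0, 2000.0),
    "p_o": (0.0, 2000.0),
    "mu_o": (22.0, 2200.0),
    "sigma2_o": (2.0, 20000.0),
    "mu_p": (22.0, 2200.0),
    "sigma2_p": (2.0, 20000.0),
}


@dataclass(frozen=True)
class PSOConfig:
    n_particles: int = 50
    n_iters: int = 70
    inertia: float = 0.5
    c1: float = 1.5
    c2: float = 1.5
    bounds: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if not (0.0 < self.c1 + self.c2 < 4.0):
            raise ValueError("c1 + c2 must lie in (0, 4)")
        for lo, hi in self.bounds:
            if not (lo < hi):
                raise ValueError(f"invalid bound ({lo}, {hi})")


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping of the swarm."""

    X: np.ndarray  # (n_particles, n_dims)
    V: np.ndarray
    pbest_X: np.ndarray
    pbest_val: np.ndarray
    gbest_x: np.ndarray
    gbest_val: float
    n_evals: int = 0


@dataclass
class FitResult:
    """Optimised parameters and the gbest-MSE trajectory (non-increasing)."""

    params: dict[str, float]
    best_value: float
    trajectory: np.ndarray
    n_evaluations: int


def spectrum_mse(target: Spectrum, model: Spectrum) -> float:
    """(1/n)·Σ (Y(f_i) − S(f_i;θ))² on the target's frequency grid.

    If the grids differ, the model spectrum is linearly interpolated onto
    the target grid; the model grid must cover the target grid.
    """
    if len(target.freqs) == len(model.freqs) and np.array_equal(target.freqs, model.freqs):
        s = model.power
    else:
        if target.freqs[0] < model.freqs[0] - 1e-9 or target.freqs[-1] > model.freqs[-1] + 1e-9:
            raise ValueError(
                "model spectrum does not cover the target frequency grid "
                f"([{model.freqs[0]:.3f}, {model.freqs[-1]:.3f}] vs "
                f"[{target.freqs[0]:.3f}, {target.freqs[-1]:.3f}] Hz)"
            )
        s = np.interp(target.freqs, model.freqs, model.power)
    return float(np.mean((target.power - s) ** 2))


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    vals = np.empty(len(X))
    for i, x in enumerate(X):
        try:
            v = float(objective(x))
        except FloatingPointError:
            v = np.inf
        if not np.isfinite(v):
            logger.warning("objective returned non-finite value at %s; treating as +inf", x)
            v = np.inf
        vals[i] = v
    return vals


def init_swarm(objective, cfg: PSOConfig, rng: np.random.Generator) -> SwarmState:
    """Uniformly sample particle positions within bounds, velocities at zero."""
    bounds = np.asarray(cfg.bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    X = rng.uniform(lo, hi, size=(cfg.n_particles, len(bounds)))
    V = np.zeros_like(X)
    vals = _evaluate(objective, X)
    best = int(np.argmin(vals))
    return SwarmState(
        X=X,
        V=V,
        pbest_X=X.copy(),
        pbest_val=vals.copy(),
        gbest_x=X[best].copy(),
        gbest_val=float(vals[best]),
        n_evals=len(X),
    )


def pso_step(swarm: SwarmState, objective, cfg: PSOConfig, rng: np.random.Generator) -> SwarmState:
    """One velocity/position update for every particle (in place)."""
    bounds = np.asarray(cfg.bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    shape = swarm.X.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    swarm.V = (
        cfg.inertia * swarm.V
        + cfg.c1 * r1 * (swarm.pbest_X - swarm.X)
        + cfg.c2 * r2 * (swarm.gbest_x[None, :] - swarm.X)
    )
    swarm.X = swarm.X + swarm.V
    out_of_bounds = (swarm.X < lo) | (swarm.X > hi)
    swarm.X = np.clip(swarm.X, lo, hi)
    swarm.V[out_of_bounds] = 0.0

    vals = _evaluate(objective, swarm.X)
    swarm.n_evals += len(vals)
    improved = vals < swarm.pbest_val
    swarm.pbest_val[improved] = vals[improved]
    swarm.pbest_X[improved] = swarm.X[improved]
    best = int(np.argmin(swarm.pbest_val))
    if swarm.pbest_val[best] < swarm.gbest_val:
        swarm.gbest_val = float(swarm.pbest_val[best])
        swarm.gbest_x = swarm.pbest_X[best].copy()
    return swarm


def minimize(objective, cfg: PSOConfig) -> tuple[np.ndarray, float, np.ndarray, int]:
    """Run the full swarm; returns (best_x, best_val, trajectory, n_evals).

    The trajectory holds the global-best objective value after
    initialisation and after each of the ``n_iters`` iterations
    (length n_iters + 1) and is non-increasing by construction.
    """
    if not cfg.bounds:
        raise ValueError("PSOConfig.bounds must be set")
    rng = np.random.default_rng(cfg.seed)
    swarm = init_swarm(objective, cfg, rng)
    traj = [swarm.gbest_val]
    for _ in range(cfg.n_iters):
        swarm = pso_step(swarm, objective, cfg, rng)
        traj.append(swarm.gbest_val)
    if not np.all(np.isfinite([swarm.gbest_val])):
        raise RuntimeError("all objective evaluations were non-finite; fit failed")
    return swarm.gbest_x, swarm.gbest_val, np.asarray(traj), swarm.n_evals


def _apply_params(spec: CoupledModelSpec, names: list[str], x: np.ndarray) -> CoupledModelSpec:
    values = dict(zip(names, x))
    coupling = spec.coupling
    occ, par = spec.occipital, spec.parietal
    if "o_p" in values or "p_o" in values:
        coupling = replace(
            coupling,
            o_p=values.get("o_p", coupling.o_p),
            p_o=values.get("p_o", coupling.p_o),
        )
    if "mu_o" in values or "sigma2_o" in values:
        occ = replace(
            occ,
            noise=NoiseSpec(
                mu=values.get("mu_o", occ.noise.mu),
                sigma2=values.get("sigma2_o", occ.noise.sigma2),
            ),
        )
    if "mu_p" in values or "sigma2_p" in values:
        par = replace(
            par,
            noise=NoiseSpec(
                mu=values.get("mu_p", par.noise.mu),
                sigma2=values.get("sigma2_p", par.noise.sigma2),
            ),
        )
    return replace(spec, occipital=occ, parietal=par, coupling=coupling)


def _template_params(spec: CoupledModelSpec) -> dict[str, float]:
    return {
        "o_p": spec.coupling.o_p,
        "p_o": spec.coupling.p_o,
        "mu_o": spec.occipital.noise.mu,
        "sigma2_o": spec.occipital.noise.sigma2,
        "mu_p": spec.parietal.noise.mu,
        "sigma2_p": spec.parietal.noise.sigma2,
    }


def fit_model(
    target: Spectrum,
    spec_template: CoupledModelSpec,
    free: list[str] | None = None,
    cfg: PSOConfig | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    sim_seed: int | None = None,
) -> FitResult:
    """Fit the coupled model's free parameters to a target spectrum.

    Every objective evaluation simulates the coupled model at the candidate
    θ with one fixed simulation seed (default: the template's config seed),
    so the objective is deterministic and pbest bookkeeping is well
    defined.  ``free`` selects which of the six named dimensions
    (o_p, p_o, mu_o, sigma2_o, mu_p, sigma2_p) are optimised; the rest stay
    at their template values.  With ``free=[]`` the template is evaluated
    once and returned unchanged.
    """
    if free is None:
        free = list(PARAMETER_NAMES)
    unknown = set(free) - set(PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter dimensions: {sorted(unknown)}")
    cfg = cfg or PSOConfig()
    sim_seed = spec_template.cfg.seed if sim_seed is None else sim_seed
    all_bounds = {**DEFAULT_BOUNDS, **(bounds or {})}

    def objective(x: np.ndarray) -> float:
        spec = _apply_params(spec_template, free, x)
        out = simulate_coupled(spec, seed=sim_seed)
        return spectrum_mse(target, compute_psd(out.occipital))

    if not free:
        mse = objective(np.empty(0))
        return FitResult(
            params=_template_params(spec_template),
            best_value=mse,
            trajectory=np.array([mse]),
            n_evaluations=1,
        )

    cfg = replace(cfg, bounds=tuple(all_bounds[name] for name in free))
    best_x, best_val, traj, n_evals = minimize(objective, cfg)
    params = _template_params(spec_template)
    params.update(dict(zip(free, (float(v) for v in best_x))))
    return FitResult(params=params, best_value=best_val, trajectory=traj, n_evaluations=n_evals)
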