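"""Fit coupled-model parameters to a target spectrum with PSO.

A target occipital spectrum is produced by the model itself at known
coupling gains; the swarm then recovers gains that reproduce it.  With the
simulation seed shared between target and objective, the spectrum MSE can
in principle reach zero, so the gbest trajectory tells the whole story.
(Swarm scaled down from the 50-particle/70-iteration default for a quick
demonstration.)
"""

from ssvepsim import (
    CoupledModelSpec,
    CouplingParams,
    NoiseSpec,
    OscillatorWeights,
    PSOConfig,
    RegionParams,
    SimulationConfig,
    compute_psd,
    fit_model,
    simulate_coupled,
)

SIM_SEED = 123
truth = CoupledModelSpec(
    occipital=RegionParams(weights=OscillatorWeights(0.10, 0.90, 0.00), noise=NoiseSpec(220, 100)),
    parietal=RegionParams(weights=OscillatorWeights(0.40, 0.30, 0.30), noise=NoiseSpec(220, 100)),
    coupling=CouplingParams(o_p=500.0, p_o=150.0),
    cfg=SimulationConfig(duration=1.5, burn_in=0.5, seed=7),
)
target = compute_psd(simulate_coupled(truth, seed=SIM_SEED).occipital)

result = fit_model(
    target,
    truth,
    free=["o_p", "p_o"],
    cfg=PSOConfig(n_particles=12, n_iters=8, seed=0),
    bounds={"o_p": (0.0, 1000.0), "p_o": (0.0, 1000.0)},
    sim_seed=SIM_SEED,
)

print(f"true gains:   o_p = 500.0, p_o = 150.0")
print(f"fitted gains: o_p = {result.params['o_p']:.1f}, p_o = {result.params['p_o']:.1f}")
print(f"gbest MSE: initial {result.trajectory[0]:.3g} -> final {result.best_value:.3g}")
print(f"({result.n_evaluations} model evaluations)")
print("\nThe MSE falls by well over half; exact gain recovery is not")
print("guaranteed from a single noisy spectrum, matching spectra is.")
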