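# ssvepsim

Simulation of steady-state visual evoked potentials (SSVEP) with a
multi-dynamic, two-region coupled neural mass model — plus the analysis
tooling that makes such a simulator useful for brain–computer interface
(BCI) work: band-energy weight identification, particle-swarm parameter
fitting against target spectra, consistency metrics, signal augmentation,
and an end-to-end command-decoding demo.

## Who this is for

SSVEP-based BCIs decode which flickering stimulus a user attends by the
stimulus-locked frequency content of occipital EEG.  Developing and testing
such systems against recorded EEG is slow and subject-dependent; a
physiologically grounded simulator lets you generate unlimited
stimulus-locked signals with controllable spectra, test decoding pipelines,
and study how cortical parameters shape the signal.  This package is for
researchers and engineers who want that simulator as a plain Python
library.

## The model

**Single region.**  A cortical region is three coupled neuronal
subpopulations (pyramidal cells, excitatory and inhibitory interneurons).
Mean membrane potential v becomes mean firing rate through the sigmoid

    S(v) = 2·e0 / (1 + exp(r·(v0 − v)))          (e0 = 2.5 s⁻¹, v0 = 6 mV, r = 0.56 mV⁻¹)

and presynaptic rate becomes postsynaptic potential through the synaptic
kernel h(t) = G·ω·t·e^(−ωt), realised as ÿ = G·ω·x − 2ω·ẏ − ω²·y per
subpopulation.  With the classic constants (Ge = 3.25 mV, ωe = 100 s⁻¹,
Gi = 22 mV, ωi = 50 s⁻¹, connectivity C = 135) and Gaussian white-noise
drive n(t) ~ N(μ, σ²), the EEG-like output E(t) = y1 − y2 oscillates in
the alpha band.

**Multi-dynamic region.**  Real EEG is broadband.  Here every
subpopulation runs three kernels in parallel — slow (δ), standard (α) and
fast (γ) time constants — and the branch outputs are merged with convex
weights (w_δ, w_α, w_γ), Σw = 1.  The weights are identified from data:
compute the signal's power spectral density, sum it over the δ [0,4), α
[8,16) and γ [32,64) Hz bands, and take each band's share of the three
bands' total.

**Coupled model.**  Two such regions — occipital and parietal — exchange
signals through their pyramidal populations.  A region's output is passed
through the sigmoid, de-meaned against its running mean, scaled by a
coupling gain (o_p: occipital→parietal, p_o: parietal→occipital), shaped
by a cross-regional encoder (a weighted excitatory kernel bank), and added
to the other region's input.

**Fitting.**  Free parameters θ = (o_p, p_o, μ_occ, σ²_occ, μ_par, σ²_par)
are fitted to a target spectrum Y(f) by particle swarm optimisation of
MSE(θ) = (1/n)·Σᵢ (Y(fᵢ) − S(fᵢ; θ))², with 50 particles, 70 iterations,
inertia 0.5 and cognitive/social factors 1.5; noise means search
[22, 2200] and variances [2, 20000].

## Worked example

```python
from ssvepsim import NoiseSpec, SimulationConfig, compute_psd, simulate_traditional

ts = simulate_traditional(NoiseSpec(mu=220.0, sigma2=100.0), SimulationConfig(seed=0))
print(len(ts), ts.fs, round(compute_psd(ts).peak_frequency(), 2))
```

prints

```
3072 1024.0 10.0
```

— 3 s of signal (4 s simulated at dt = 4/4096 s minus 1 s burn-in) whose
periodogram peaks at 10 Hz: the alpha rhythm the single region generates
under moderate drive.  The `examples/` directory walks through every
capability the same way; `examples/03_coupled_regions.py` for instance
prints the coupling sweeps:

```
Unidirectional (o_p = 0), both regions alpha-dominant:
  p_o =      0: occipital RMS 3.053 mV, peak 10.00 Hz
  p_o =    100: occipital RMS 3.200 mV, peak 9.67 Hz
  p_o =    200: occipital RMS 3.286 mV, peak 9.67 Hz

Bidirectional (o_p = p_o), parietal weighted (0.40, 0.30, 0.30):
  gain =      0: occipital centroid 10.00 Hz
  gain =    600: occipital centroid 9.62 Hz
  gain =   1200: occipital centroid 9.04 Hz
```

— one-way coupling amplifies the occipital signal at a stable dominant
frequency (the peak moves at most one 1/3 Hz frequency bin), while two-way
coupling to a delta-heavy parietal region pulls the occipital spectrum
toward lower frequencies.

A thin CLI mirrors the library (`ssvepsim simulate | simulate-coupled |
surrogate | psd | identify-weights | fit | metrics | augment | demo |
sweep`); every run writes a manifest with seeds and parameter hashes for
bit-exact reproduction.

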