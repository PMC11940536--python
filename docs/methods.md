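# Methods

This note records the model equations as implemented, the defaults and why
they were chosen, the numerical scheme, and what the synthetic data used in
testing does and does not establish.

## Single-region dynamics

Each region contains pyramidal cells (subpopulation 0), excitatory
interneurons (1) and inhibitory interneurons (2).  Two primitives define
the dynamics:

* **Potential→rate sigmoid** `S(v) = 2·e0/(1 + exp(r·(v0 − v)))` with
  e0 = 2.5 s⁻¹, v0 = 6 mV, r = 0.56 mV⁻¹.  (One published form of this
  sigmoid omits r from the exponent; the standard parameterisation with r
  is used, since without it r would be a dead parameter.)
* **Rate→potential synaptic kernel** `h(t) = G·ω·t·e^(−ωt)` (t ≥ 0),
  equivalently the second-order ODE `ÿ = G·ω·x − 2ω·ẏ − ω²·y` driven by
  the presynaptic rate x.  Peak G/e at t = 1/ω; area G/ω.

The wiring is the classic three-population loop: the pyramidal branch is
driven by S(y1 − y2), the excitatory-interneuron branch by
n(t) + C2·S(C1·y0), the inhibitory branch by C4·S(C3·y0), with
connectivity C1 = 135, C2 = 0.8·C1, C3 = C4 = 0.25·C1.  These constants
are the standard physiologically grounded values for this model family;
they are held fixed throughout (only noise and coupling parameters are
ever fitted).  External drive n(t) is Gaussian, N(μ, σ²), drawn
independently per integration step, injected only into the
excitatory-interneuron branch (configurable).  Output: E(t) = y1 − y2.

## Numerical scheme

Fixed-step explicit Euler at dt = 4/4096 s ≈ 0.977 ms, which doubles as
the output sampling step (fs = 1024 Hz).  The noise draw is per step with
no 1/√dt rescaling — the model is treated as a noise-driven map at the
stated sampling rate rather than a continuous-time SDE, so σ² is
meaningful only at this dt.  Defaults: 4 s simulated, first 1 s discarded
as burn-in before any spectral analysis.  Divergence (non-finite state) is
detected per step and reported with the region name and step index.
Higher-order integrators are deliberately out of scope.

The Euler-integrated kernel converges to the closed form at first order:
halving dt halves the maximum deviation from h(t) (asserted in the tests
at dt = 2·10⁻⁴ and 10⁻⁴ s).

## Multi-dynamic regions

Every subpopulation runs three parallel kernels — δ, α, γ — all seeing the
same presynaptic drive; branch outputs are merged by convex weights
(w_δ, w_α, w_γ).  The merged potentials close the loop (the sigmoid inputs
use the weighted sums), and the per-step noise realisation is shared
across the three branches of a subpopulation.  With one-hot α weights and
the standard kernels this reduces *exactly* (same floating-point
operations) to the traditional model.

**Branch kernel constants** (nowhere fixed by prior work; a documented
convention of this package): the α branch uses the classic kernels
(Ge = 3.25 mV at ωe = 100 s⁻¹; Gi = 22 mV at ωi = 50 s⁻¹); the δ branch
divides both inverse time constants by 5 (ωe = 20, ωi = 10) and the γ
branch multiplies them by 4 (ωe = 400, ωi = 200), with **gains
unchanged**.  Keeping G fixed (rather than the G·τ product) gives the
slow branch a proportionally larger per-spike charge transfer (G/ω), so
up-weighting the δ branch genuinely shifts the region's output toward low
frequencies: a (0.40, 0.30, 0.30)-weighted region is δ-dominant (spectral
peak ≈ 1.7 Hz), a (0.10, 0.90, 0.00) region is α-dominant.  The
alternative G·τ-preserving convention was evaluated and rejected: under it
a (0.40, 0.30, 0.30) region peaks near 22 Hz, and coupling it to an
α-dominant region cannot shift the latter's spectrum downward at any
tested gain — contradicting the qualitative behaviour the coupled model
exists to exhibit.  All six kernels are user-configurable.

## Coupled occipital–parietal model

Per step and per region, the coupling signal is

    c = gain · ( S(y_out) − mean_so_far(S(y_out)) )

i.e. the source's output potential is converted to a mean spike density by
the sigmoid and then de-meaned with a *causal running mean* (an acausal
two-pass mode de-means against the whole-run mean for post-hoc
replication; the causal mean is the default because it keeps simulation
streaming).  De-meaning after the sigmoid makes the injected drive
zero-mean: coupling transmits the source's oscillation without shifting
the target's operating point.  (Applying the sigmoid after de-meaning was
evaluated and rejected: the resulting DC offset slightly damps the target
alpha at small gains, inverting the expected amplitude trend.)

The coupling signal then drives the **cross-regional encoder** — a
weighted parallel bank of excitatory kernels, by default the source
region's own bank and weights, configurable independently — and the
encoder output is added to the target region's external input at the same
summing junction as its noise.  No conduction delay by default; an
integer-step delay is available.  Each region draws noise from an
independent child stream of the master seed, so zero-gain coupling
factorises bit-exactly into two independent single-region runs, and
swapping region labels together with their streams and gains swaps the
outputs bit-exactly.

Characteristic behaviour (asserted over seed averages in the tests):

* Unidirectional p_o ∈ {0, 100, 200} with both regions α-dominant:
  occipital RMS grows monotonically; dominant frequency stays within one
  frequency bin.
* Bidirectional o_p = p_o ∈ {0, 400, 800, 1200} with a δ-heavy parietal
  (0.40, 0.30, 0.30): the occipital spectral centroid (≤ 64 Hz) falls
  monotonically.  The sweep spans the gain scale recovered by the
  spectrum fits; below ≈ 300 the occipital's own alpha limit cycle swamps
  the injected delta and the centroid is flat.

## Spectral analysis and weight identification

PSD = one-sided rectangular-window periodogram of the de-meaned signal
(Welch averaging available as an option for smoother sweep figures);
Parseval holds to 10⁻⁶ relative.  Bands are half-open and contiguous —
δ [0,4), θ [4,8), α [8,16), β [16,32), γ [32,64) Hz — which resolves the
overlapping printed boundaries (4, 16, 32 Hz) uniquely.  Band energy is
the plain sum of PSD bins in the interval; the oscillator weights are the
δ/α/γ energies normalised by their three-band total (θ and β measured but
excluded by design), then renormalised so the sum is exactly 1.  Because
the weights are ratios, the PSD normalisation convention cancels.

The demo classifier picks the candidate stimulus frequency nearest the
global PSD argmax, rejecting if farther than a tolerance (default 0.5 Hz).

## PSO fitting

Classic inertia-weight PSO: 50 particles, 70 iterations, k = 0.5,
c1 = c2 = 1.5 (c1 + c2 ∈ (0, 4)), fresh uniform r1, r2 per particle and
dimension, velocities initialised to zero, positions clipped to bounds
with the offending velocity component zeroed, non-finite objective values
treated as +∞.  Default six dimensions (o_p, p_o, μ_occ, σ²_occ, μ_par,
σ²_par); bounds μ ∈ [22, 2200], σ² ∈ [2, 20000]; coupling-gain bounds are
not fixed by prior work and default to [0, 2000], covering the gain scale
the fits recover.

The objective simulates the coupled model at θ with **one fixed simulation
seed shared by all evaluations of a fit**, making it deterministic (a
stochastic objective would make personal-best bookkeeping ill-defined);
seed-averaged evaluation is available via the API by fitting against an
averaged target.  Self-consistency testing generates the target from the
model at known θ* with that same seed, so zero MSE is attainable; the
tests assert a ≥ 50 % median MSE reduction from the initial swarm best
(exact θ recovery is not identifiable from a single spectrum and is not
claimed).  Problem sizes in the self-consistency tests are scaled for a
desk run: 12 particles × 8 iterations on 1.5 s simulations (0.5 s
burn-in), 10 swarm seeds; observed median reduction ≈ 99 %.

## Consistency metrics

MAE = mean|a−b|, RMSE = √(mean (a−b)²), ME = max|a−b| over pointwise
differences of equal-length, equal-rate signals.  ME is interpreted as the
maximum absolute pointwise error, consistent with MAE ≤ RMSE ≤ ME.

## Augmentation

Five operators; each application draws one uniformly (a compose-all mode
applies all five in sequence).  Parameter ranges are not fixed by prior
work; the defaults are conservative, label-preserving perturbations:
circular shift up to fs/10 samples, smooth multiplicative envelope in
[0.8, 1.2] (monotone-piecewise-cubic through 5 random control points),
one contiguous zeroed window of fs/20–fs/5 samples, global gain in
[0.7, 1.3], additive Gaussian noise at 5 % of signal RMS.  Every operator
preserves length; a dataset of N inputs with k operations per input yields
exactly N·k outputs with labels and provenance recorded in a manifest.

## Surrogate signals

Because no recorded SSVEP data ship with the package, stimulus-locked
surrogates stand in: harmonic sinusoids at f0, 2f0, 3f0 (default
amplitudes 1.0/0.5/0.25 mV, random phases) over 1/f^β noise synthesised by
spectral shaping of white noise and rescaled to an exact target variance
(default 0.3 mV², β = 1 — a plausible signal-to-background ratio for a
clear SSVEP response).  The surrogate reproduces the *band-energy
structure* of stimulus-locked EEG and nothing else: no inter-subject
variability, no non-stationarity, no artefacts (blinks, movement), no
channel structure.  Tests passing on surrogates therefore establish the
pipeline's correctness (weight identification, classification, fitting
machinery), not performance on recorded EEG.

## Known limitations

* σ² is tied to dt = 4/4096 s; changing dt changes the effective noise
  level (no continuous-time calibration is attempted).
* The δ/γ branch constants and the coupling/augmentation ranges are
  package conventions, chosen once and documented above; other choices
  would change quantitative (not qualitative) behaviour.
* Exactly two regions; the 6-dimensional fit vector follows the
  parameters named for optimisation (an 18-dimensional variant including
  both regions' weight simplices is not provided).
* The dominant-frequency classifier is deliberately minimal plumbing for
  the demo loop; it is not a competitive SSVEP decoder, and no neural
  classifier is included.
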