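"""Simulate the traditional single-region model and find its alpha peak.

A cortical region driven by Gaussian input with mean around 200-220 and
modest variance settles into an ~10 Hz alpha oscillation; the dominant
periodogram frequency is the model's most basic fingerprint.
"""

from ssvepsim import NoiseSpec, SimulationConfig, compute_psd, simulate_traditional

for mu in (200.0, 220.0):
    ts = simulate_traditional(NoiseSpec(mu=mu, sigma2=100.0), SimulationConfig(seed=0))
    spectrum = compute_psd(ts)
    print(
        f"mu = {mu:6.1f}: {len(ts)} samples at {ts.fs:.0f} Hz, "
        f"dominant frequency {spectrum.peak_frequency():.2f} Hz"
    )

print("\nBoth drives put the spectral peak at ~10 Hz: the alpha rhythm the")
print("model generates is robust to the exact input level.")
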