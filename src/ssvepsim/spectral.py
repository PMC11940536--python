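"""Power spectra, EEG band energies and oscillator-weight identification.

The frequency content of a simulated or recorded signal is summarised by a
one-sided periodogram.  Five canonical EEG sub-bands partition [0, 64) Hz;
the relative energies of the delta, alpha and gamma bands (normalised to
their joint total) define the oscillator weights of the multi-dynamic
model, which by construction lie in [0, 1] and sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram, welch

from .core import TimeSeries
from .region import OscillatorWeights

__all__ = [
    "Spectrum",
    "Band",
    "BandTable",
    "compute_psd",
    "band_energies",
    "identify_weights",
    "dominant_frequency",
    "spectral_centroid",
]


@dataclass
class Spectrum:
    """A frequency grid (Hz, strictly increasing) and nonnegative PSD values."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if len(self.freqs) and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD values must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def peak_frequency(self) -> float:
        """Frequency of the global PSD maximum."""
        return float(self.freqs[int(np.argmax(self.power))])


@dataclass(frozen=True)
class Band:
    label: str
    lo: float
    hi: float  # half-open interval [lo, hi)


@dataclass(frozen=True)
class BandTable:
    """The five EEG sub-bands, contiguous half-open intervals on [0, 64) Hz."""

    bands: tuple[Band, ...] = (
        Band("delta", 0.0, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha", 8.0, 16.0),
        Band("beta", 16.0, 32.0),
        Band("gamma", 32.0, 64.0),
    )

    def __post_init__(self) -> None:
        for a, b in zip(self.bands, self.bands[1:]):
            if a.hi != b.lo:
                raise ValueError("bands must be contiguous and non-overlapping")

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, label: str) -> Band:
        for band in self.bands:
            if band.label == label:
                return band
        raise KeyError(label)


DEFAULT_BANDS = BandTable()


def compute_psd(x: TimeSeries, method: str = "periodogram", nperseg: int | None = None) -> Spectrum:
    """One-sided PSD of the de-meaned signal.

    The default is a plain rectangular-window periodogram with frequency
    resolution fs/N, which satisfies Parseval's identity: the PSD bins
    summed times the bin width equal the signal variance.  ``method="welch"``
    averages over segments (smoother, coarser resolution) for sweep figures.
    """
    if len(x) < 2:
        raise ValueError("need at least 2 samples to compute a PSD")
    if method == "periodogram":
        f, p = periodogram(x.values, fs=x.fs, window="boxcar", detrend="constant")
    elif method == "welch":
        f, p = welch(x.values, fs=x.fs, nperseg=nperseg or min(len(x), 1024), detrend="constant")
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return Spectrum(freqs=f, power=p)


def band_energies(s: Spectrum, bands: BandTable = DEFAULT_BANDS) -> dict[str, float]:
    """Energy per band: the sum of PSD bins with frequency in [lo, hi)."""
    if s.freqs[-1] < bands.bands[-1].hi - s.df:
        raise ValueError(
            f"spectrum reaches only {s.freqs[-1]:.1f} Hz; bands require "
            f"coverage up to {bands.bands[-1].hi:.1f} Hz"
        )
    out: dict[str, float] = {}
    for band in bands:
        mask = (s.freqs >= band.lo) & (s.freqs < band.hi)
        out[band.label] = float(np.sum(s.power[mask]))
    return out


def identify_weights(s: Spectrum, bands: BandTable = DEFAULT_BANDS) -> OscillatorWeights:
    """Oscillator weights from the delta/alpha/gamma band-energy ratios.

    w_i = E_i / (E_delta + E_alpha + E_gamma) for i in {delta, alpha, gamma};
    theta and beta energies are computed but deliberately excluded.  The
    result is renormalised so the three weights sum to exactly 1.
    """
    e = band_energies(s, bands)
    total = e["delta"] + e["alpha"] + e["gamma"]
    if total <= 0:
        raise ValueError("zero total energy in the delta/alpha/gamma bands")
    w = np.array([e["delta"], e["alpha"], e["gamma"]]) / total
    w = w / w.sum()  # exact renormalisation against rounding
    return OscillatorWeights(w_delta=float(w[0]), w_alpha=float(w[1]), w_gamma=float(w[2]))


def dominant_frequency(
    s: Spectrum, candidates: list[float], tol: float = 0.5
) -> float | None:
    """Nearest candidate stimulus frequency to the PSD argmax, or None.

    Returns the candidate closest to the global peak if it lies within
    ``tol`` Hz; otherwise None (no confident detection).
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    f_peak = s.peak_frequency()
    best = min(candidates, key=lambda c: abs(c - f_peak))
    return best if abs(best - f_peak) <= tol else None


def spectral_centroid(s: Spectrum, fmax: float | None = None) -> float:
    """Power-weighted mean frequency, optionally restricted to f <= fmax."""
    f, p = s.freqs, s.power
    if fmax is not None:
        keep = f <= fmax
        f, p = f[keep], p[keep]
    total = float(np.sum(p))
    if total <= 0:
        raise ValueError("cannot compute the centroid of an all-zero spectrum")
    return float(np.sum(f * p) / total)
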