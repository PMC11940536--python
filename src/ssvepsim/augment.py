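"""Stochastic signal augmentation for expanding small SSVEP datasets.

Five label-preserving operators: circular signal shifting, smooth amplitude
distortion, temporal masking (zeroing a contiguous window), global scale
transformation, and additive Gaussian noise.  Each augmentation application
picks one operator uniformly at random (a compose-all mode applies all five
in sequence); applying ``ops_per_sample`` augmentations to every input
expands a dataset by that factor while every output keeps its input's
length and label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import TimeSeries

__all__ = ["AugmentConfig", "OPERATORS", "augment_once", "augment_dataset"]

OPERATORS = ("shift", "amplitude", "mask", "scale", "noise")


@dataclass(frozen=True)
class AugmentConfig:
    """Operator parameter ranges; ``None`` fields derive from the signal.

    * ``max_shift``: largest circular shift in samples (default fs/10).
    * ``amp_distortion_range``: bounds of the smooth multiplicative
      envelope (default (0.8, 1.2)).
    * ``mask_len_range``: contiguous zeroed-window length in samples
      (default (fs/20, fs/5)).
    * ``scale_range``: global gain bounds (default (0.7, 1.3)).
    * ``noise_sigma``: additive Gaussian std in mV (default 5% of the
      signal's RMS).
    * ``ops_per_sample``: augmentations per input signal (default 100).
    """

    max_shift: int | None = None
    amp_distortion_range: tuple[float, float] = (0.8, 1.2)
    mask_len_range: tuple[int, int] | None = None
    scale_range: tuple[float, float] = (0.7, 1.3)
    noise_sigma: float | None = None
    ops_per_sample: int = 100
    seed: int = 0
    compose_all: bool = False

    def __post_init__(self) -> None:
        for name in ("amp_distortion_range", "scale_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.mask_len_range is not None and not (
            0 < self.mask_len_range[0] <= self.mask_len_range[1]
        ):
            raise ValueError("mask_len_range must be ordered and positive")
        if self.ops_per_sample < 1:
            raise ValueError("ops_per_sample must be at least 1")


def _resolved(cfg: AugmentConfig, x: TimeSeries) -> AugmentConfig:
    from dataclasses import replace

    max_shift = cfg.max_shift if cfg.max_shift is not None else max(1, round(x.fs / 10))
    mask_range = (
        cfg.mask_len_range
        if cfg.mask_len_range is not None
        else (max(1, round(x.fs / 20)), max(1, round(x.fs / 5)))
    )
    noise_sigma = (
        cfg.noise_sigma
        if cfg.noise_sigma is not None
        else 0.05 * float(np.sqrt(np.mean(x.values**2)))
    )
    return replace(cfg, max_shift=max_shift, mask_len_range=mask_range, noise_sigma=noise_sigma)


def _apply_shift(v: np.ndarray, cfg: AugmentConfig, rng) -> np.ndarray:
    u = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
    return np.roll(v, u)


def _apply_amplitude(v: np.ndarray, cfg: AugmentConfig, rng) -> np.ndarray:
    # smooth monotone-piecewise envelope through a few random control points
    lo, hi = cfg.amp_distortion_range
    n_ctrl = 5
    ctrl_x = np.linspace(0, len(v) - 1, n_ctrl)
    ctrl_y = rng.uniform(lo, hi, n_ctrl)
    envelope = PchipInterpolator(ctrl_x, ctrl_y)(np.arange(len(v)))
    return v * envelope


def _apply_mask(v: np.ndarray, cfg: AugmentConfig, rng) -> np.ndarray:
    lo, hi = cfg.mask_len_range
    if lo > len(v):
        raise ValueError(f"mask length {lo} exceeds signal length {len(v)}")
    length = int(rng.integers(lo, min(hi, len(v)) + 1))
    start = int(rng.integers(0, len(v) - length + 1))
    out = v.copy()
    out[start : start + length] = 0.0
    return out


def _apply_scale(v: np.ndarray, cfg: AugmentConfig, rng) -> np.ndarray:
    return v * float(rng.uniform(*cfg.scale_range))


def _apply_noise(v: np.ndarray, cfg: AugmentConfig, rng) -> np.ndarray:
    return v + rng.normal(0.0, cfg.noise_sigma, len(v))


_APPLY = {
    "shift": _apply_shift,
    "amplitude": _apply_amplitude,
    "mask": _apply_mask,
    "scale": _apply_scale,
    "noise": _apply_noise,
}


def augment_once(
    x: TimeSeries, cfg: AugmentConfig, rng: np.random.Generator, operator: str | None = None
) -> tuple[TimeSeries, str]:
    """Apply one augmentation; returns (augmented signal, operator name).

    ``operator`` forces a specific operator; otherwise one is drawn
    uniformly (or all five composed in sequence if ``cfg.compose_all``).
    Output length always equals input length.
    """
    if len(x) == 0:
        raise ValueError("cannot augment an empty signal")
    cfg = _resolved(cfg, x)
    if operator is not None:
        ops = [operator]
    elif cfg.compose_all:
        ops = list(OPERATORS)
    else:
        ops = [OPERATORS[int(rng.integers(len(OPERATORS)))]]
    v = x.values
    for op in ops:
        if op not in _APPLY:
            raise ValueError(f"unknown operator {op!r}")
        v = _APPLY[op](v, cfg, rng)
    return TimeSeries(fs=x.fs, values=v), "+".join(ops)


def augment_dataset(
    samples: list[TimeSeries],
    cfg: AugmentConfig,
    labels: list | None = None,
):
    """Expand a dataset by ``cfg.ops_per_sample`` augmentations per sample.

    Returns ``(augmented, aug_labels, manifest)`` where ``manifest`` maps
    each output to its source index and the operator applied, and
    ``aug_labels`` repeats each input label (None if no labels given).
    The output order and content are fully determined by ``cfg.seed``.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    if labels is not None and len(labels) != len(samples):
        raise ValueError("labels must match samples in length")
    rng = np.random.default_rng(cfg.seed)
    augmented: list[TimeSeries] = []
    aug_labels: list | None = [] if labels is not None else None
    manifest: list[dict] = []
    for idx, x in enumerate(samples):
        for _ in range(cfg.ops_per_sample):
            out, op = augment_once(x, cfg, rng)
            augmented.append(out)
            manifest.append({"source": idx, "operator": op})
            if aug_labels is not None:
                aug_labels.append(labels[idx])
    return augmented, aug_labels, manifest
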