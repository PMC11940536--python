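"""Time-domain consistency metrics between two equally sampled signals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries

__all__ = ["ErrorMetrics", "compare_signals"]


@dataclass(frozen=True)
class ErrorMetrics:
    """MAE, RMSE and ME (maximum absolute pointwise error), all in mV.

    For any pair of signals mae <= rmse <= me: the RMS dominates the mean
    of |a−b| (Cauchy–Schwarz) and is itself dominated by the maximum.
    """

    mae: float
    rmse: float
    me: float

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "rmse": self.rmse, "me": self.me}


def compare_signals(a: TimeSeries, b: TimeSeries) -> ErrorMetrics:
    """Pointwise agreement between two signals of equal length and rate."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if a.fs != b.fs:
        raise ValueError(f"sampling-rate mismatch: {a.fs} vs {b.fs}")
    if len(a) == 0:
        raise ValueError("cannot compare empty signals")
    d = np.abs(a.values - b.values)
    return ErrorMetrics(
        mae=float(np.mean(d)),
        rmse=float(np.sqrt(np.mean(d * d))),
        me=float(np.max(d)),
    )
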