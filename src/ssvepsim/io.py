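"""Plain-text I/O: delimited signals and spectra, YAML configs, manifests.

Signals travel as headered two-column text (time_s, amplitude_mV), coupled
outputs as three columns (time_s, occipital_mV, parietal_mV), spectra as
(freq_Hz, psd).  A JSON sidecar records the sampling rate, seed and a hash
of the generating parameters so any output can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .core import (
    ConnectivityConstants,
    NoiseSpec,
    SigmoidParams,
    SimulationConfig,
    SynapticKernel,
    TimeSeries,
)
from .coupled import CoupledModelSpec, CoupledOutput, CouplingParams
from .region import KernelBank, OscillatorWeights, RegionParams
from .spectral import Spectrum

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_coupled",
    "read_coupled",
    "write_spectrum",
    "read_spectrum",
    "params_hash",
    "spec_to_dict",
    "spec_from_dict",
    "region_to_dict",
    "region_from_dict",
    "load_config",
    "save_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def params_hash(obj) -> str:
    """Stable short hash of a (nested) dataclass/dict parameter structure."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_timeseries(path, ts: TimeSeries, seed: int | None = None, params=None) -> None:
    path = Path(path)
    data = np.column_stack([ts.times, ts.values])
    np.savetxt(path, data, header="time_s\tamplitude_mV", delimiter="\t", comments="")
    meta = {"fs": ts.fs, "n": len(ts), "seed": seed}
    if params is not None:
        meta["params_hash"] = params_hash(params)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_timeseries(path) -> TimeSeries:
    path = Path(path)
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path} is not a 2-column time-series file")
    t, v = data[:, 0], data[:, 1]
    sidecar = _sidecar(path)
    if sidecar.exists():
        fs = float(json.loads(sidecar.read_text())["fs"])
    else:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path} is not uniformly sampled")
        fs = 1.0 / float(dt[0])
    return TimeSeries(fs=fs, values=v)


def write_coupled(path, out: CoupledOutput, seed: int | None = None, params=None) -> None:
    path = Path(path)
    data = np.column_stack([out.occipital.times, out.occipital.values, out.parietal.values])
    np.savetxt(
        path, data, header="time_s\toccipital_mV\tparietal_mV", delimiter="\t", comments=""
    )
    meta = {"fs": out.occipital.fs, "n": len(out.occipital), "seed": seed}
    if params is not None:
        meta["params_hash"] = params_hash(params)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_coupled(path) -> CoupledOutput:
    path = Path(path)
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError(f"{path} is not a 3-column coupled-output file")
    t = data[:, 0]
    dt = np.diff(t)
    fs = 1.0 / float(dt[0])
    return CoupledOutput(
        occipital=TimeSeries(fs=fs, values=data[:, 1]),
        parietal=TimeSeries(fs=fs, values=data[:, 2]),
    )


def write_spectrum(path, s: Spectrum) -> None:
    np.savetxt(
        Path(path),
        np.column_stack([s.freqs, s.power]),
        header="freq_Hz\tpsd",
        delimiter="\t",
        comments="",
    )


def read_spectrum(path) -> Spectrum:
    data = np.loadtxt(Path(path), skiprows=1, delimiter="\t")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path} is not a 2-column spectrum file")
    return Spectrum(freqs=data[:, 0], power=data[:, 1])


# -- configuration (de)serialisation ----------------------------------------


def _kernel_to_dict(k: SynapticKernel) -> dict:
    return {"G": k.G, "omega": k.omega, "polarity": k.polarity}


def _kernel_from_dict(d: dict) -> SynapticKernel:
    return SynapticKernel(G=d["G"], omega=d["omega"], polarity=d.get("polarity", "excitatory"))


def region_to_dict(p: RegionParams) -> dict:
    return {
        "sigmoid": dataclasses.asdict(p.sigmoid),
        "bank": {
            "exc": [_kernel_to_dict(k) for k in p.bank.exc],
            "inh": [_kernel_to_dict(k) for k in p.bank.inh],
        },
        "weights": dataclasses.asdict(p.weights),
        "connectivity": dataclasses.asdict(p.connectivity),
        "noise": dataclasses.asdict(p.noise),
    }


def region_from_dict(d: dict) -> RegionParams:
    kwargs = {}
    if "sigmoid" in d:
        kwargs["sigmoid"] = SigmoidParams(**d["sigmoid"])
    if "bank" in d:
        kwargs["bank"] = KernelBank(
            exc=tuple(_kernel_from_dict(k) for k in d["bank"]["exc"]),
            inh=tuple(_kernel_from_dict(k) for k in d["bank"]["inh"]),
        )
    if "weights" in d:
        kwargs["weights"] = OscillatorWeights(**d["weights"])
    if "connectivity" in d:
        kwargs["connectivity"] = ConnectivityConstants(**d["connectivity"])
    if "noise" in d:
        kwargs["noise"] = NoiseSpec(**d["noise"])
    return RegionParams(**kwargs)


def spec_to_dict(spec: CoupledModelSpec) -> dict:
    coupling = {
        "o_p": spec.coupling.o_p,
        "p_o": spec.coupling.p_o,
        "delay_steps": spec.coupling.delay_steps,
    }
    if spec.coupling.encoder_bank is not None:
        coupling["encoder_bank"] = {
            "exc": [_kernel_to_dict(k) for k in spec.coupling.encoder_bank.exc],
            "inh": [_kernel_to_dict(k) for k in spec.coupling.encoder_bank.inh],
        }
    if spec.coupling.encoder_weights is not None:
        coupling["encoder_weights"] = dataclasses.asdict(spec.coupling.encoder_weights)
    return {
        "occipital": region_to_dict(spec.occipital),
        "parietal": region_to_dict(spec.parietal),
        "coupling": coupling,
        "cfg": dataclasses.asdict(spec.cfg),
    }


def spec_from_dict(d: dict) -> CoupledModelSpec:
    kwargs = {}
    if "occipital" in d:
        kwargs["occipital"] = region_from_dict(d["occipital"])
    if "parietal" in d:
        kwargs["parietal"] = region_from_dict(d["parietal"])
    if "coupling" in d:
        c = dict(d["coupling"])
        if "encoder_bank" in c:
            c["encoder_bank"] = KernelBank(
                exc=tuple(_kernel_from_dict(k) for k in c["encoder_bank"]["exc"]),
                inh=tuple(_kernel_from_dict(k) for k in c["encoder_bank"]["inh"]),
            )
        if "encoder_weights" in c:
            c["encoder_weights"] = OscillatorWeights(**c["encoder_weights"])
        kwargs["coupling"] = CouplingParams(**c)
    if "cfg" in d:
        kwargs["cfg"] = SimulationConfig(**d["cfg"])
    return CoupledModelSpec(**kwargs)


def load_config(path) -> CoupledModelSpec:
    """Read a coupled-model specification from a YAML (or JSON) file."""
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_config(path, spec: CoupledModelSpec) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
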