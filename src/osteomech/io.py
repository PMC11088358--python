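"""Delimited-text I/O for signals, records and cohort manifests.

Signal files are CSV with columns ``time_s``, ``strain`` and (optionally)
``stress_MPa``; stress is stored in MPa on disk and converted to Pa in
memory.  Parameter files are JSON with unit-suffixed keys (see
:meth:`osteomech.rheology.RheoParams.to_json`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocol import ProtocolSpec
from .rheology import StrainSignal, StressSignal

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_protocol_yaml",
    "write_protocol_yaml",
    "write_cohort",
]


def read_signal_csv(path):
    """Read a signal CSV; returns ``(StrainSignal, StressSignal | None)``."""
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"time_s", "strain"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time_s, strain")
    signal = StrainSignal(df["time_s"].to_numpy(float), df["strain"].to_numpy(float))
    stress = None
    if "stress_MPa" in df.columns:
        stress = StressSignal(df["stress_MPa"].to_numpy(float) * 1e6)
    return signal, stress


def write_signal_csv(path, signal: StrainSignal, stress: StressSignal | None = None):
    data = {"time_s": signal.t, "strain": signal.eps}
    if stress is not None:
        data["stress_MPa"] = stress.sigma / 1e6
    pd.DataFrame(data).to_csv(path, index=False)


def read_protocol_yaml(path) -> ProtocolSpec:
    raw = yaml.safe_load(Path(path).read_text())
    raw["peak_strains"] = tuple(raw["peak_strains"])
    return ProtocolSpec(**raw)


def write_protocol_yaml(path, spec: ProtocolSpec) -> None:
    data = {
        "peak_strains": [float(p) for p in spec.peak_strains],
        "strain_rate": spec.strain_rate,
        "hold_s": spec.hold_s,
        "unload_target": spec.unload_target,
        "hold_after_unload": spec.hold_after_unload,
        "sample_hz": spec.sample_hz,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_cohort(directory, records, manifest: pd.DataFrame) -> Path:
    """Write a cohort manifest plus one signal CSV per specimen."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(directory / "manifest.csv", index=False)
    for rec in records:
        write_signal_csv(directory / f"{rec.specimen_id}.csv", rec.signal, rec.stress)
    return directory
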