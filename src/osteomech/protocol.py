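"""Displacement-controlled cyclic load–hold–unload strain protocols.

Tensile tests are emulated as a sequence of cycles with increasing peak
strain: ramp to the cycle peak at a fixed strain rate, hold for ``hold_s``
seconds (stress relaxation), unload at the same rate, and proceed to the
next, larger peak.  The final cycle ramps to the last peak and holds there;
simulated specimens usually fracture during one of the later ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rheology import StrainSignal

__all__ = ["ProtocolSpec", "build_protocol", "cortical_protocol", "trabecular_protocol"]


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of the cyclic load–hold–unload protocol.

    ``peak_strains`` must be strictly increasing.  ``unload_target`` is the
    strain each unloading ramp aims for when the protocol is built open-loop;
    the synthetic-specimen generator instead stops unloading at the
    zero-stress crossing (see :mod:`osteomech.cohort`).
    """

    peak_strains: tuple
    strain_rate: float = 0.002      # 1/s
    hold_s: float = 10.0            # hold after each loading ramp, s
    unload_target: float = 0.0      # strain
    hold_after_unload: bool = False
    sample_hz: float = 10.0

    def __post_init__(self) -> None:
        peaks = tuple(float(p) for p in self.peak_strains)
        if len(peaks) < 1 or np.any(np.diff(peaks) <= 0.0):
            raise ValueError("peak_strains must be non-empty and strictly increasing")
        if self.strain_rate <= 0.0 or self.sample_hz <= 0.0 or self.hold_s < 0.0:
            raise ValueError("strain_rate and sample_hz must be > 0, hold_s >= 0")
        object.__setattr__(self, "peak_strains", peaks)

    @property
    def n_cycles(self) -> int:
        return len(self.peak_strains)

    @classmethod
    def linear(cls, n_cycles: int, eps_last: float, first_frac: float = 0.2, **kwargs):
        """Linearly spaced peak schedule from ``first_frac*eps_last`` to ``eps_last``."""
        peaks = tuple(np.linspace(first_frac * eps_last, eps_last, n_cycles))
        return cls(peak_strains=peaks, **kwargs)


def cortical_protocol(**kwargs) -> ProtocolSpec:
    """Default 7-cycle protocol for cortical specimens (last peak 2.6% strain)."""
    return ProtocolSpec.linear(7, 0.026, **kwargs)


def trabecular_protocol(**kwargs) -> ProtocolSpec:
    """Default 7-cycle protocol for trabecular specimens (last peak 5% strain)."""
    return ProtocolSpec.linear(7, 0.05, **kwargs)


def _segment(t0: float, e0: float, e1: float, duration: float, hz: float):
    """Time/strain samples of one linear segment, endpoint included, start excluded."""
    n = max(1, int(np.ceil(duration * hz)))
    s = np.linspace(0.0, 1.0, n + 1)[1:]
    return t0 + s * duration, e0 + s * (e1 - e0)


def build_protocol(spec: ProtocolSpec) -> StrainSignal:
    """Open-loop strain signal of the cyclic protocol.

    Each ramp runs at ``spec.strain_rate``; segment endpoints (cycle peaks,
    hold boundaries) are sampled exactly, so per-cycle strain maxima equal
    ``spec.peak_strains`` regardless of the sampling rate.
    """
    t_parts = [np.array([0.0])]
    e_parts = [np.array([0.0])]
    t_now, e_now = 0.0, 0.0

    def add(e_target: float, duration: float):
        nonlocal t_now, e_now
        if duration <= 0.0:
            return
        ts, es = _segment(t_now, e_now, e_target, duration, spec.sample_hz)
        t_parts.append(ts)
        e_parts.append(es)
        t_now, e_now = float(ts[-1]), float(es[-1])

    last = spec.n_cycles - 1
    for i, peak in enumerate(spec.peak_strains):
        add(peak, (peak - e_now) / spec.strain_rate)
        if spec.hold_s > 0.0:
            add(peak, spec.hold_s)
        if i < last:
            target = min(spec.unload_target, peak)
            add(target, (e_now - target) / spec.strain_rate)
            if spec.hold_after_unload and spec.hold_s > 0.0:
                add(target, spec.hold_s)

    return StrainSignal(np.concatenate(t_parts), np.concatenate(e_parts))
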