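"""Envelope-curve evaluation of apparent mechanical properties.

The envelope of a cyclic tensile record is the outer boundary traced in
monotone strain: samples are kept only while the strain exceeds its running
maximum.  Apparent (model-free) properties are read off this polyline:
apparent Young's modulus (regression over a low-stress window of the first
loading branch), yield point (offset-line or linearity-deviation criterion),
maximum stress, ultimate strain, and elastic / post-yield work densities.
Per-cycle loading and unloading tangent moduli are fitted branch-wise after
segmenting the record at strain-direction reversals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rheology import StrainSignal, StressSignal

__all__ = [
    "ApparentProps",
    "CycleModuli",
    "envelope_curve",
    "cycle_moduli",
    "elastic_modulus",
    "yield_point",
    "works",
    "apparent_properties",
]


@dataclass(frozen=True)
class ApparentProps:
    """Apparent properties evaluated on the envelope curve (SI units, J/m^3)."""

    E_hat: float
    eps_y_hat: float | None
    sigma_y_hat: float | None
    eps_u_hat: float
    eps_at_max: float
    sigma_max_hat: float
    W_el_hat: float | None
    W_py_hat: float | None


@dataclass(frozen=True)
class CycleModuli:
    cycle_index: int
    loading_modulus: float   # Pa; NaN if the branch was too short to fit
    unloading_modulus: float


def envelope_curve(signal: StrainSignal, stress: StressSignal):
    """Monotone-strain envelope polyline ``(eps_env, sigma_env)``.

    Keeps the first sample and every sample whose strain strictly exceeds the
    running maximum; a monotone record is returned unchanged.
    """
    eps = signal.eps
    sig = stress.sigma
    if eps.size != sig.size:
        raise ValueError("strain and stress must have equal length")
    running = np.maximum.accumulate(eps)
    keep = eps >= running
    keep &= np.r_[True, eps[1:] > running[:-1]]
    return eps[keep], sig[keep]


def _branches(eps: np.ndarray):
    """Maximal runs of constant strain direction: list of (start, stop, sign)."""
    d = np.sign(np.diff(eps))
    branches = []
    i = 0
    n = d.size
    while i < n:
        if d[i] == 0:
            i += 1
            continue
        j = i
        while j < n and d[j] == d[i]:
            j += 1
        branches.append((i, j, int(d[i])))  # samples eps[i..j] inclusive
        i = j
    return branches


def _tangent(eps, sig, lo_frac, hi_frac, min_samples=4):
    """Least-squares slope of sigma vs eps within a stress-span window."""
    span_lo, span_hi = sig.min(), sig.max()
    lo = span_lo + lo_frac * (span_hi - span_lo)
    hi = span_lo + hi_frac * (span_hi - span_lo)
    sel = (sig >= lo) & (sig <= hi)
    if sel.sum() < min_samples:
        return float("nan")
    return float(np.polyfit(eps[sel], sig[sel], 1)[0])


def cycle_moduli(
    signal: StrainSignal,
    stress: StressSignal,
    window: tuple = (0.2, 0.8),
) -> list[CycleModuli]:
    """Per-cycle loading/unloading tangent moduli.

    Branches are segmented at strain-direction reversals (holds break
    branches but open no new cycle); the tangent is a linear fit over the
    ``window`` fraction of each branch's stress span.  Branches with fewer
    than 4 samples inside the window yield NaN.
    """
    eps, sig = signal.eps, stress.sigma
    out = []
    loading = float("nan")
    k = 0
    for i, j, direction in _branches(eps):
        m = _tangent(eps[i:j + 1], sig[i:j + 1], *window)
        if direction > 0:
            if not np.isnan(loading):
                # loading branch without a matching unload (final ramp)
                k += 1
                out.append(CycleModuli(k, loading, float("nan")))
            loading = m
        else:
            k += 1
            out.append(CycleModuli(k, loading, m))
            loading = float("nan")
    if not np.isnan(loading):
        k += 1
        out.append(CycleModuli(k, loading, float("nan")))
    return out


def elastic_modulus(signal: StrainSignal, stress: StressSignal,
                    window: tuple = (0.1, 0.4)) -> float:
    """Apparent Young's modulus: regression over a 10–40% stress window of the
    first loading branch."""
    eps, sig = signal.eps, stress.sigma
    branches = _branches(eps)
    if not branches:
        raise ValueError("record has no loading branch")
    i, j, _ = branches[0]
    return _tangent(eps[i:j + 1], sig[i:j + 1], *window)


def yield_point(
    eps_env: np.ndarray,
    sig_env: np.ndarray,
    E_hat: float,
    offset: float = 2e-4,
    criterion: str = "offset",
    linear_tol_frac: float = 0.02,
):
    """Apparent yield point on the envelope.

    ``criterion='offset'``: first crossing of the envelope with the offset
    line ``sigma = E_hat * (eps - offset)``.  ``criterion='deviation'``:
    first point where the envelope falls below the linear prediction
    ``E_hat * eps`` by more than ``linear_tol_frac * max(sigma)``.  Returns
    ``(eps_y, sigma_y)`` or ``(None, None)`` when no yield is detected.
    """
    if criterion == "offset":
        resid = sig_env - E_hat * (eps_env - offset)
    elif criterion == "deviation":
        resid = sig_env - (E_hat * eps_env - linear_tol_frac * sig_env.max())
    else:
        raise ValueError(f"unknown yield criterion {criterion!r}")
    below = np.flatnonzero(resid < 0.0)
    below = below[below > 0]
    if below.size == 0:
        return None, None
    i = below[0]
    # linear interpolation of the sign change between samples i-1 and i
    w = resid[i - 1] / (resid[i - 1] - resid[i])
    eps_y = eps_env[i - 1] + w * (eps_env[i] - eps_env[i - 1])
    sig_y = sig_env[i - 1] + w * (sig_env[i] - sig_env[i - 1])
    return float(eps_y), float(sig_y)


def works(eps_env: np.ndarray, sig_env: np.ndarray, eps_y_hat: float):
    """Elastic and post-yield work densities (trapezoidal, J/m^3).

    The envelope is split exactly at ``eps_y_hat`` (with an interpolated
    sample inserted), so ``W_el + W_py`` equals the total envelope area by
    construction.
    """
    if eps_y_hat is None:
        return None, None
    sig_y = float(np.interp(eps_y_hat, eps_env, sig_env))
    pre = eps_env < eps_y_hat
    post = eps_env > eps_y_hat
    e_el = np.r_[eps_env[pre], eps_y_hat]
    s_el = np.r_[sig_env[pre], sig_y]
    e_py = np.r_[eps_y_hat, eps_env[post]]
    s_py = np.r_[sig_y, sig_env[post]]
    W_el = float(np.trapezoid(s_el, e_el))
    W_py = float(np.trapezoid(s_py, e_py)) if e_py.size > 1 else 0.0
    return W_el, W_py


def apparent_properties(
    signal: StrainSignal,
    stress: StressSignal,
    offset: float = 2e-4,
    criterion: str = "offset",
    modulus_window: tuple = (0.1, 0.4),
) -> ApparentProps:
    """Full envelope evaluation of one cyclic tensile record."""
    eps_env, sig_env = envelope_curve(signal, stress)
    E_hat = elastic_modulus(signal, stress, window=modulus_window)
    eps_y, sig_y = yield_point(eps_env, sig_env, E_hat, offset=offset, criterion=criterion)
    W_el, W_py = works(eps_env, sig_env, eps_y)
    i_max = int(np.argmax(sig_env))
    return ApparentProps(
        E_hat=E_hat,
        eps_y_hat=eps_y,
        sigma_y_hat=sig_y,
        eps_u_hat=float(eps_env[-1]),
        eps_at_max=float(eps_env[i_max]),
        sigma_max_hat=float(sig_env[i_max]),
        W_el_hat=W_el,
        W_py_hat=W_py,
    )
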