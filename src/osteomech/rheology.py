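"""Extended two-layer elasto-visco-plastic rheological model with damage.

The model is a parallel arrangement of two layers subjected to the same
engineering strain history:

* a **Prandtl layer** — linear spring ``E_pr`` in series with a frictional
  slider whose flow stress hardens exponentially from the yield stress
  ``sigma_y`` towards the ultimate stress ``sigma_u`` with rate ``p``:
  ``sigma_flow(kappa) = sigma_u + (sigma_y - sigma_u) * exp(-p * kappa)``,
  where ``kappa`` is the accumulated equivalent plastic strain; and

* a **Maxwell layer** — linear spring ``E_mx`` in series with a linear
  dashpot of viscosity ``eta``, carrying the rate-dependent overstress that
  relaxes during holds with time constant ``eta / ((1 - D) * E_mx)``.

Both spring stiffnesses degrade equally by a scalar damage variable
``D = 1 - exp(-k_D * kappa)`` driven by the equivalent plastic strain.  The
total stress is ``sigma = (1 - D) * E_pr * (eps - eps_pl) + sigma_mx``.

Units are SI throughout (Pa, s, dimensionless strain).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "RheoParams",
    "ModelState",
    "StrainSignal",
    "StressSignal",
    "DerivedModuli",
    "Trajectory",
    "flow_stress",
    "damage_at",
    "simulate_stress",
    "derived_moduli",
    "fracture_kappa",
]


@dataclass(frozen=True)
class RheoParams:
    """Constitutive parameter vector of the two-layer model (SI units)."""

    E_pr: float      # Prandtl spring modulus, Pa
    E_mx: float      # Maxwell spring modulus, Pa
    sigma_y: float   # yield stress, Pa
    sigma_u: float   # ultimate (saturation) stress, Pa
    p: float         # exponential hardening rate, dimensionless
    eta: float       # dashpot viscosity, Pa*s
    k_D: float       # damage rate per unit equivalent plastic strain

    _FIELDS = ("E_pr", "E_mx", "sigma_y", "sigma_u", "p", "eta", "k_D")

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.sigma_u <= self.sigma_y:
            raise ValueError(
                f"sigma_u ({self.sigma_u}) must exceed sigma_y ({self.sigma_y})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values) -> "RheoParams":
        return cls(*[float(v) for v in values])

    # JSON round trip uses the unit-suffixed key convention of the on-disk format
    _JSON_KEYS = {
        "E_pr": "E_pr_Pa",
        "E_mx": "E_mx_Pa",
        "sigma_y": "sigma_y_Pa",
        "sigma_u": "sigma_u_Pa",
        "p": "p",
        "eta": "eta_Pa_s",
        "k_D": "k_D",
    }

    def to_json(self, path) -> None:
        payload = {k: getattr(self, f) for f, k in self._JSON_KEYS.items()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "RheoParams":
        payload = json.loads(Path(path).read_text())
        return cls(**{f: float(payload[k]) for f, k in cls._JSON_KEYS.items()})


@dataclass
class ModelState:
    """Internal state: plastic strain, its accumulated magnitude, Maxwell stress, damage."""

    eps_pl: float = 0.0
    kappa: float = 0.0
    sigma_mx: float = 0.0
    D: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa < 0.0:
            raise ValueError("kappa must be non-negative")
        if not (0.0 <= self.D < 1.0):
            raise ValueError("D must lie in [0, 1)")


@dataclass(frozen=True)
class StrainSignal:
    """Engineering strain samples on a strictly increasing time grid (s)."""

    t: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        eps = np.asarray(self.eps, dtype=float)
        if t.ndim != 1 or eps.ndim != 1 or t.size != eps.size or t.size < 2:
            raise ValueError("t and eps must be 1-D arrays of equal length >= 2")
        if np.any(np.diff(t) <= 0.0):
            raise ValueError("time vector must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "eps", eps)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class StressSignal:
    """Engineering stress samples (Pa) aligned to a StrainSignal's time grid."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.ndim != 1:
            raise ValueError("sigma must be a 1-D array")
        object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return self.sigma.size


@dataclass(frozen=True)
class DerivedModuli:
    """Long-term / instantaneous moduli and loss factor at a reference frequency."""

    E_inf: float
    E_0: float
    tan_delta: float
    omega_ref: float


@dataclass
class Trajectory:
    """Per-sample internal-state history returned by :func:`simulate_stress`."""

    eps_pl: np.ndarray
    kappa: np.ndarray
    sigma_mx: np.ndarray
    D: np.ndarray


def flow_stress(params: RheoParams, kappa):
    """Flow stress of the hardening slider at equivalent plastic strain ``kappa``.

    Starts at ``sigma_y`` for virgin material and saturates towards
    ``sigma_u`` with exponential rate ``p``.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0.0):
        raise ValueError("kappa must be non-negative")
    value = params.sigma_u + (params.sigma_y - params.sigma_u) * np.exp(-params.p * kappa)
    return value if value.ndim else float(value)


def damage_at(params: RheoParams, kappa):
    """Damage ``D = 1 - exp(-k_D * kappa)``; saturating in [0, 1)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0.0):
        raise ValueError("kappa must be non-negative")
    value = 1.0 - np.exp(-params.k_D * kappa)
    return value if value.ndim else float(value)


def fracture_kappa(params: RheoParams) -> float:
    """Equivalent plastic strain at which the equilibrium envelope reaches 0.99*sigma_u.

    The model has no intrinsic rupture event; simulated specimens are
    truncated once the flow stress has saturated to 99% of the ultimate
    stress, i.e. at ``kappa* = ln((sigma_u - sigma_y) / (0.01 sigma_u)) / p``.
    If the yield stress already exceeds ``0.99 sigma_u`` the specimen is
    considered to fracture at the onset of yielding.
    """
    ratio = (params.sigma_u - params.sigma_y) / (0.01 * params.sigma_u)
    if ratio <= 1.0:
        return 1e-9
    return math.log(ratio) / params.p


@njit(cache=True)
def _integrate(t, eps, E_pr, E_mx, sig_y, sig_u, p, eta, k_D,
               eps_pl0, kappa0, sig_mx0):  # pragma: no cover - jitted
    n = t.size
    sigma = np.empty(n)
    eps_pl_tr = np.empty(n)
    kappa_tr = np.empty(n)
    sig_mx_tr = np.empty(n)
    D_tr = np.empty(n)

    eps_pl = eps_pl0
    kappa = kappa0
    sig_mx = sig_mx0
    D = 1.0 - math.exp(-k_D * kappa)

    for i in range(n):
        # --- Prandtl layer: elastic predictor + return mapping -------------
        e_tr = eps[i] - eps_pl
        a = abs(e_tr)
        sflow = sig_u + (sig_y - sig_u) * math.exp(-p * kappa)
        if E_pr * a > sflow:
            # solve E_pr*(a - dk) = sigma_flow(kappa + dk): monotone, root in (0, a)
            lo = 0.0
            hi = a
            dk = 0.5 * a
            for _ in range(80):
                ex = math.exp(-p * (kappa + dk))
                g = E_pr * (a - dk) - (sig_u + (sig_y - sig_u) * ex)
                if abs(g) < 1e-9 * sig_u:
                    break
                if g > 0.0:
                    lo = dk
                else:
                    hi = dk
                gp = -E_pr - p * (sig_u - sig_y) * ex
                step = dk - g / gp
                if step <= lo or step >= hi:
                    step = 0.5 * (lo + hi)
                dk = step
            if e_tr >= 0.0:
                eps_pl += dk
            else:
                eps_pl -= dk
            kappa += dk
            D = 1.0 - math.exp(-k_D * kappa)

        # --- Maxwell layer: exponential integrator over the step -----------
        if i > 0:
            dt = t[i] - t[i - 1]
            rate = (eps[i] - eps[i - 1]) / dt
            tau = eta / ((1.0 - D) * E_mx)
            f = math.exp(-dt / tau)
            sig_mx = eta * rate + (sig_mx - eta * rate) * f

        sigma[i] = (1.0 - D) * E_pr * (eps[i] - eps_pl) + sig_mx
        eps_pl_tr[i] = eps_pl
        kappa_tr[i] = kappa
        sig_mx_tr[i] = sig_mx
        D_tr[i] = D

    return sigma, eps_pl_tr, kappa_tr, sig_mx_tr, D_tr


def simulate_stress(
    params: RheoParams,
    signal: StrainSignal,
    initial: ModelState | None = None,
) -> tuple[StressSignal, Trajectory]:
    """Stress response of the model to an arbitrary strain history.

    The plastic slider is updated with an implicit (radial-return) solve per
    time step; the Maxwell overstress is advanced with an exact exponential
    integrator assuming piecewise-constant strain rate and damage frozen at
    its end-of-step value.  ``kappa`` and ``D`` are non-decreasing along the
    returned trajectory.
    """
    if not isinstance(signal, StrainSignal):
        signal = StrainSignal(*signal)
    state = initial or ModelState()
    if state.D >= 1.0:
        raise ValueError("initial damage must be < 1")
    sigma, eps_pl, kappa, sig_mx, D = _integrate(
        signal.t, signal.eps,
        params.E_pr, params.E_mx, params.sigma_y, params.sigma_u,
        params.p, params.eta, params.k_D,
        state.eps_pl, state.kappa, state.sigma_mx,
    )
    return StressSignal(sigma), Trajectory(eps_pl, kappa, sig_mx, D)


def derived_moduli(params: RheoParams, omega_ref: float = 2.0 * math.pi) -> DerivedModuli:
    """Long-term modulus, instantaneous modulus and loss factor.

    ``E_inf = E_pr`` (fully relaxed), ``E_0 = E_pr + E_mx`` (instantaneous).
    The loss factor is that of the standard linear solid at angular frequency
    ``omega_ref`` (default 1 Hz), with relaxation time ``tau = eta / E_mx``.
    """
    if omega_ref <= 0.0:
        raise ValueError("omega_ref must be positive")
    tau = params.eta / params.E_mx
    wt = omega_ref * tau
    tan_delta = (params.E_mx * wt) / (
        params.E_pr * (1.0 + wt * wt) + params.E_mx * wt * wt
    )
    return DerivedModuli(
        E_inf=params.E_pr,
        E_0=params.E_pr + params.E_mx,
        tan_delta=tan_delta,
        omega_ref=omega_ref,
    )
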