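"""Per-specimen identification of the rheological parameter vector.

The forward model is driven with the specimen's recorded strain history and
all seven constitutive parameters are adjusted by bounded least squares
(scipy TRF) so the simulated stress matches the recorded stress.  The
optimization works in log-parameter space with the ultimate stress
reparameterized as ``sigma_u = sigma_y + delta`` (``delta > 0``), which
enforces positivity and the yield/ultimate ordering by construction.
Multi-start: the first start comes from signal-based heuristics (tangent
modulus, hold-phase relaxation, envelope yield estimate); the remaining
starts jitter it multiplicatively with a seeded RNG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import envelope as env
from .rheology import (
    DerivedModuli,
    RheoParams,
    StrainSignal,
    StressSignal,
    derived_moduli,
    simulate_stress,
)

__all__ = ["FitConfig", "FitResult", "rmse", "fit_specimen", "fit_cohort",
           "DEFAULT_BOUNDS"]

# Per-parameter bounds of the internal vector (E_pr, E_mx, sigma_y, delta, p, eta, k_D)
DEFAULT_BOUNDS = {
    "E_pr": (0.1e9, 50e9),
    "E_mx": (0.1e9, 50e9),
    "sigma_y": (5e6, 200e6),
    "delta": (0.1e6, 295e6),
    "p": (1.0, 1000.0),
    "eta": (0.1e9, 100e9),
    "k_D": (0.1, 500.0),
}
_ORDER = ("E_pr", "E_mx", "sigma_y", "delta", "p", "eta", "k_D")


@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 5
    seed: int = 0
    jitter_sd: float = 0.35          # lognormal jitter of the multi-start initials
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-14
    max_nfev: int = 4000
    omega_ref: float = 2.0 * math.pi  # for the derived loss factor


@dataclass
class FitResult:
    params_hat: RheoParams | None
    rmse: float
    derived: DerivedModuli | None
    D_max: float
    D_end: float
    converged: bool
    n_starts_used: int
    bounds: dict
    message: str = ""


def rmse(observed: StressSignal, predicted: StressSignal) -> float:
    """Root mean squared stress error, Pa."""
    obs = np.asarray(observed.sigma if isinstance(observed, StressSignal) else observed,
                     dtype=float)
    pred = np.asarray(predicted.sigma if isinstance(predicted, StressSignal) else predicted,
                      dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted stress must have equal length")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _to_internal(params: RheoParams) -> np.ndarray:
    return np.array([
        params.E_pr, params.E_mx, params.sigma_y,
        params.sigma_u - params.sigma_y, params.p, params.eta, params.k_D,
    ])


def _from_internal(x: np.ndarray) -> RheoParams:
    E_pr, E_mx, sy, delta, p, eta, kD = x
    return RheoParams(E_pr, E_mx, sy, sy + delta, p, eta, kD)


def heuristic_initials(signal: StrainSignal, stress: StressSignal,
                       strain_rate_hint: float | None = None) -> np.ndarray:
    """Signal-based starting values for the internal parameter vector.

    * instantaneous tangent of the first loading branch -> total stiffness;
    * first hold-phase relaxation amplitude and time constant -> eta, E_mx;
    * relaxed stress at the end of the first hold -> E_pr;
    * envelope offset-yield -> sigma_y; envelope maximum -> sigma_u.
    """
    t, eps, sig = signal.t, signal.eps, stress.sigma
    d = np.diff(eps)
    rate = strain_rate_hint or float(np.median(np.abs(d[np.abs(d) > 0]) / np.diff(t)[np.abs(d) > 0]))

    try:
        s1 = env.elastic_modulus(signal, stress)
        if not np.isfinite(s1) or s1 <= 0:
            raise ValueError
    except ValueError:
        s1 = max(sig.max(), 1.0) / max(eps.max(), 1e-6)

    # first hold: longest early run of constant strain
    hold = None
    i = 0
    while i < d.size:
        if d[i] == 0.0:
            j = i
            while j < d.size and d[j] == 0.0:
                j += 1
            if j - i >= 5:
                hold = (i, j)
                break
            i = j
        else:
            i += 1

    eta0 = 0.3 * s1  # fallback: relaxation time ~0.3 s worth of stiffness
    E_mx0 = 0.35 * s1
    E_pr0 = 0.65 * s1
    if hold is not None:
        i, j = hold
        sh = sig[i:j + 1]
        th = t[i:j + 1]
        amp = sh[0] - sh[-1]
        if amp > 0:
            target = sh[-1] + amp / math.e
            below = np.flatnonzero(sh <= target)
            tau = float(th[below[0]] - th[0]) if below.size else float(th[-1] - th[0]) / 3.0
            tau = max(tau, 1e-2)
            eta0 = max(amp / rate, 1e-3 * s1)
            E_mx0 = eta0 / tau
            E_pr0 = max(s1 - E_mx0, 0.15 * s1)
        peak_eps = eps[i]
        if peak_eps > 0:
            E_pr0 = max(min(E_pr0, 1.5 * sh[-1] / peak_eps), 0.15 * s1)

    eps_env, sig_env = env.envelope_curve(signal, stress)
    sig_max = float(sig_env.max())
    _, sy0 = env.yield_point(eps_env, sig_env, s1)
    if sy0 is None or sy0 <= 0:
        sy0 = 0.5 * sig_max
    su0 = max(1.15 * sig_max, 1.3 * sy0)

    x0 = np.array([E_pr0, E_mx0, sy0, su0 - sy0, 80.0, eta0, 40.0])
    lo = np.array([DEFAULT_BOUNDS[k][0] for k in _ORDER])
    hi = np.array([DEFAULT_BOUNDS[k][1] for k in _ORDER])
    return np.clip(x0, lo * 1.01, hi * 0.99)


def fit_specimen(record, config: FitConfig | None = None) -> FitResult:
    """Identify all seven parameters of one tensile record.

    ``record`` needs ``signal`` and ``stress`` attributes (a
    :class:`~osteomech.cohort.SpecimenRecord` or any duck-typed pair).
    Returns a flagged, non-converged result rather than raising when the
    record is unusable or no start converges.
    """
    config = config or FitConfig()
    signal: StrainSignal = record.signal
    stress: StressSignal = record.stress
    bounds = {**DEFAULT_BOUNDS, **config.bounds}

    if np.max(np.abs(stress.sigma)) < 1.0:  # < 1 Pa: no signal recorded
        return FitResult(None, float("nan"), None, float("nan"), float("nan"),
                         False, 0, bounds, "degenerate stress record")

    lo = np.log(np.array([bounds[k][0] for k in _ORDER]))
    hi = np.log(np.array([bounds[k][1] for k in _ORDER]))
    obs_mpa = stress.sigma / 1e6

    def residual(u):
        params = _from_internal(np.exp(u))
        pred, _ = simulate_stress(params, signal)
        return pred.sigma / 1e6 - obs_mpa

    x0 = heuristic_initials(signal, stress)
    rng = np.random.default_rng(config.seed)
    starts = [np.clip(np.log(x0), lo, hi)]
    for _ in range(config.n_starts - 1):
        jitter = rng.normal(0.0, config.jitter_sd, size=len(_ORDER))
        starts.append(np.clip(np.log(x0) + jitter, lo, hi))

    best = None
    n_ok = 0
    for u0 in starts:
        try:
            sol = least_squares(
                residual, u0, bounds=(lo, hi), method="trf",
                xtol=config.xtol, ftol=config.ftol, gtol=config.gtol,
                max_nfev=config.max_nfev,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return FitResult(None, float("nan"), None, float("nan"), float("nan"),
                         False, 0, bounds, "no start converged")

    params_hat = _from_internal(np.exp(best.x))
    pred, traj = simulate_stress(params_hat, signal)
    fit_rmse = rmse(stress, pred)
    i_max = int(np.argmax(pred.sigma))
    return FitResult(
        params_hat=params_hat,
        rmse=fit_rmse,
        derived=derived_moduli(params_hat, config.omega_ref),
        D_max=float(traj.D[i_max]),
        D_end=float(traj.D[-1]),
        converged=True,
        n_starts_used=n_ok,
        bounds=bounds,
    )


def fit_cohort(records, config: FitConfig | None = None) -> pd.DataFrame:
    """Fit every record; one row per specimen, per-specimen failures isolated."""
    config = config or FitConfig()
    rows = []
    for rec in records:
        meta = {
            "specimen_id": getattr(rec, "specimen_id", None),
            "donor_id": getattr(rec, "donor_id", None),
            "tissue": getattr(rec, "tissue", None),
            "group": getattr(rec, "group", None),
            "sex": getattr(rec, "sex", None),
            "age": getattr(rec, "age", float("nan")),
            "bmd": getattr(rec, "bmd", float("nan")),
            "tmd_mean": getattr(rec, "tmd_mean", float("nan")),
        }
        if getattr(rec, "rejected", False):
            rows.append({**meta, "converged": False, "rmse": float("nan"),
                         "message": "rejected record"})
            continue
        try:
            fr = fit_specimen(rec, config)
        except Exception as exc:  # keep cohort fits fault-isolated
            rows.append({**meta, "converged": False, "rmse": float("nan"),
                         "message": f"error: {exc}"})
            continue
        row = {**meta, "converged": fr.converged, "rmse": fr.rmse,
               "message": fr.message, "n_starts_used": fr.n_starts_used,
               "D_max": fr.D_max, "D_end": fr.D_end}
        if fr.params_hat is not None:
            row.update({f: getattr(fr.params_hat, f) for f in RheoParams._FIELDS})
            row["E_inf"] = fr.derived.E_inf
            row["E_0"] = fr.derived.E_0
            row["tan_delta"] = fr.derived.tan_delta
        rows.append(row)
    return pd.DataFrame(rows)
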