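"""Synthetic specimen and cohort generation.

Stands in for cadaveric tensile-test cohorts: group-level constitutive
parameter distributions (per-tissue, per-group means and SDs), donor-level
random effects with repeated specimens per donor, donor BMD, specimen TMD
coupled to stiffness, and additive Gaussian stress noise calibrated to the
fit quality observed in real records.

Specimens are generated by co-simulating the cyclic protocol with the
forward model: each unloading ramp stops where the simulated stress crosses
zero (experimental unloading is to near-zero force, not zero strain), and
the record is truncated at simulated fracture (flow-stress saturation, see
:func:`osteomech.rheology.fracture_kappa`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .protocol import ProtocolSpec, cortical_protocol, trabecular_protocol
from .rheology import (
    ModelState,
    RheoParams,
    StrainSignal,
    StressSignal,
    Trajectory,
    _integrate,
    fracture_kappa,
)

__all__ = [
    "GroupSpec",
    "SpecimenRecord",
    "sample_params",
    "generate_specimen",
    "generate_cohort",
    "load_preset",
    "PRESET_NAMES",
]

_PARAM_FIELDS = RheoParams._FIELDS


@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one tissue/group cohort."""

    tissue: str                      # 'trabecular' | 'cortical'
    group: str                       # 'CTRL' | 'FRAC'
    param_means: RheoParams
    param_sds: dict                  # field name -> SD (same units as the mean)
    n_donors: int = 10
    specimens_per_donor: float = 4.4
    donor_effect_frac: float = 0.5   # share of between-specimen variance at donor level
    noise_sd: float = 3.2e6          # additive stress noise SD, Pa
    bmd_mean: float = 0.9            # donor areal BMD, g/cm^2
    bmd_sd: float = 0.2
    tmd_mean: float = 1000.0         # specimen mean TMD, mgHA/cm^3
    tmd_sd: float = 30.0
    tmd_stiffness_rho: float = 0.6   # correlation of specimen TMD with E_pr deviation
    age_mean: float = 70.0
    age_sd: float = 10.0
    female_frac: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tissue not in ("trabecular", "cortical"):
            raise ValueError("tissue must be 'trabecular' or 'cortical'")
        if self.n_donors < 1 or self.specimens_per_donor < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.donor_effect_frac <= 1.0:
            raise ValueError("donor_effect_frac must lie in [0, 1]")
        sds = {k: float(v) for k, v in self.param_sds.items()}
        unknown = set(sds) - set(_PARAM_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter SD keys: {sorted(unknown)}")
        if any(v < 0.0 for v in sds.values()):
            raise ValueError("parameter SDs must be >= 0")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "param_sds", sds)

    def default_protocol(self) -> ProtocolSpec:
        return trabecular_protocol() if self.tissue == "trabecular" else cortical_protocol()


@dataclass
class SpecimenRecord:
    """One (synthetic) tensile test with donor metadata."""

    specimen_id: str
    donor_id: str
    tissue: str
    group: str
    sex: str
    age: float
    bmd: float
    tmd_mean: float
    signal: StrainSignal
    stress: StressSignal
    true_params: RheoParams | None = None
    trajectory: Trajectory | None = None
    fractured: bool = False
    rejected: bool = False  # failure before the first cycle completed

    def __post_init__(self) -> None:
        if len(self.signal) != len(self.stress):
            raise ValueError("signal and stress must be aligned")


def _truncated_normal(rng, mean, sd, lower=0.0, max_tries=1000):
    if sd == 0.0:
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x > lower:
            return x
    raise RuntimeError("truncated-normal sampling failed; check mean/SD")


def sample_params(spec: GroupSpec, rng: np.random.Generator,
                  donor_shift: dict | None = None):
    """Draw one specimen's parameter vector.

    Variance is split between a donor-level shift (supplied via
    ``donor_shift``, drawn by :func:`generate_cohort`) and a specimen-level
    deviation; each parameter is a truncated normal (> 0) and draws are
    rejected until ``sigma_u > sigma_y``.  Returns ``(params, z_Epr)`` where
    ``z_Epr`` is the standardized total deviation of ``E_pr`` used to couple
    TMD to stiffness.
    """
    means = {f: getattr(spec.param_means, f) for f in _PARAM_FIELDS}
    if any(m <= 0 for m in means.values()):
        raise ValueError("parameter means must be strictly positive")
    shift = donor_shift or {f: 0.0 for f in _PARAM_FIELDS}
    spec_frac = np.sqrt(1.0 - spec.donor_effect_frac)
    for _ in range(1000):
        values = {}
        z_epr = 0.0
        for f in _PARAM_FIELDS:
            sd = spec.param_sds.get(f, 0.0)
            centre = means[f] + shift.get(f, 0.0)
            x = _truncated_normal(rng, centre, spec_frac * sd)
            if f == "E_pr" and sd > 0.0:
                z_epr = (x - means[f]) / sd
            values[f] = x
        if values["sigma_u"] > values["sigma_y"]:
            return RheoParams(**values), z_epr
    raise RuntimeError("could not satisfy sigma_u > sigma_y; check group spec")


def _simulate_protocol_adaptive(params: RheoParams, protocol: ProtocolSpec):
    """Co-simulate the protocol with the model.

    Unloading ramps stop at the zero-stress crossing (floored at zero
    strain); the record is truncated at simulated fracture.  Returns
    ``(signal, stress, trajectory, fractured)``.
    """
    hz = protocol.sample_hz
    rate = protocol.strain_rate
    kap_star = fracture_kappa(params)

    t_all = [np.array([0.0])]
    e_all = [np.array([0.0])]
    state = ModelState()
    sigma0, traj0 = _run_segment(params, np.array([0.0]), np.array([0.0]), state)
    s_all = [sigma0[:1]]
    traj_all = [tuple(a[:1] for a in traj0)]
    t_now, e_now = 0.0, 0.0
    fractured = False

    def seg(e_target, duration):
        n = max(1, int(np.ceil(duration * hz)))
        s = np.linspace(0.0, 1.0, n + 1)[1:]
        return t_now + s * duration, e_now + s * (e_target - e_now)

    def push(ts, es, upto=None):
        nonlocal t_now, e_now, state
        sigma, traj = _run_segment(params, ts, es, state, prev=(t_now, e_now))
        cut = len(ts) if upto is None else upto
        t_all.append(ts[:cut])
        e_all.append(es[:cut])
        s_all.append(sigma[:cut])
        traj_all.append(tuple(a[:cut] for a in traj))
        last = cut - 1
        state = ModelState(
            eps_pl=traj[0][last], kappa=traj[1][last],
            sigma_mx=traj[2][last], D=traj[3][last],
        )
        t_now, e_now = float(ts[last]), float(es[last])
        return sigma, traj

    last_cycle = protocol.n_cycles - 1
    for i, peak in enumerate(protocol.peak_strains):
        ts, es = seg(peak, (peak - e_now) / rate)
        _, traj = _run_segment(params, ts, es, state, prev=(t_now, e_now))
        over = np.flatnonzero(traj[1] >= kap_star)
        if over.size:
            push(ts, es, upto=int(over[0]) + 1)
            fractured = True
            break
        push(ts, es)
        if protocol.hold_s > 0.0:
            push(*seg(peak, protocol.hold_s))
        if i < last_cycle:
            ts, es = seg(0.0, e_now / rate)
            sigma, _ = _run_segment(params, ts, es, state, prev=(t_now, e_now))
            nonpos = np.flatnonzero(sigma <= 0.0)
            cut = int(nonpos[0]) + 1 if nonpos.size else len(ts)
            push(ts, es, upto=cut)
            if protocol.hold_after_unload and protocol.hold_s > 0.0:
                push(*seg(e_now, protocol.hold_s))

    t = np.concatenate(t_all)
    eps = np.concatenate(e_all)
    sigma = np.concatenate(s_all)
    traj = Trajectory(*[np.concatenate([p[k] for p in traj_all]) for k in range(4)])
    return StrainSignal(t, eps), StressSignal(sigma), traj, fractured


def _run_segment(params, ts, es, state, prev=None):
    """Integrate one segment from ``state``.

    ``prev`` is the (time, strain) point the state refers to; prepending it
    makes the stepper advance the Maxwell branch across the segment boundary
    exactly as a whole-signal simulation would.  The prepended sample is
    stripped from all outputs.
    """
    if prev is not None:
        ts = np.r_[prev[0], ts]
        es = np.r_[prev[1], es]
    sigma, eps_pl, kappa, sig_mx, D = _integrate(
        ts, es,
        params.E_pr, params.E_mx, params.sigma_y, params.sigma_u,
        params.p, params.eta, params.k_D,
        state.eps_pl, state.kappa, state.sigma_mx,
    )
    out = (sigma, (eps_pl, kappa, sig_mx, D))
    if prev is not None:
        out = (sigma[1:], (eps_pl[1:], kappa[1:], sig_mx[1:], D[1:]))
    return out


def generate_specimen(
    params: RheoParams,
    protocol: ProtocolSpec,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    **metadata,
) -> SpecimenRecord:
    """Simulate one specimen under the protocol and add measurement noise.

    The noise-free response is co-simulated (adaptive unloading, fracture
    truncation); i.i.d. Gaussian noise of SD ``noise_sd`` (Pa) is then added
    to the stress channel.  A record whose fracture precedes completion of
    the first cycle is flagged ``rejected`` (mimicking discarded tests).
    """
    rng = rng or np.random.default_rng()
    signal, stress, traj, fractured = _simulate_protocol_adaptive(params, protocol)
    sigma = stress.sigma
    if noise_sd > 0.0:
        sigma = sigma + rng.normal(0.0, noise_sd, size=sigma.size)
    first_cycle_t = (protocol.peak_strains[0] / protocol.strain_rate) + protocol.hold_s
    rejected = fractured and signal.t[-1] < first_cycle_t
    meta = {
        "specimen_id": "spec-0", "donor_id": "donor-0",
        "tissue": "cortical", "group": "CTRL", "sex": "F",
        "age": float("nan"), "bmd": float("nan"), "tmd_mean": float("nan"),
    }
    meta.update(metadata)
    return SpecimenRecord(
        signal=signal, stress=StressSignal(sigma), true_params=params,
        trajectory=traj, fractured=fractured, rejected=rejected, **meta,
    )


def generate_cohort(
    spec: GroupSpec,
    protocol: ProtocolSpec | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Generate a full cohort: donors, specimens, metadata manifest.

    Returns ``(records, manifest)`` where ``manifest`` is a tidy DataFrame
    with one row per specimen including the true parameter columns.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    protocol = protocol or spec.default_protocol()

    records = []
    rows = []
    for d in range(spec.n_donors):
        donor_id = f"{spec.tissue[:4]}-{spec.group}-D{d:03d}"
        donor_frac = np.sqrt(spec.donor_effect_frac)
        shift = {
            f: rng.normal(0.0, donor_frac * spec.param_sds.get(f, 0.0))
            for f in _PARAM_FIELDS
        }
        bmd = _truncated_normal(rng, spec.bmd_mean, spec.bmd_sd, lower=0.05)
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 40.0, 105.0))
        sex = "F" if rng.random() < spec.female_frac else "M"
        n_spec = 1 + rng.poisson(max(spec.specimens_per_donor - 1.0, 0.0))
        for s in range(n_spec):
            params, z_epr = sample_params(spec, rng, donor_shift=shift)
            w = rng.normal()
            rho = spec.tmd_stiffness_rho
            tmd = spec.tmd_mean + spec.tmd_sd * (rho * z_epr + np.sqrt(1 - rho**2) * w)
            rec = generate_specimen(
                params, protocol, noise_sd=spec.noise_sd, rng=rng,
                specimen_id=f"{donor_id}-S{s:02d}", donor_id=donor_id,
                tissue=spec.tissue, group=spec.group, sex=sex, age=age,
                bmd=bmd, tmd_mean=tmd,
            )
            records.append(rec)
            row = {
                "specimen_id": rec.specimen_id, "donor_id": donor_id,
                "tissue": spec.tissue, "group": spec.group, "sex": sex,
                "age": age, "bmd": bmd, "tmd_mean": tmd,
                "fractured": rec.fractured, "rejected": rec.rejected,
                "n_samples": len(rec.signal),
            }
            row.update({f"true_{f}": getattr(params, f) for f in _PARAM_FIELDS})
            rows.append(row)
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged group presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "table2_trab_ctrl",
    "table2_trab_frac",
    "table2_cort_ctrl",
    "table2_cort_frac",
)


def load_preset(name: str) -> GroupSpec:
    """Load a packaged cohort preset (``table2_trab_ctrl`` etc.)."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("osteomech.presets").joinpath(f"{name}.yaml").read_text()
    return group_spec_from_yaml(text)


def group_spec_from_yaml(text: str) -> GroupSpec:
    raw = yaml.safe_load(text)
    means = RheoParams(**{f: float(raw["param_means"][f]) for f in _PARAM_FIELDS})
    kwargs = {}
    for k, v in raw.items():
        if k == "param_means":
            continue
        if k == "param_sds":
            v = {kk: float(vv) for kk, vv in v.items()}
        elif isinstance(v, str) and k not in ("tissue", "group"):
            v = float(v)  # YAML 1.1 reads '3.2e6' as a string
        kwargs[k] = v
    kwargs["param_means"] = means
    return GroupSpec(**kwargs)


def group_spec_to_yaml(spec: GroupSpec) -> str:
    data = {
        "tissue": spec.tissue, "group": spec.group,
        "param_means": {f: float(getattr(spec.param_means, f)) for f in _PARAM_FIELDS},
        "param_sds": dict(spec.param_sds),
        "n_donors": spec.n_donors,
        "specimens_per_donor": spec.specimens_per_donor,
        "donor_effect_frac": spec.donor_effect_frac,
        "noise_sd": spec.noise_sd,
        "bmd_mean": spec.bmd_mean, "bmd_sd": spec.bmd_sd,
        "tmd_mean": spec.tmd_mean, "tmd_sd": spec.tmd_sd,
        "tmd_stiffness_rho": spec.tmd_stiffness_rho,
        "age_mean": spec.age_mean, "age_sd": spec.age_sd,
        "female_frac": spec.female_frac,
    }
    return yaml.safe_dump(data, sort_keys=False)
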