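"""Constitutive-model unit tests against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteomech.rheology import (
    ModelState,
    RheoParams,
    StrainSignal,
    damage_at,
    derived_moduli,
    flow_stress,
    fracture_kappa,
    simulate_stress,
)

CORT = RheoParams(E_pr=13.1e9, E_mx=7.6e9, sigma_y=50e6, sigma_u=65e6,
                  p=188.0, eta=15.6e9, k_D=82.3)


class TestParams:
    @pytest.mark.parametrize("field,value", [
        ("E_pr", -1.0), ("E_pr", 0.0), ("eta", -5.0), ("k_D", 0.0),
    ])
    def test_positivity_enforced(self, field, value):
        kwargs = dict(E_pr=1e9, E_mx=1e9, sigma_y=1e7, sigma_u=2e7,
                      p=10.0, eta=1e9, k_D=10.0)
        kwargs[field] = value
        with pytest.raises(ValueError):
            RheoParams(**kwargs)

    def test_yield_below_ultimate_enforced(self):
        with pytest.raises(ValueError):
            RheoParams(E_pr=1e9, E_mx=1e9, sigma_y=2e7, sigma_u=2e7,
                       p=10.0, eta=1e9, k_D=10.0)

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "params.json"
        CORT.to_json(path)
        assert RheoParams.from_json(path) == CORT


class TestFlowStress:
    def test_starts_at_yield(self):
        assert flow_stress(CORT, 0.0) == pytest.approx(50e6)

    def test_saturates_at_ultimate(self):
        assert flow_stress(CORT, 10.0) == pytest.approx(65e6, rel=1e-9)

    def test_matches_scalar_formula(self):
        # independent evaluation of sigma_u + (sigma_y-sigma_u)*exp(-1.88)
        assert flow_stress(CORT, 0.01) == pytest.approx(62711148.41364674, rel=1e-12)

    def test_strictly_increasing(self):
        kappa = np.linspace(0.0, 0.05, 200)
        assert np.all(np.diff(flow_stress(CORT, kappa)) > 0.0)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            flow_stress(CORT, -1e-3)


class TestDamage:
    def test_virgin_state_undamaged(self):
        assert damage_at(CORT, 0.0) == 0.0

    def test_matches_ode_quadrature(self):
        # brute-force integration of dD = k_D (1 - D) dkappa
        kappa_grid = np.linspace(0.0, 0.03, 30001)
        D = 0.0
        dk = kappa_grid[1] - kappa_grid[0]
        for _ in kappa_grid[1:]:
            D += CORT.k_D * (1.0 - D) * dk
        assert damage_at(CORT, kappa_grid[-1]) == pytest.approx(D, rel=1e-3)

    def test_monotone_and_bounded(self):
        kappa = np.linspace(0.0, 0.05, 500)
        D = damage_at(CORT, kappa)
        assert np.all(np.diff(D) > 0.0)
        assert np.all((D >= 0.0) & (D < 1.0))

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            damage_at(CORT, -0.1)


class TestSimulate:
    def test_zero_strain_gives_zero_stress(self, elastic_params):
        signal = StrainSignal(np.linspace(0.0, 60.0, 400), np.zeros(400))
        stress, traj = simulate_stress(elastic_params, signal)
        assert np.all(stress.sigma == 0.0)
        assert np.all(traj.kappa == 0.0) and np.all(traj.D == 0.0)

    def test_zener_ramp_closed_form(self, elastic_params):
        # below yield: sigma(t) = E_pr*eps + eta*rate*(1 - exp(-E_mx t / eta))
        p = elastic_params
        rate = 0.001
        t = np.linspace(0.0, 5.0, 50001)
        stress, _ = simulate_stress(p, StrainSignal(t, rate * t))
        expected = p.E_pr * rate * t + p.eta * rate * (1.0 - np.exp(-p.E_mx * t / p.eta))
        err = np.max(np.abs(stress.sigma[1:] - expected[1:])) / expected[-1]
        assert err < 1e-3

    def test_hold_relaxation_closed_form(self, elastic_params):
        p = elastic_params
        rate, eps0 = 0.001, 0.004
        t_ramp = np.linspace(0.0, eps0 / rate, 2001)
        t_hold = np.linspace(eps0 / rate, eps0 / rate + 30.0, 3001)[1:]
        t = np.r_[t_ramp, t_hold]
        eps = np.minimum(rate * t, eps0)
        stress, _ = simulate_stress(p, StrainSignal(t, eps))
        tau = p.eta / p.E_mx
        sig_mx0 = p.eta * rate * (1.0 - math.exp(-t_ramp[-1] / tau))
        hold = t_hold - t_ramp[-1]
        expected = p.E_pr * eps0 + sig_mx0 * np.exp(-hold / tau)
        err = np.max(np.abs(stress.sigma[len(t_ramp):] - expected)) / (p.E_pr * eps0)
        assert err < 1e-3
        # fully relaxed stress approaches the long-term spring alone
        assert stress.sigma[-1] == pytest.approx(p.E_pr * eps0, rel=1e-3)

    def test_agrees_with_explicit_fine_step_integrator(self):
        """Production stepper vs brute-force explicit Euler at 100x finer steps."""
        from osteomech.protocol import ProtocolSpec, build_protocol

        spec = ProtocolSpec.linear(3, 0.012, hold_s=5.0, sample_hz=5.0)
        signal = build_protocol(spec)
        stress, _ = simulate_stress(CORT, signal)

        # independent explicit integrator on a 100x refined grid
        t_f = np.interp(np.linspace(0, signal.t.size - 1, (signal.t.size - 1) * 100 + 1),
                        np.arange(signal.t.size), signal.t)
        e_f = np.interp(t_f, signal.t, signal.eps)
        eps_pl = kappa = sig_mx = 0.0
        out = np.zeros_like(t_f)
        for i in range(1, t_f.size):
            dt = t_f[i] - t_f[i - 1]
            D = 1.0 - math.exp(-CORT.k_D * kappa)
            e_tr = e_f[i] - eps_pl
            sflow = CORT.sigma_u + (CORT.sigma_y - CORT.sigma_u) * math.exp(-CORT.p * kappa)
            if CORT.E_pr * abs(e_tr) > sflow:
                lo, hi = 0.0, abs(e_tr)
                for _ in range(60):  # plain bisection: independent of the Newton solve
                    mid = 0.5 * (lo + hi)
                    g = CORT.E_pr * (abs(e_tr) - mid) - (
                        CORT.sigma_u + (CORT.sigma_y - CORT.sigma_u)
                        * math.exp(-CORT.p * (kappa + mid)))
                    if g > 0:
                        lo = mid
                    else:
                        hi = mid
                dk = 0.5 * (lo + hi)
                eps_pl += math.copysign(dk, e_tr)
                kappa += dk
                D = 1.0 - math.exp(-CORT.k_D * kappa)
            rate = (e_f[i] - e_f[i - 1]) / dt
            sig_mx += dt * (1.0 - D) * CORT.E_mx * (rate - sig_mx / CORT.eta)
            out[i] = (1.0 - D) * CORT.E_pr * (e_f[i] - eps_pl) + sig_mx
        ref = out[::100]
        scale = np.max(np.abs(ref))
        assert np.max(np.abs(stress.sigma - ref)) / scale < 5e-3

    def test_rate_limits(self, elastic_params):
        p = elastic_params
        eps_peak = 0.003
        # slow: peak stress -> E_pr * eps_peak
        t = np.linspace(0.0, eps_peak / 1e-6, 4000)
        slow, _ = simulate_stress(p, StrainSignal(t, 1e-6 * t))
        assert slow.sigma[-1] == pytest.approx(p.E_pr * eps_peak, rel=5e-3)
        # fast (short times): tangent -> E_pr + E_mx
        t = np.linspace(0.0, eps_peak / 1.0, 4000)
        fast, _ = simulate_stress(p, StrainSignal(t, 1.0 * t))
        tangent = fast.sigma[-1] / eps_peak
        assert tangent == pytest.approx(p.E_pr + p.E_mx, rel=5e-3)

    def test_no_plastic_hysteresis_below_yield(self, elastic_params):
        """Loading and unloading tangents agree at vanishing rate (kappa stays 0)."""
        p = elastic_params
        rate = 1e-5
        eps0 = 0.002
        T = eps0 / rate
        t = np.linspace(0.0, 2 * T, 8001)
        eps = np.where(t <= T, rate * t, eps0 - rate * (t - T))
        stress, traj = simulate_stress(p, StrainSignal(t, eps))
        assert np.all(traj.kappa == 0.0)
        mid = t.size // 2
        load_tan = np.polyfit(eps[mid // 2:mid], stress.sigma[mid // 2:mid], 1)[0]
        unload_tan = np.polyfit(eps[mid + mid // 2:], stress.sigma[mid + mid // 2:], 1)[0]
        assert load_tan == pytest.approx(unload_tan, rel=2e-2)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-0.02, 0.04), min_size=3, max_size=12),
           st.integers(0, 10_000))
    def test_kappa_and_damage_never_decrease(self, knots, seed):
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.uniform(0.5, 5.0, len(knots)))
        t = np.r_[0.0, t]
        eps = np.r_[0.0, knots]
        signal = StrainSignal(t, eps)
        _, traj = simulate_stress(CORT, signal)
        assert np.all(np.diff(traj.kappa) >= -1e-15)
        assert np.all(np.diff(traj.D) >= -1e-15)
        assert np.all((traj.D >= 0.0) & (traj.D < 1.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            StrainSignal(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            simulate_stress(CORT, StrainSignal(np.array([0.0, 1.0]), np.zeros(2)),
                            initial=ModelState(D=1.0))


class TestDerivedModuli:
    def test_cortical_group_means(self):
        d = derived_moduli(CORT)
        assert d.E_inf == pytest.approx(13.1e9)
        assert d.E_0 == pytest.approx(20.7e9)
        assert d.tan_delta == pytest.approx(0.028359799244614178, rel=1e-12)

    @pytest.mark.parametrize("omega", [1e-6, 1e6])
    def test_elastic_and_glassy_limits_lossless(self, omega):
        assert derived_moduli(CORT, omega).tan_delta < 1e-3

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            derived_moduli(CORT, 0.0)


def test_fracture_kappa_matches_flow_saturation():
    k_star = fracture_kappa(CORT)
    assert flow_stress(CORT, k_star) == pytest.approx(0.99 * CORT.sigma_u, rel=1e-9)
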