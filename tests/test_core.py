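"""Unit tests for the traditional single-region neural mass model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq, fsolve, minimize_scalar

from ssvepsim.core import (
    ConnectivityConstants,
    NoiseSpec,
    SigmoidParams,
    SimulationConfig,
    SimulationDiverged,
    SynapticKernel,
    default_excitatory_kernel,
    default_inhibitory_kernel,
    impulse_response,
    region_derivatives,
    sigmoid,
    simulate_traditional,
)


class TestSigmoid:
    def test_half_maximum_at_v0(self):
        p = SigmoidParams()
        assert sigmoid(p.v0, p) == pytest.approx(p.e0)

    def test_saturates_at_twice_e0(self):
        p = SigmoidParams()
        assert sigmoid(p.v0 + 1000.0 / p.r, p) > 1.999 * p.e0

    def test_standard_value_at_zero(self):
        # independent arithmetic: 2·2.5 / (1 + e^{0.56·6})
        p = SigmoidParams(e0=2.5, v0=6.0, r=0.56)
        expected = 5.0 / (1.0 + math.exp(3.36))
        assert sigmoid(0.0, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1678, abs=5e-5)

    @given(st.floats(min_value=-100, max_value=100), st.floats(min_value=-100, max_value=100))
    @settings(deadline=None)
    def test_monotone_and_bounded(self, v1, v2):
        p = SigmoidParams()
        s1, s2 = sigmoid(v1, p), sigmoid(v2, p)
        assert 0.0 <= s1 <= 2 * p.e0 and 0.0 <= s2 <= 2 * p.e0
        if v1 < v2:
            assert s1 <= s2

    def test_rejects_non_finite_input(self):
        with pytest.raises(ValueError):
            sigmoid(float("nan"), SigmoidParams())

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            SigmoidParams(e0=-1.0)
        with pytest.raises(ValueError):
            SigmoidParams(r=0.0)


class TestImpulseResponse:
    def test_zero_at_origin_and_before(self):
        k = default_excitatory_kernel()
        assert impulse_response(k, 0.0) == 0.0
        assert impulse_response(k, -0.5) == 0.0

    def test_peak_location_and_value(self):
        # the analytic maximum G/e at t = 1/omega, cross-checked by
        # numerical maximisation of the curve itself
        k = SynapticKernel(G=3.25, omega=100.0)
        res = minimize_scalar(
            lambda t: -impulse_response(k, t),
            bounds=(0, 10 / k.omega),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert res.x == pytest.approx(1.0 / k.omega, rel=1e-5)
        assert -res.fun == pytest.approx(k.G / math.e, rel=1e-8)
        assert k.G / math.e == pytest.approx(1.1956, abs=5e-5)

    @pytest.mark.parametrize("kernel", [default_excitatory_kernel(), default_inhibitory_kernel()])
    def test_integral_equals_G_over_omega(self, kernel):
        total, _ = quad(lambda t: impulse_response(kernel, t), 0, 20 / kernel.omega)
        assert total == pytest.approx(kernel.G / kernel.omega, rel=1e-6)


class TestRegionDerivatives:
    def setup_method(self):
        self.sig = SigmoidParams()
        self.exc = default_excitatory_kernel()
        self.inh = default_inhibitory_kernel()
        self.conn = ConnectivityConstants()

    def test_all_zero_state(self):
        d = region_derivatives(np.zeros(6), 0.0, self.sig, self.exc, self.inh, self.conn)
        s0 = sigmoid(0.0, self.sig)
        assert d[3] == pytest.approx(self.exc.G * self.exc.omega * s0)
        assert d[4] == pytest.approx(self.exc.G * self.exc.omega * self.conn.C2 * s0)
        assert d[5] == pytest.approx(self.inh.G * self.inh.omega * self.conn.C4 * s0)
        assert np.all(d[:3] == 0.0)

    def test_input_rate_enters_linearly_in_y4_only(self):
        state = np.array([0.1, 0.5, -0.2, 0.0, 0.0, 0.0])
        d1 = region_derivatives(state, 100.0, self.sig, self.exc, self.inh, self.conn)
        d2 = region_derivatives(state, 200.0, self.sig, self.exc, self.inh, self.conn)
        delta = d2 - d1
        assert delta[4] == pytest.approx(self.exc.G * self.exc.omega * 100.0)
        mask = np.ones(6, dtype=bool)
        mask[4] = False
        assert np.allclose(delta[mask], 0.0)

    def test_equilibrium_residual(self):
        # locate the fixed point with an independent root finder and verify
        # the derivatives vanish there
        def rhs(state):
            return region_derivatives(state, 220.0, self.sig, self.exc, self.inh, self.conn)

        x0 = np.array([0.1, 5.0, 5.0, 0.0, 0.0, 0.0])
        eq = fsolve(rhs, x0, full_output=False, xtol=1e-13)
        assert np.max(np.abs(rhs(eq))) < 1e-8


class TestSimulateTraditional:
    def test_output_length(self):
        cfg = SimulationConfig(duration=2.0, burn_in=0.5, seed=0)
        ts = simulate_traditional(NoiseSpec(220, 100), cfg)
        assert len(ts) == round((cfg.duration - cfg.burn_in) / cfg.dt)
        assert ts.fs == pytest.approx(1.0 / cfg.dt)

    def test_seed_determinism(self):
        cfg = SimulationConfig(duration=1.5, burn_in=0.5, seed=42)
        a = simulate_traditional(NoiseSpec(220, 100), cfg)
        b = simulate_traditional(NoiseSpec(220, 100), cfg)
        assert np.array_equal(a.values, b.values)

    def test_zero_variance_is_seed_independent(self):
        noise = NoiseSpec(mu=220.0, sigma2=0.0)
        a = simulate_traditional(noise, SimulationConfig(duration=1.5, burn_in=0.5, seed=1))
        b = simulate_traditional(noise, SimulationConfig(duration=1.5, burn_in=0.5, seed=2))
        assert np.array_equal(a.values, b.values)

    def test_divergence_is_flagged_with_step(self):
        # absurd gain forces overflow; the error names the first bad step
        bad = SynapticKernel(G=1e154, omega=1e5)
        with pytest.raises(SimulationDiverged) as err:
            simulate_traditional(
                NoiseSpec(220, 100),
                SimulationConfig(duration=1.5, burn_in=0.5, seed=0),
                exc=bad,
            )
        assert err.value.step >= 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=1.0, burn_in=2.0)
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0)


class TestKernelODEEquivalence:
    """The second-order ODE pair reproduces the synaptic kernel."""

    @staticmethod
    def _simulate_impulse(kernel, dt, t_end):
        # unit-rate impulse: one step of height 1/dt at t = 0
        n = round(t_end / dt)
        y = yd = 0.0
        gw, w, w2 = kernel.G * kernel.omega, kernel.omega, kernel.omega**2
        out = np.empty(n)
        for i in range(n):
            x = 1.0 / dt if i == 0 else 0.0
            ydd = gw * x - 2.0 * w * yd - w2 * y
            y, yd = y + dt * yd, yd + dt * ydd
            out[i] = y
        return out

    def test_first_order_convergence_to_kernel(self):
        k = default_excitatory_kernel()
        t_end = 10 / k.omega
        errors = {}
        for dt in (1e-4, 5e-5):
            sim = self._simulate_impulse(k, dt, t_end)
            grid = (np.arange(len(sim)) + 1) * dt
            errors[dt] = np.max(np.abs(sim - impulse_response(k, grid)))
        # O(dt) error: halving dt halves the error (ratio within 30%)
        ratio = errors[1e-4] / errors[5e-5]
        assert 1.5 < ratio < 2.5
        assert errors[1e-4] < 0.05 * k.G / math.e
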