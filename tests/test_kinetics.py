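"""Gating kinetics: the h-gate low-pass property and channel currents."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dendrocfc import kinetics as kin


class TestIhGate:
    def test_activation_monotone_decreasing(self):
        v = np.linspace(-120.0, 50.0, 500)
        act = kin.ih_activation(v)
        assert np.all(np.diff(act) < 0)
        assert np.all((act >= 0) & (act <= 1))

    def test_saturation_limits(self):
        assert kin.ih_activation(-300.0) == pytest.approx(1.0, abs=1e-6)
        assert kin.ih_activation(150.0) == pytest.approx(0.0, abs=1e-6)

    def test_more_active_at_hyperpolarized_rest(self):
        # across the resting range, depolarization deactivates the gate
        assert kin.ih_activation(-85.0) > kin.ih_activation(-56.0)

    def test_time_constant_positive_and_slow(self):
        v = np.linspace(-120.0, -40.0, 200)
        tau = kin.ih_time_constant(v)
        assert np.all(tau > 0)
        # slower than one 40 Hz period across the operating range
        v_op = np.linspace(-90.0, -55.0, 100)
        assert np.all(kin.ih_time_constant(v_op) > 25.0)

    def test_gate_blind_to_gamma_but_follows_theta(self):
        # single-pole low-pass factor 1/sqrt(1+(w tau)^2) at each frequency:
        # the gate must partition the two injected bands - attenuate 40 Hz
        # modulation more than tenfold in absolute terms (a single pole caps
        # the *relative* attenuation at the frequency ratio, 10x) while
        # still following 4 Hz with appreciable gain
        tau_s = float(kin.ih_time_constant(-70.0)) * 1e-3
        a4 = 1.0 / np.sqrt(1.0 + (2 * np.pi * 4 * tau_s) ** 2)
        a40 = 1.0 / np.sqrt(1.0 + (2 * np.pi * 40 * tau_s) ** 2)
        assert a40 < 0.1
        assert a4 > 0.25
        assert a4 / a40 > 5.0

    def test_sinusoidal_drive_response_matches_ode(self):
        """Gate under V(t) = -70 + 10 sin(2 pi 4 t): 4 Hz oscillation with
        a lag in (0, 90) degrees, cross-checked against solve_ivp."""
        gate = kin.channel_spec("h").gates[0]

        def v_of_t(t_ms):
            return -70.0 + 10.0 * np.sin(2 * np.pi * 4.0 * t_ms * 1e-3)

        def rhs(t, y):
            v = v_of_t(t)
            return (gate.steady_state(v) - y[0]) / gate.time_constant(v)

        x0 = float(gate.steady_state(-70.0))
        sol = solve_ivp(rhs, (0.0, 3000.0), [x0], max_step=1.0,
                        dense_output=True)
        t = np.linspace(2000.0, 3000.0, 4001)  # last 4 cycles
        x = sol.sol(t)[0]
        # oscillates about its mean at 4 Hz
        xc = x - x.mean()
        period = 250.0
        # phase of gate minimum relative to voltage maximum: voltage peaks
        # at t = 62.5 + k*250; the gate (deactivating with depolarization)
        # reaches its minimum a lag later
        t_vpeak = 2062.5
        t_xmin = t[np.argmin(np.where((t >= 2000) & (t < 2250), x, np.inf))]
        lag_deg = ((t_xmin - t_vpeak) / period) * 360.0 % 360.0
        assert 0.0 < lag_deg < 90.0
        # amplitude matches the linearized first-order response
        tau = float(gate.time_constant(-70.0))
        # finite-difference slope of the steady-state curve at -70
        dmdv = (gate.steady_state(-69.5) - gate.steady_state(-70.5)) / 1.0
        w = 2 * np.pi * 4e-3  # rad/ms
        pred_amp = abs(dmdv) * 10.0 / np.sqrt(1.0 + (w * tau) ** 2)
        assert np.ptp(xc) / 2.0 == pytest.approx(pred_amp, rel=0.15)


class TestGateRelaxation:
    @pytest.mark.parametrize("channel,gate_idx", [("KM", 0), ("KA", 1)])
    def test_fixed_voltage_relaxation_is_exponential(self, channel, gate_idx):
        gate = kin.channel_spec(channel).gates[gate_idx]
        v = -50.0
        x0, xinf = 0.1, float(gate.steady_state(v))
        tau = float(gate.time_constant(v))
        t = np.linspace(0.0, 5 * tau, 200)
        closed = xinf + (x0 - xinf) * np.exp(-t / tau)
        # exponential-Euler iteration with small steps converges to the
        # same trajectory
        dt = tau / 500.0
        steps = np.arange(0.0, 5 * tau, dt)
        x = np.empty(steps.size)
        cur = x0
        for i, _ in enumerate(steps):
            x[i] = cur
            cur += (xinf - cur) * (1 - np.exp(-dt / tau))
        interp = np.interp(t, steps, x)
        assert np.allclose(interp, closed, atol=1e-3)


class TestChannelCurrent:
    def test_zero_density_zero_current(self):
        spec = kin.channel_spec("KDR")
        assert kin.channel_current(spec, 0.0, [1.0], -20.0) == 0.0

    def test_zero_at_reversal(self):
        spec = kin.channel_spec("h")
        assert kin.channel_current(
            spec, 5.0, [1.0], spec.reversal
        ) == pytest.approx(0.0)

    def test_linear_in_density_and_inward_sign(self):
        spec = kin.channel_spec("h")
        i1 = kin.channel_current(spec, 52.9971, [0.5], -80.0)
        i2 = kin.channel_current(spec, 2 * 52.9971, [0.5], -80.0)
        assert i2 == pytest.approx(2 * i1)
        assert i1 < 0  # inward below the h reversal
        expected = 52.9971 * 0.5 ** spec.gates[0].exponent * (
            -80.0 - spec.reversal
        )
        assert i1 == pytest.approx(expected)

    def test_gate_state_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            kin.channel_current(kin.channel_spec("KDR"), 1.0, [1.2], 0.0)

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            kin.channel_spec("KX")

    def test_ca_gated_currents_vanish_without_calcium(self):
        kc = kin.channel_spec("KC")
        assert kin.channel_current(kc, 10.0, [1.0], -20.0, chi=0.0) == 0.0
        k2 = kin.channel_spec("K2")
        q_inf = k2.gates[0].steady_state(0.0)  # chi = 0
        assert q_inf == 0.0
        assert kin.channel_current(k2, 10.0, [q_inf], -20.0, chi=0.0) == 0.0
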