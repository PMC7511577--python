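"""Cable integrator against closed-form and hand-solved oracles."""

import numpy as np
import pytest

from dendrocfc.model import build_model
from dendrocfc.protocols import CurrentSource, InjectionProtocol, sine, step
from dendrocfc.simulator import (
    IntegrationError,
    _Compiled,
    input_resistance,
    integrate,
    resting_state,
    steady_state,
)
from dendrocfc.synth import generate_passive_fixture
from conftest import make_passive_chain, make_passive_model


class TestPassiveOracles:
    def test_step_response_matches_rc_closed_form(self):
        r, cm_uf, area = 100.0, 1.0, 1e-5
        model = make_passive_model(r, cm_uf, e_leak=-70.0, area_cm2=area)
        proto = InjectionProtocol((step("soma", 0.2),))
        tr = integrate(model, proto, duration=200.0, dt=0.025)
        c_nf = cm_uf * area * 1e3
        t_ref, v_ref = generate_passive_fixture(r, c_nf, proto, 200.0,
                                                v_rest=-70.0)
        v_sim = np.interp(t_ref, tr.t, tr.channel("soma"))
        assert np.max(np.abs(v_sim - v_ref)) < 0.01 * (0.2 * r)

    def test_sinusoid_steady_state_amplitude(self):
        r, cm_uf, area = 100.0, 1.0, 1e-5
        model = make_passive_model(r, cm_uf, e_leak=-70.0, area_cm2=area)
        f = 40.0
        proto = InjectionProtocol((sine("soma", 0.2, f),))
        tr = integrate(model, proto, duration=300.0, dt=0.025)
        tau_ms = r * (cm_uf * area * 1e3)
        w = 2 * np.pi * f * 1e-3
        expected = 0.2 * r / np.sqrt(1 + (w * tau_ms) ** 2)
        steady = tr.channel("soma")[tr.t > 150.0] + 70.0
        assert (steady.max() - steady.min()) / 2 == pytest.approx(
            expected, rel=0.01
        )

    def test_two_compartment_dc_divider(self):
        model = make_passive_chain(2)
        cm = _Compiled(model)
        amp = 0.1  # nA into c0
        v = steady_state(model, {"c0": amp})
        # hand-solved 2x2 conductance system (relative to e_leak)
        g_l = model.passive.g_leak * cm.area[0]  # mS per compartment
        g_ax = cm.g_axial_ms[(1, 0)]  # mS
        i_ms = amp * 1e-3  # nA -> uA; with mS and mV: I(uA) = G(mS)*V(mV)
        a = np.array([[g_l + g_ax, -g_ax], [-g_ax, g_l + g_ax]])
        dv = np.linalg.solve(a, np.array([i_ms, 0.0]))
        assert v - model.passive.e_leak == pytest.approx(dv, rel=1e-6)

    def test_passive_rest_is_leak_reversal(self):
        model = make_passive_chain(4, e_leak=-64.0)
        rest = resting_state(model)
        assert np.allclose(list(rest.values()), -64.0, atol=1e-9)

    def test_isolated_passive_input_resistance_analytic(self):
        model = make_passive_model(r_mohm=80.0)
        assert input_resistance(model, "soma", method="steady") == (
            pytest.approx(80.0, rel=1e-6)
        )
        assert input_resistance(model, "soma", duration=500.0) == (
            pytest.approx(80.0, rel=1e-3)
        )

    def test_axial_current_balance_at_steady_state(self):
        """Interior nodes carry no net current at steady state (solved
        independently from the assembled linear system)."""
        model = make_passive_chain(3)
        cm = _Compiled(model)
        v = steady_state(model, {"c0": 0.2})
        g_l = model.passive.g_leak  # mS/cm^2
        for i in (1, 2):
            axial = -(cm.L @ v)[i]  # mS/cm^2 * mV = uA/cm^2 into node i
            leak = g_l * (v[i] - model.passive.e_leak)
            assert axial - leak == pytest.approx(0.0, abs=1e-9)


class TestActiveModels:
    def test_rest_within_reported_range(self):
        for mode in ("exp_gradient", "uniform", "none"):
            rest = np.array(list(resting_state(build_model(mode)).values()))
            assert rest.min() > -90.0 and rest.max() < -50.0

    def test_removing_h_current_hyperpolarizes_everywhere(self):
        r_none = resting_state(build_model("none"))
        r_unif = resting_state(build_model("uniform"))
        for cid in r_none:
            assert r_none[cid] < r_unif[cid] + 1e-9

    def test_gradient_depolarizes_distal_dendrite(self):
        r_unif = resting_state(build_model("uniform"))
        r_exp = resting_state(build_model("exp_gradient"))
        for cid in ("tuft1", "tuft2", "tuft3", "apdend13"):
            assert r_exp[cid] > r_unif[cid]

    def test_input_resistance_ordering_across_models(self):
        r = {
            mode: {
                site: input_resistance(build_model(mode), site,
                                       method="steady")
                for site in ("soma", "apdend13")
            }
            for mode in ("exp_gradient", "uniform", "none")
        }
        for site in ("soma", "apdend13"):
            assert r["none"][site] > r["uniform"][site] > (
                r["exp_gradient"][site]
            )

    def test_step_and_steady_measurements_agree(self):
        model = build_model("uniform")
        r_steady = input_resistance(model, "soma", method="steady")
        r_step = input_resistance(model, "soma", method="step")
        assert r_step == pytest.approx(r_steady, rel=0.05)


class TestIntegrationContract:
    def test_engines_equivalent(self):
        model = build_model("exp_gradient")
        proto = InjectionProtocol(
            (sine("apdend13", 1.5, 4.0), sine("apdend1", 1.5, 40.0))
        )
        tr_nb = integrate(model, proto, duration=150.0, dt=0.05,
                          engine="numba")
        tr_np = integrate(model, proto, duration=150.0, dt=0.05,
                          engine="numpy")
        assert np.max(np.abs(tr_nb.v - tr_np.v)) < 1e-9

    def test_halving_dt_barely_changes_solution(self):
        model = build_model("uniform")
        proto = InjectionProtocol(
            (sine("apdend13", 1.5, 4.0), sine("apdend1", 1.5, 40.0))
        )
        tr_a = integrate(model, proto, duration=600.0, dt=0.05,
                         record_every=20)
        tr_b = integrate(model, proto, duration=600.0, dt=0.025,
                         record_every=40)
        late = tr_a.t > 400.0
        assert np.max(np.abs(tr_a.v[late] - tr_b.v[late])) < 0.1

    def test_determinism(self):
        model = build_model("none")
        proto = InjectionProtocol((sine("soma", 1.0, 4.0),))
        a = integrate(model, proto, duration=100.0, dt=0.05)
        b = integrate(model, proto, duration=100.0, dt=0.05)
        assert np.array_equal(a.v, b.v)

    def test_blow_up_reports_site_and_time(self):
        model = build_model("none")
        proto = InjectionProtocol((step("tuft3", 80.0),))
        with pytest.raises(IntegrationError, match="tuft3|t="):
            integrate(model, proto, duration=500.0, dt=0.05)

    def test_oversized_dt_rejected(self):
        model = build_model("none")
        with pytest.raises(ValueError, match="dt"):
            integrate(model, InjectionProtocol(()), duration=10.0, dt=0.1)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            CurrentSource("soma", "sawtooth", 1.0)
        with pytest.raises(ValueError):
            CurrentSource("soma", "sine", float("inf"), 4.0)

    def test_trace_csv_round_trip(self, tmp_path):
        from dendrocfc.cfc import read_trace_csv

        model = make_passive_model()
        proto = InjectionProtocol((step("soma", 0.1),))
        tr = integrate(model, proto, duration=50.0, dt=0.05)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        df = read_trace_csv(path)
        assert list(df.columns) == ["time_ms", "soma"]
        assert np.allclose(df["soma"].to_numpy(), tr.channel("soma"))
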