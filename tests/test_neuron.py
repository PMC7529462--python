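"""Three-compartment TC neuron: geometry, integrator, protocols."""

import numpy as np
import pytest
from scipy.optimize import brentq, fsolve

from thalburst import IonConditions, TCModel, TCNeuronParams, condition_params
from thalburst.channels import channel_current, gating_steady_taus
from thalburst.neuron import reference_neuron
from thalburst.passive import analytic_pulse_response


@pytest.fixture(scope="module")
def passive_params():
    return TCNeuronParams(diam_soma=30.0, diam_dend=5.0, l_dend=400.0,
                          g_pas=1e-4)


class TestGeometry:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            TCNeuronParams(diam_soma=-1.0, diam_dend=5.0, l_dend=400.0,
                           g_pas=1e-4)

    def test_negative_density_rejected(self):
        d = np.zeros((3, 5))
        d[0, 0] = -1e-4
        with pytest.raises(ValueError):
            TCNeuronParams(diam_soma=30.0, diam_dend=5.0, l_dend=400.0,
                           g_pas=1e-4, densities=d)

    def test_param_dict_round_trip(self):
        p = reference_neuron()
        q = TCNeuronParams.from_dict(p.to_dict())
        assert np.allclose(q.densities, p.densities)
        assert q.diam_soma == p.diam_soma


class TestPassiveBehaviour:
    def test_settles_to_leak_reversal(self, passive_params):
        m = TCModel(passive_params)
        n = 20001
        t, v, *_ = m._run(0.1, 2000.0, np.zeros(n), np.zeros(n),
                          v0=-80.0, rec_every=100)
        assert np.allclose(v[-1], -70.0, atol=1e-3)

    def test_input_resistance_matches_three_node_circuit(self, passive_params):
        """Steady deflection to a small step equals the analytic solution of
        the 3-node resistor network."""
        p = passive_params
        m = TCModel(p)
        n = 60001
        i_inj = np.full(n, 0.01)  # +10 pA
        t, v, *_ = m._run(0.1, 6000.0, i_inj, np.zeros(n), rec_every=100)
        gp = p.g_pas * p.areas * 1e6
        g12, g23 = p.axial_conductances
        G = np.array([[gp[0] + g12, -g12, 0.0],
                      [-g12, gp[1] + g12 + g23, -g23],
                      [0.0, -g23, gp[2] + g23]])
        b = np.array([gp[0] * -70.0 + 0.01, gp[1] * -70.0, gp[2] * -70.0])
        v_analytic = np.linalg.solve(G, b)
        assert np.allclose(v[-1], v_analytic, atol=1e-3)

    def test_engine_matches_analytic_pulse_response(self, passive_params):
        m = TCModel(passive_params)
        tr = m.run_current_pulse(amplitude_pa=-50.0, width_ms=10.0,
                                 t_total=500.0)
        va = analytic_pulse_response(passive_params, tr.t, -50.0, 10.0,
                                     onset_ms=100.0)
        assert np.max(np.abs((tr.v_soma + 70.0) - va)) < 0.05

    def test_dendritic_attenuation_monotone(self, passive_params):
        m = TCModel(passive_params)
        n = 40001
        t, v, *_ = m._run(0.1, 4000.0, np.full(n, 0.05), np.zeros(n),
                          rec_every=200)
        soma, d1, d2 = v[-1]
        assert soma > d1 > d2  # depolarizing somatic injection attenuates


class TestHoldingCurrent:
    def test_passive_at_leak_reversal_is_zero(self, passive_params):
        i, ok = TCModel(passive_params).find_holding_current(-70.0)
        assert ok and i == pytest.approx(0.0, abs=1e-5)

    def test_passive_matches_circuit_solution(self, passive_params):
        p = passive_params
        i, ok = TCModel(p).find_holding_current(-65.0)
        gp = p.g_pas * p.areas * 1e6
        g12, g23 = p.axial_conductances
        # dendrites unclamped: solve their steady state with soma at -65
        A = np.array([[gp[1] + g12 + g23, -g23], [-g23, gp[2] + g23]])
        b = np.array([gp[1] * -70.0 + g12 * -65.0, gp[2] * -70.0])
        v1, v2 = np.linalg.solve(A, b)
        expect = gp[0] * (-65.0 + 70.0) + g12 * (-65.0 - v1)
        assert ok and i == pytest.approx(expect, rel=1e-3)

    def test_full_model_matches_steady_state_root(self, ref_params):
        """Independent oracle: solve the nonlinear steady state of the two
        dendritic compartments (gates at steady state) with the soma clamped,
        then read the clamp current off the algebraic system."""
        p = ref_params
        ions = IonConditions()
        v_hold = -70.0
        areas = p.areas * 1e6  # cm^2 -> uS conversion factor with S/cm^2
        g12, g23 = p.axial_conductances

        def dens_row(k):
            return {"pbar_T": p.densities[k, 0], "gbar_h": p.densities[k, 1],
                    "gbar_A": p.densities[k, 2], "gbar_Kir": p.densities[k, 3],
                    "gbar_NaP": p.densities[k, 4]}

        def membrane_current(v, k):
            # steady-state ionic current density (mA/cm^2)
            git = gating_steady_taus("IT", v)
            gih = gating_steady_taus("Ih", v)
            gia = gating_steady_taus("IA", v)
            i = channel_current("IT", {"m": git["m_inf"], "h": git["h_inf"]},
                                v, dens_row(k), ions)
            i += channel_current("Ih", {"m": gih["m_inf"]}, v, dens_row(k), ions)
            i += channel_current("IA", {"m1": gia["m1_inf"], "m2": gia["m2_inf"],
                                        "h1": gia["h_inf"], "h2": gia["h_inf"]},
                                 v, dens_row(k), ions)
            i += channel_current("IKir", {}, v, dens_row(k), ions)
            i += channel_current("INaP", {}, v, dens_row(k), ions)
            i += channel_current("leak", {}, v,
                                 {"g_pas": p.g_pas, "e_pas": p.e_pas})
            return i

        def resid(x):
            v1, v2 = x
            r1 = (-membrane_current(v1, 1) * areas[1]
                  + g12 * (v_hold - v1) + g23 * (v2 - v1))
            r2 = -membrane_current(v2, 2) * areas[2] + g23 * (v1 - v2)
            return [r1, r2]

        v1, v2 = fsolve(resid, [-70.0, -70.0], xtol=1e-12)
        i_expect = membrane_current(v_hold, 0) * areas[0] + g12 * (v_hold - v1)
        i_sim, ok = TCModel(p).find_holding_current(v_hold)
        assert ok
        # calcium accumulation shifts the GHK driving force slightly in the
        # dynamic run; agree to a couple of pA
        assert i_sim == pytest.approx(i_expect, abs=3e-3)

    def test_out_of_range_hold_rejected(self, ref_model):
        with pytest.raises(ValueError):
            ref_model.find_holding_current(-30.0)


class TestIpscProtocol:
    def test_zero_amplitude_waveform_stays_at_hold(self, ref_model):
        k = condition_params("Control").with_scale(1e-9)
        tr = ref_model.run_ipsc_protocol(k, v_hold=-65.0, t_total=8000.0)
        # after pulse recovery, before/during "IPSC" the trace sits at hold
        late = tr.v_soma[(tr.t > 2800) & (tr.t < 8000)]
        assert np.max(np.abs(late + 65.0)) < 0.5

    def test_gat3_produces_lts_dual_does_not(self, ipsc_traces_200):
        w3 = ipsc_traces_200["GAT3-Block"]
        wd = ipsc_traces_200["Dual-Block"]
        sel = lambda tr: tr.v_soma[(tr.t > 3100) & (tr.t < 10000)]
        assert sel(w3).max() > -48.0       # rebound low-threshold spike
        assert sel(wd).max() < -55.0       # no rebound event

    def test_timestep_convergence(self, ref_params):
        k = condition_params("GAT1-Block").with_scale(2.0)
        peaks = {}
        lat = {}
        for dt in (0.1, 0.05):
            tr = TCModel(ref_params).run_ipsc_protocol(k, dt=dt,
                                                       t_total=6000.0,
                                                       rec_dt=1.0)
            w = (tr.t > 3100) & (tr.t < 6000)
            peaks[dt] = tr.v_soma[w].max()
            lat[dt] = tr.t[w][np.argmax(tr.v_soma[w])]
        assert abs(lat[0.1] - lat[0.05]) < 1.0   # LTS latency stable
        assert abs(peaks[0.1] - peaks[0.05]) < 1.0

    def test_gates_clamped_to_steady_state(self, ref_model):
        """After a long voltage clamp every T gate equals its steady state."""
        n = 30001
        t, v, mt, ht, *_ = ref_model._run(0.1, 3000.0, np.zeros(n),
                                          np.zeros(n), clamp_ms=3000.0,
                                          v_clamp=-70.0, rec_every=100)
        g = gating_steady_taus("IT", v[-1])
        assert np.allclose(mt[-1], g["m_inf"], atol=1e-6)
        assert np.allclose(ht[-1], g["h_inf"], atol=1e-6)

    def test_gates_bounded_through_lts(self, ipsc_traces_200):
        for tr in ipsc_traces_200.values():
            for g in (tr.gates["mT"], tr.gates["hT"]):
                assert np.all((g >= 0.0) & (g <= 1.0))

    def test_trace_export_long_format(self, ipsc_traces_200, tmp_path):
        tr = ipsc_traces_200["Control"]
        df = tr.to_frame()
        assert set(df.columns) == {"t", "compartment", "variable", "value"}
        assert set(df["compartment"].unique()) == {"soma", "dend1", "dend2"}


class TestCurrentPulse:
    def test_zero_amplitude_flat(self, passive_params):
        tr = TCModel(passive_params).run_current_pulse(amplitude_pa=0.0,
                                                       t_total=300.0)
        assert np.ptp(tr.v_soma) < 1e-6

    def test_invalid_width_rejected(self, passive_params):
        with pytest.raises(ValueError):
            TCModel(passive_params).run_current_pulse(width_ms=0.0)
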