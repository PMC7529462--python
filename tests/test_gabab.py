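"""GABA_B conductance waveforms: parameter table, evaluation, manipulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thalburst.gabab import (CONDITIONS, GababKinetics, condition_params,
                             eval_conductance, eval_exp_terms, exp_terms,
                             kinetics_table_from_config, vary_kinetics,
                             waveform_to_csv)


class TestConditionTable:
    def test_control_row(self):
        k = condition_params("Control")
        assert (k.A, k.tau_rise, k.tau_fall_fast, k.tau_fall_slow, k.w) == \
            (16.00, 52.00, 90.10, 1073.20, 0.952)
        assert k.scale == 1.0

    def test_dual_block_row(self):
        k = condition_params("Dual-Block")
        assert (k.A, k.tau_rise, k.tau_fall_fast, k.tau_fall_slow, k.w) == \
            (6.32, 39.88, 65.80, 2600.00, 0.629)

    def test_gat1_differs_from_control_only_in_amplitude(self):
        c = condition_params("Control")
        g1 = condition_params("GAT1-Block")
        assert g1.A == 24.00 and c.A == 16.00
        assert (g1.tau_rise, g1.tau_fall_fast, g1.tau_fall_slow, g1.w) == \
            (c.tau_rise, c.tau_fall_fast, c.tau_fall_slow, c.w)

    def test_unknown_label_lists_valid_conditions(self):
        with pytest.raises(KeyError, match="Control"):
            condition_params("GAT5-Block")

    @pytest.mark.parametrize("field,value", [("tau_rise", -1.0), ("w", 1.5),
                                             ("A", -2.0), ("scale", 0.0)])
    def test_invalid_parameters_rejected(self, field, value):
        kw = dict(A=16.0, tau_rise=52.0, tau_fall_fast=90.1,
                  tau_fall_slow=1073.2, w=0.952)
        kw[field] = value
        with pytest.raises(ValueError):
            GababKinetics(**kw)


class TestEvalConductance:
    def test_zero_at_onset_and_vanishing_at_infinity(self):
        k = condition_params("Control")
        t = np.array([0.0, 1e6])
        g = eval_conductance(k, t, onset=0.0)
        assert g[0] == 0.0
        assert g[1] < 1e-12

    def test_zero_before_onset(self):
        k = condition_params("GAT3-Block")
        t = np.arange(0.0, 500.0, 1.0)
        g = eval_conductance(k, t, onset=300.0)
        assert np.all(g[t <= 300.0] == 0.0)
        assert np.all(g[t > 301.0] > 0.0)

    @pytest.mark.parametrize("cond", CONDITIONS)
    def test_peak_against_dense_grid_search(self, cond):
        # brute-force maximization on a 0.01 ms grid is the oracle
        k = condition_params(cond)
        t = np.arange(0.0, 3000.0, 0.01)
        rise = (1.0 - np.exp(-t / k.tau_rise)) ** 8
        dec = k.w * np.exp(-t / k.tau_fall_fast) + (1 - k.w) * np.exp(-t / k.tau_fall_slow)
        direct = k.A * rise * dec
        g = eval_conductance(k, t)
        assert np.allclose(g, direct, atol=1e-12)
        i = int(np.argmax(direct))
        assert 0.0 < t[i] < 2000.0  # peak after onset, before 2 s
        assert g[i] == pytest.approx(direct.max(), rel=1e-12)

    def test_single_interior_maximum(self):
        for cond in CONDITIONS:
            k = condition_params(cond)
            t = np.arange(0.0, 8000.0, 0.5)
            g = eval_conductance(k, t)
            d = np.diff(g)
            sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-14])) != 0)
            assert sign_changes == 1

    @given(scale=st.floats(0.25, 8.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_linearity(self, scale):
        k = condition_params("Control")
        t = np.arange(0.0, 2000.0, 1.0)
        assert np.allclose(eval_conductance(k.with_scale(scale), t),
                           scale * eval_conductance(k, t))

    def test_nonnegative_everywhere(self):
        k = condition_params("Dual-Block").with_scale(4.0)
        t = np.arange(-100.0, 20000.0, 0.7)
        assert np.all(eval_conductance(k, t, onset=50.0) >= 0.0)


class TestVaryKinetics:
    def test_identity(self):
        k = condition_params("GAT3-Block")
        k2 = vary_kinetics(k, 1.0, 1.0)
        t = np.arange(0.0, 5000.0, 1.0)
        assert np.allclose(eval_conductance(k, t), eval_conductance(k2, t))

    def test_charge_preserved_under_time_rescaling(self):
        k = condition_params("Dual-Block")
        k2 = vary_kinetics(k, time_factor=2.0, preserve_charge=True)
        t = np.arange(0.0, 40.0 * k2.tau_fall_slow, 0.1)
        q1 = np.trapezoid(eval_conductance(k, t), t)
        q2 = np.trapezoid(eval_conductance(k2, t), t)
        assert abs(q2 / q1 - 1.0) < 1e-3

    def test_amp_fixed_time_rescaling_doubles_charge(self):
        k = condition_params("GAT3-Block")
        k2 = vary_kinetics(k, time_factor=2.0)
        t = np.arange(0.0, 40.0 * k2.tau_fall_slow, 0.1)
        q1 = np.trapezoid(eval_conductance(k, t), t)
        q2 = np.trapezoid(eval_conductance(k2, t), t)
        assert abs(q2 / q1 - 2.0) < 0.01

    def test_contradictory_request_rejected(self):
        k = condition_params("Control")
        with pytest.raises(ValueError):
            vary_kinetics(k, time_factor=2.0, amp_factor=1.5,
                          preserve_charge=True)


class TestQ10:
    def test_identity_at_measurement_temperature(self):
        k = condition_params("Control")
        assert k.at_temperature(33.0) == k

    def test_warmer_is_faster(self):
        k = condition_params("Control").at_temperature(37.0)
        ref = condition_params("Control")
        f = 2.1 ** 0.4
        assert k.tau_rise == pytest.approx(ref.tau_rise / f)
        assert k.tau_fall_slow == pytest.approx(ref.tau_fall_slow / f)


class TestExpTerms:
    @pytest.mark.parametrize("cond", CONDITIONS)
    def test_18_terms_reconstruct_waveform(self, cond):
        k = condition_params(cond).with_scale(2.0)
        amps, taus = exp_terms(k)
        assert len(amps) == len(taus) == 18
        t = np.arange(0.0, 8000.0, 0.1)
        direct = eval_conductance(k, t)
        expanded = eval_exp_terms(amps, taus, t)
        scale = max(direct.max(), 1.0)
        assert np.max(np.abs(expanded - direct)) / scale < 1e-9


class TestExternalInterfaces:
    def test_csv_export(self, tmp_path):
        path = tmp_path / "wave.csv"
        waveform_to_csv(condition_params("Control"), path, t_end=100.0)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape[1] == 2 and data[0, 1] == 0.0

    def test_config_round_trip(self, tmp_path):
        import json

        table = {c: {f: getattr(condition_params(c), f) for f in
                     ("A", "tau_rise", "tau_fall_fast", "tau_fall_slow", "w")}
                 for c in CONDITIONS}
        path = tmp_path / "table.json"
        path.write_text(json.dumps(table))
        loaded = kinetics_table_from_config(path)
        assert loaded["GAT3-Block"].tau_fall_fast == 273.40
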