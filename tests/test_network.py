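"""RT-TC networks: synapse kernels, topology, protocols."""

import numpy as np
import pytest

from thalburst import (build_ring_network, build_two_cell, condition_params,
                       gabab_event_kernel, reference_neuron)
from thalburst.gabab import eval_conductance, eval_exp_terms
from thalburst.network import GABAB_EVENT_SCALE, AmpaSpec, RTParams
from thalburst.oscillations import trial_oscillation


@pytest.fixture(scope="module")
def spiking_tc():
    return reference_neuron().with_spiking()


class TestGababEventKernel:
    def test_event_is_one_twelfth_of_template(self):
        k = condition_params("GAT3-Block")
        amps, taus = gabab_event_kernel(k)
        assert len(amps) == 18
        t = np.arange(0.0, 6000.0, 0.1)
        event = eval_exp_terms(amps, taus, t)
        template = eval_conductance(k, t)
        assert event.max() == pytest.approx(template.max() / 12.0, rel=1e-9)
        assert GABAB_EVENT_SCALE == pytest.approx(1.0 / 12.0)

    def test_linearity_of_superposed_events(self):
        # by construction: the conductance of two delayed events equals the
        # sum of shifted single-event kernels
        k = condition_params("Control")
        amps, taus = gabab_event_kernel(k)
        t = np.arange(0.0, 4000.0, 0.5)
        two = eval_exp_terms(amps, taus, t, onset=100.0) \
            + eval_exp_terms(amps, taus, t, onset=150.0)
        one_a = eval_exp_terms(amps, taus, t, onset=100.0)
        one_b = eval_exp_terms(amps, taus, t, onset=150.0)
        assert np.allclose(two, one_a + one_b)


class TestTopology:
    def test_ring_fan_in_and_out(self):
        net = build_ring_network([reference_neuron()],
                                 condition_params("Control"), n_cells=100)
        assert net.rt_targets.shape == (100, 9)
        assert net.tc_targets.shape == (100, 5)
        # every TC receives exactly 9 inhibitory afferents
        counts = np.bincount(net.rt_targets.ravel(), minlength=100)
        assert np.all(counts == 9)
        counts = np.bincount(net.tc_targets.ravel(), minlength=100)
        assert np.all(counts == 5)

    def test_rt0_inhibits_wrapped_neighborhood(self):
        net = build_ring_network([reference_neuron()],
                                 condition_params("Control"), n_cells=100)
        assert set(net.rt_targets[0]) == {96, 97, 98, 99, 0, 1, 2, 3, 4}

    def test_center_stimulus_cells(self):
        net = build_ring_network([reference_neuron()],
                                 condition_params("Control"), n_cells=100)
        assert list(net.stim_cells) == list(range(40, 60))

    def test_heterogeneous_build_deterministic(self):
        pool = [reference_neuron(), reference_neuron().with_spiking()]
        n1 = build_ring_network(pool, condition_params("Control"), n_cells=20,
                                heterogeneous=True, seed=5)
        n2 = build_ring_network(pool, condition_params("Control"), n_cells=20,
                                heterogeneous=True, seed=5)
        assert [p.gbar_na for p in n1.tc_params] == \
            [p.gbar_na for p in n2.tc_params]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            build_ring_network([], condition_params("Control"))


class TestTwoCell:
    def test_silenced_synapses_no_tc_spikes(self, spiking_tc):
        net = build_two_cell(spiking_tc, condition_params("GAT3-Block"))
        res = net.run(-65.0, seed=1, t_total=6000.0, silence_synapses=True,
                      randomize_leak=False)
        sc, st = res["spike_cell"], res["spike_t"]
        assert np.sum(sc == 0) == 0            # TC silent when disconnected
        assert np.sum((sc == 1) & (st >= 3000.0)) >= 8  # RT still bursts

    def test_rt_burst_evokes_template_like_conductance(self, spiking_tc):
        """The synaptically evoked GABA_B conductance approximates the
        corresponding dynamic-clamp template (burst of ~12 spikes at 1/12
        amplitude each)."""
        k = condition_params("GAT3-Block")
        net = build_two_cell(spiking_tc, k)
        res = net.run(-65.0, seed=1, t_total=9000.0, randomize_leak=False)
        st = res["spike_t"][res["spike_cell"] == 1]
        burst = st[(st >= 3000.0) & (st <= 3200.0)]
        g = res["gb_rec"][:, 0]
        t = np.arange(len(g)) * res["rec_dt"]
        # superposition oracle: sum of 1/12 kernels at the spike times
        amps, taus = gabab_event_kernel(k)
        manual = np.zeros_like(g)
        for ts in st:
            manual += eval_exp_terms(amps, taus, t, onset=ts + 1.0)
        # agreement to the 0.1 ms event-timing quantization of the engine
        assert np.max(np.abs(g - manual)) < 2e-3 * max(1.0, manual.max())
        # burst-summed peak within ~40 % of the template peak
        template_peak = eval_conductance(k, np.arange(0, 4000.0, 0.5)).max()
        w = (t >= 3000.0) & (t <= 7000.0)
        assert g[w].max() == pytest.approx(template_peak,
                                           rel=0.5 + abs(len(burst) - 12) / 12)

    def test_gat3_oscillates_dual_does_not(self, spiking_tc):
        out = {}
        for cond in ("GAT3-Block", "Dual-Block"):
            net = build_two_cell(spiking_tc, condition_params(cond))
            res = net.run(-69.0, seed=3, t_total=15000.0, randomize_leak=False)
            st = res["spike_t"]
            tr = trial_oscillation(st[st >= res["stim_end"]], res["stim_end"])
            out[cond] = tr
        assert out["GAT3-Block"]["oscillated"]
        assert not out["Dual-Block"]["oscillated"]

    def test_cycles_led_by_tc_rebound_bursts(self, spiking_tc):
        """Each oscillation cycle contains a TC rebound burst preceding the
        next RT burst."""
        net = build_two_cell(spiking_tc, condition_params("GAT3-Block"))
        res = net.run(-69.0, seed=3, t_total=12000.0, randomize_leak=False)
        sc, st = res["spike_cell"], res["spike_t"]
        rt = np.sort(st[(sc == 1) & (st > 3200.0)])
        tc = np.sort(st[(sc == 0) & (st > 3200.0)])
        # group RT spikes into bursts by >100 ms gaps
        bursts = np.split(rt, np.flatnonzero(np.diff(rt) > 100.0) + 1)
        led = sum(1 for b in bursts if b.size and
                  np.any((tc < b[0]) & (tc > b[0] - 120.0)))
        assert led >= max(1, len(bursts) - 1)

    def test_seeded_determinism(self, spiking_tc):
        net = build_two_cell(spiking_tc, condition_params("GAT1-Block"))
        r1 = net.run(-67.0, seed=9, t_total=8000.0)
        r2 = net.run(-67.0, seed=9, t_total=8000.0)
        assert np.array_equal(r1["spike_t"], r2["spike_t"])
        assert np.array_equal(r1["spike_cell"], r2["spike_cell"])

    def test_leak_reversal_outside_protocol_rejected(self, spiking_tc):
        net = build_two_cell(spiking_tc, condition_params("Control"))
        with pytest.raises(ValueError):
            net.run(-80.0, seed=0)


class TestRingNetwork:
    def test_small_ring_oscillates_under_gat3(self, spiking_tc):
        net = build_ring_network([spiking_tc], condition_params("GAT3-Block"),
                                 n_cells=20, seed=2)
        res = net.run(-65.0, seed=2, t_total=12000.0)
        st = res["spike_t"]
        tr = trial_oscillation(st[st >= res["stim_end"]], res["stim_end"])
        assert tr["n_bursts"] >= 3

    def test_discrepancy_tracked_per_tc_cell(self, spiking_tc):
        net = build_ring_network([spiking_tc], condition_params("GAT3-Block"),
                                 n_cells=20, seed=2)
        res = net.run(-65.0, seed=2, t_total=9000.0)
        assert res["max_disc"].shape == (20,)
        assert np.any(res["max_disc"] > 1e-2)  # oscillating cells pass threshold
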