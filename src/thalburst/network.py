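"""RT-TC network construction and simulation.

Two-cell and ring networks couple single-compartment reticular thalamic (RT)
neurons to three-compartment thalamocortical (TC) neurons: RT inhibits TC
through GABA_B receptors (the IPSC waveform expanded into 18 pure
exponentials so that overlapping events sum linearly, per-event amplitude
1/12 of the dynamic-clamp template) and TC excites RT through biexponential
AMPA synapses (0.5 ms rise, 5.6 ms decay, 7 nS).  Spikes are threshold
crossings at -30 mV with a 1 ms transmission delay and release probability 1.

In the ring topology each RT neuron inhibits the nine nearest TC cells
(offsets -4..+4, wrapped) and each TC neuron excites the five nearest RT
cells (offsets -2..+2); oscillations are evoked by a 0.2 nA / 40 ms pulse
into the center fifth of the RT layer after 3 s of stabilization, across a
grid of leak reversal potentials (-73..-60 mV) and leak-randomized trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import engine
from .channels import IonConditions, PARAMS
from .gabab import GababKinetics, exp_terms
from .neuron import CM, E_GABA, TCNeuronParams
from .oscillations import network_metrics, trial_oscillation

__all__ = ["AmpaSpec", "SynapseSpec", "RTParams", "Network",
           "build_two_cell", "build_ring_network", "gabab_event_kernel",
           "run_network_protocol"]

#: conductance scale of one synaptic GABA_B event relative to the
#: dynamic-clamp template (temporal summation over an RT burst restores it)
GABAB_EVENT_SCALE = 1.0 / 12.0
SPIKE_THRESHOLD = -30.0  # mV
DELAY_MS = 1.0


@dataclass(frozen=True)
class AmpaSpec:
    tau_rise: float = 0.5    # ms
    tau_decay: float = 5.6   # ms
    g_max: float = 7.0       # nS per synapse
    e_rev: float = 0.0       # mV

    @property
    def peak_norm(self) -> float:
        """Amplitude making the biexponential difference peak at g_max."""
        tr, td = self.tau_rise, self.tau_decay
        tp = np.log(td / tr) * tr * td / (td - tr)
        return self.g_max / (np.exp(-tp / td) - np.exp(-tp / tr))


@dataclass(frozen=True)
class SynapseSpec:
    """GABA_B synapse built from one IPSC waveform parameter set."""

    kinetics: GababKinetics
    event_scale: float = GABAB_EVENT_SCALE
    e_rev: float = E_GABA


@dataclass(frozen=True)
class RTParams:
    """Single-compartment reticular thalamic neuron.

    Fast Na/K spiking currents, the reticular T-type calcium current (GHK)
    and leak; geometry a cylinder with length = diameter.  Densities are the
    package's frozen calibration of the cited single-compartment RT model
    (burst of ~a dozen spikes to a 0.2 nA / 40 ms pulse).
    """

    diam: float = 70.0         # um, cylinder length = diameter
    g_pas: float = 5.0e-5      # S/cm^2 (randomized 4.5e-5..5.5e-5 in trials)
    e_pas: float = -85.0       # mV
    pbar_T: float = 2.0e-4     # cm/s
    gbar_na: float = 0.1       # S/cm^2
    gbar_k: float = 0.08       # S/cm^2
    cm: float = 1.0            # uF/cm^2

    @property
    def area(self) -> float:
        return float(np.pi * self.diam ** 2 * 1e-8)  # cm^2


def gabab_event_kernel(k: GababKinetics,
                       event_scale: float = GABAB_EVENT_SCALE):
    """18-term exponential representation of one synaptic GABA_B event.

    Returns (amplitudes_nS, taus_ms); the amplitudes already include the
    per-event 1/12 scale so that summing over a typical RT burst reproduces
    the dynamic-clamp template.
    """
    amps, taus = exp_terms(k)
    return amps * event_scale, taus


@dataclass
class Network:
    """Assembled RT-TC network ready for simulation."""

    tc_params: list
    rt_params: RTParams
    syn: SynapseSpec
    ampa: AmpaSpec
    rt_targets: np.ndarray     # (n_rt, fan_out) TC indices
    tc_targets: np.ndarray     # (n_tc, fan_out) RT indices
    stim_cells: np.ndarray     # RT indices receiving the stimulus
    topology: str = "ring"
    seed: int = 0

    @property
    def n_tc(self) -> int:
        return len(self.tc_params)

    @property
    def n_rt(self) -> int:
        return 1 if self.rt_targets.ndim == 1 else self.rt_targets.shape[0]

    def run(self, e_pas_leak: float, seed: int, t_total: float = 30000.0,
            dt: float = 0.1, stim_start: float = 3000.0,
            stim_amp_na: float = 0.2, stim_dur: float = 40.0,
            rec_dt: float = 1.0, randomize_leak: bool = True,
            disc_window: tuple = (2000.0, 3000.0), silence_synapses=False):
        """One trial: leak randomization, stimulation, spike collection.

        ``e_pas_leak`` replaces the TC leak reversal (and initial V) for the
        trial; RT leak density is drawn U(45, 55) uS/cm^2 and TC leak density
        jittered +-10 % when ``randomize_leak``.  Returns a dict with spike
        times, per-TC max open-probability discrepancy inside ``disc_window``
        (relative to stimulation start), and sampled traces.
        """
        if not -73.0 <= e_pas_leak <= -60.0:
            raise ValueError("leak reversal outside the protocol range")
        rng = np.random.default_rng(seed)
        n_tc, n_rt = self.n_tc, max(1, self.rt_targets.shape[0])
        areas = np.stack([p.areas for p in self.tc_params])
        g12 = np.array([p.axial_conductances[0] for p in self.tc_params])
        g23 = np.array([p.axial_conductances[1] for p in self.tc_params])
        gpas_tc = np.array([p.g_pas for p in self.tc_params])
        if randomize_leak:
            gpas_tc = gpas_tc * rng.uniform(0.9, 1.1, n_tc)
        epas_tc = np.full(n_tc, e_pas_leak)
        dens = np.stack([p.densities for p in self.tc_params])
        gna_tc = np.array([p.gbar_na for p in self.tc_params])
        gk_tc = np.array([p.gbar_k for p in self.tc_params])
        rt = self.rt_params
        area_rt = np.full(n_rt, rt.area)
        gpas_rt = (rng.uniform(4.5e-5, 5.5e-5, n_rt) if randomize_leak
                   else np.full(n_rt, rt.g_pas))
        amps18, taus18 = gabab_event_kernel(self.syn.kinetics,
                                            self.syn.event_scale)
        dec18 = np.exp(-dt / taus18)
        ampa_amp = 0.0 if silence_synapses else self.ampa.peak_norm
        g_amps18 = np.zeros_like(amps18) if silence_synapses else amps18
        chan = engine.build_chan_vec(IonConditions().temperature)
        n_steps = int(round(t_total / dt))
        nk = PARAMS["NaK_spk"]
        out = engine.run_network(
            dt, n_steps, areas, g12, g23, CM, gpas_tc, epas_tc, dens,
            gna_tc, gk_tc, nk["vtraub_tc"],
            area_rt, gpas_rt, rt.e_pas, rt.pbar_T, rt.gbar_na, rt.gbar_k,
            nk["vtraub_rt"], rt.cm, chan,
            self.rt_targets, g_amps18, dec18, self.tc_targets,
            ampa_amp, np.exp(-dt / self.ampa.tau_rise),
            np.exp(-dt / self.ampa.tau_decay),
            int(round(DELAY_MS / dt)), self.syn.e_rev,
            self.stim_cells.astype(np.int64),
            int(round(stim_start / dt)),
            int(round((stim_start + stim_dur) / dt)), stim_amp_na,
            int(round((stim_start + disc_window[0]) / dt)),
            int(round((stim_start + disc_window[1]) / dt)),
            max(1, int(round(rec_dt / dt))), 2_000_000)
        spike_cell, spike_t, max_disc, v_rec, gb_rec = out
        return {"spike_cell": spike_cell, "spike_t": spike_t,
                "max_disc": max_disc, "v_rec": v_rec, "gb_rec": gb_rec,
                "rec_dt": rec_dt, "n_tc": n_tc, "n_rt": n_rt,
                "stim_start": stim_start, "stim_end": stim_start + stim_dur,
                "e_pas_leak": e_pas_leak, "seed": seed}


def build_two_cell(tc_params: TCNeuronParams, kinetics: GababKinetics,
                   rt_params: RTParams | None = None, seed: int = 0,
                   ampa: AmpaSpec | None = None) -> Network:
    """One RT neuron reciprocally coupled to one TC neuron
    (RT->TC GABA_B only; TC->RT AMPA only)."""
    return Network(
        tc_params=[tc_params], rt_params=rt_params or RTParams(),
        syn=SynapseSpec(kinetics=kinetics), ampa=ampa or AmpaSpec(),
        rt_targets=np.array([[0]], dtype=np.int64),
        tc_targets=np.array([[0]], dtype=np.int64),
        stim_cells=np.array([0], dtype=np.int64),
        topology="two_cell", seed=seed)


def _ring_offsets(n: int, fan_out: int) -> np.ndarray:
    half = fan_out // 2
    return np.arange(-half, half + 1)


def build_ring_network(tc_pool: list, kinetics: GababKinetics,
                       n_cells: int = 100, heterogeneous: bool = False,
                       rt_params: RTParams | None = None, seed: int = 0,
                       rt_fan_out: int = 9, tc_fan_out: int = 5,
                       stim_fraction: float = 0.2,
                       ampa: AmpaSpec | None = None) -> Network:
    """Bilayer ring: ``n_cells`` RT + ``n_cells`` TC neurons.

    TC identities come from ``tc_pool``: homogeneous networks repeat a single
    pool entry; heterogeneous networks cycle the pool in seeded random order.
    RT cell i inhibits TC cells i-4..i+4 (mod n); TC cell i excites RT cells
    i-2..i+2.  The stimulus targets the centered ``stim_fraction`` of the RT
    layer (cells 40-59 at n = 100).
    """
    if len(tc_pool) < 1:
        raise ValueError("tc_pool must hold at least one parameter set")
    rng = np.random.default_rng(seed)
    if heterogeneous:
        order = rng.permutation(len(tc_pool))
        tc_params = [tc_pool[order[i % len(tc_pool)]] for i in range(n_cells)]
    else:
        tc_params = [tc_pool[0]] * n_cells
    rt_targets = np.stack([(i + _ring_offsets(n_cells, rt_fan_out)) % n_cells
                           for i in range(n_cells)]).astype(np.int64)
    tc_targets = np.stack([(i + _ring_offsets(n_cells, tc_fan_out)) % n_cells
                           for i in range(n_cells)]).astype(np.int64)
    n_stim = max(1, int(round(stim_fraction * n_cells)))
    start = (n_cells - n_stim) // 2
    stim_cells = np.arange(start, start + n_stim, dtype=np.int64)
    return Network(tc_params=tc_params, rt_params=rt_params or RTParams(),
                   syn=SynapseSpec(kinetics=kinetics), ampa=ampa or AmpaSpec(),
                   rt_targets=rt_targets, tc_targets=tc_targets,
                   stim_cells=stim_cells, topology="ring", seed=seed)


def run_network_protocol(network: Network, e_pas_values=None, n_trials: int = 5,
                         seed: int = 0, t_total: float = 30000.0,
                         quiescence_check: bool = True, **run_kwargs):
    """Sweep leak reversal potentials x randomized-leak trials.

    Returns ``(OscillationMetrics, per-trial records)``; each record carries
    the trial's oscillation summary, the quiescence flag (no spikes before
    stimulation), and the max TC open-probability discrepancy.
    """
    if e_pas_values is None:
        e_pas_values = np.arange(-73.0, -59.5, 1.0)
    trials, first_spikes, records = [], [], []
    ss = np.random.SeedSequence([seed, network.seed])
    trial_seeds = ss.generate_state(len(e_pas_values) * n_trials)
    i = 0
    stim_end = 0.0
    for e_pas in e_pas_values:
        for _ in range(n_trials):
            res = network.run(float(e_pas), int(trial_seeds[i] % (2 ** 31)),
                              t_total=t_total, **run_kwargs)
            i += 1
            stim_end = res["stim_end"]
            post = res["spike_t"] >= stim_end
            tr = trial_oscillation(res["spike_t"][post], stim_end)
            quiescent = not np.any(res["spike_t"] < res["stim_start"])
            tc_mask = (res["spike_cell"] < res["n_tc"]) & post
            fs = []
            for c in np.unique(res["spike_cell"][tc_mask]):
                fs.append(res["spike_t"][tc_mask][res["spike_cell"][tc_mask] == c].min())
            trials.append(tr)
            first_spikes.append(np.asarray(fs))
            records.append({**tr, "quiescent": quiescent,
                            "e_pas_leak": float(e_pas),
                            "max_disc": res["max_disc"].max(),
                            "n_spikes": int(res["spike_t"].size)})
    metrics = network_metrics(trials, first_spikes, network.n_tc, stim_end)
    return metrics, records
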