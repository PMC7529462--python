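"""Synthetic ground-truth data generators.

Stand-ins for the slice recordings: every generator is seeded, labelled
synthetic, and returns a machine-readable ground-truth sidecar next to the
raw traces so that downstream detection and estimation can be scored against
known answers.

Generators and what they emulate
--------------------------------
* :func:`synth_mua_recording` — extracellular multiunit sweeps with
  stimulus-locked, decaying burst oscillations (~500 ms period, 2-13 s
  duration) in band-limited noise.
* :func:`synth_mua_experiment` — a drug-perfusion time course: baseline and
  drug phases whose programmed duration/period effects follow the reported
  transporter-blockade effect sizes (defaults: duration +36 % GAT1-Block,
  +99 % GAT3-Block, -48 % Dual-Block; period +13 % / +32 %).
* :func:`synth_passive_sweeps` — whole-cell current-pulse responses from
  known passive three-compartment parameters (plus optional noise and
  injected bridge offsets).
* :func:`synth_dynamic_clamp_dataset` — dynamic-clamp-style voltage sweeps
  over the condition x amplitude-scale x holding-potential grid, generated
  from a known model neuron with colored (OU) voltage noise; LTS truth
  labels come from the noiseless runs.
* :func:`synth_model_population` — a heterogeneous cohort of model TC
  neurons emulating the well-fitted cohort's structure (dendritic T density
  above somatic, somatic A-type density high).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .gabab import CONDITIONS, condition_params
from .lts import analyze_sweep
from .neuron import TCModel, TCNeuronParams, reference_neuron

__all__ = ["ou_noise", "synth_mua_recording", "synth_mua_experiment",
           "synth_passive_sweeps", "synth_dynamic_clamp_dataset",
           "synth_model_population", "DRUG_EFFECTS"]

#: Programmed mean multiplicative effects of each perfusion condition on
#: oscillation duration and period (the study conditions the MUA generator
#: emulates).
DRUG_EFFECTS = {
    "Control": {"duration": 1.00, "period": 1.00},
    "GAT1-Block": {"duration": 1.36, "period": 1.13},
    "GAT3-Block": {"duration": 1.99, "period": 1.32},
    "Dual-Block": {"duration": 0.52, "period": 1.00},
}


def ou_noise(rng, n: int, dt: float, sigma: float, tau: float = 5.0) -> np.ndarray:
    """Ornstein-Uhlenbeck (colored) noise with stationary SD ``sigma``."""
    if sigma == 0:
        return np.zeros(n)
    x = np.empty(n)
    a = np.exp(-dt / tau)
    s = sigma * np.sqrt(1.0 - a * a)
    x[0] = rng.normal(0.0, sigma)
    w = rng.normal(0.0, s, n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + w[i - 1]
    return x


def _spike_waveform(dt: float, amp: float = 1.0, f_khz: float = 0.5):
    """Stereotyped biphasic extracellular spike: a Gaussian-windowed 500 Hz
    cycle, band-limited to the detection passband (minimal filter ringing)."""
    t = np.arange(-2.5, 2.5 + dt, dt)
    w = np.sin(2 * np.pi * f_khz * t) * np.exp(-0.5 * (t / 0.7) ** 2)
    return amp * w / np.abs(w).max()


def synth_mua_recording(seed: int = 0, n_sweeps: int = 5,
                        duration_ms: float = 5000.0, period_ms: float = 500.0,
                        jitter_ms: float = 20.0, spikes_per_burst: int = 15,
                        noise: float = 0.05, spike_amp: float = 1.0,
                        stim_start: float = 1000.0, sweep_ms: float = 16000.0,
                        dt: float = 0.2):
    """Multiunit sweeps with stimulus-locked decaying burst oscillations.

    Bursts recur every ``period_ms`` (Gaussian onset jitter) until
    ``duration_ms`` after the stimulus, each holding ``spikes_per_burst``
    spikes at 6 ms spacing with slow within-oscillation amplitude decay, on
    white noise of SD ``noise`` (spike amplitude 1).  Returns
    ``(t, sweeps, truth)``; truth carries per-sweep spike/burst times and
    the programmed duration and period.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, sweep_ms, dt)
    kernel = _spike_waveform(dt, spike_amp)
    half = len(kernel) // 2
    sweeps, truth_spikes, truth_bursts = [], [], []
    for _ in range(n_sweeps):
        v = rng.normal(0.0, noise, len(t))
        spikes, bursts = [], []
        n_bursts = int(np.floor(duration_ms / period_ms)) + 1
        for b in range(n_bursts):
            onset = stim_start + b * period_ms + (rng.normal(0, jitter_ms) if b else 30.0)
            if onset - stim_start > duration_ms:
                continue
            bursts.append(onset)
            decay = np.exp(-b / max(n_bursts, 1) / 0.7)
            for k in range(spikes_per_burst):
                ts = onset + 6.0 * k + rng.uniform(-0.5, 0.5)
                idx = int(round(ts / dt))
                if half < idx < len(t) - half:
                    v[idx - half: idx - half + len(kernel)] += kernel * decay \
                        * (0.8 + 0.4 * rng.random())
                    spikes.append(ts)
        sweeps.append(v)
        truth_spikes.append(np.asarray(spikes))
        truth_bursts.append(np.asarray(bursts))
    realized = [float(s[-1] - stim_start) if len(s) else 0.0
                for s in truth_spikes]
    truth = {"spike_times": truth_spikes, "burst_onsets": truth_bursts,
             "duration_ms": duration_ms, "period_ms": period_ms,
             "realized_duration_ms": realized,
             "stim_start": stim_start, "seed": seed}
    return t, sweeps, truth


def synth_mua_experiment(condition: str, seed: int = 0, n_slices: int = 8,
                         sweeps_per_phase: int = 10,
                         baseline_duration_range=(2000.0, 6000.0),
                         baseline_period: float = 500.0,
                         slice_sd: float = 0.05, **mua_kwargs):
    """Per-slice baseline and drug phases with programmed effect sizes.

    Each synthetic slice draws a baseline oscillation duration in the 2-13 s
    experimental range and applies the condition's multiplicative effect
    (log-normal slice-to-slice scatter, SD ``slice_sd``) in the drug phase.
    Returns a list of slice records with raw sweeps for both phases plus the
    programmed truth.
    """
    if condition not in DRUG_EFFECTS:
        raise KeyError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    eff = DRUG_EFFECTS[condition]
    out = []
    for s in range(n_slices):
        base_dur = rng.uniform(*baseline_duration_range)
        dur_fac = eff["duration"] * rng.lognormal(0.0, slice_sd)
        per_fac = eff["period"] * rng.lognormal(0.0, slice_sd / 2)
        drug_dur = min(base_dur * dur_fac, 13000.0)
        drug_per = baseline_period * per_fac
        sub = rng.integers(0, 2 ** 31)
        t, base_sweeps, bt = synth_mua_recording(
            seed=int(sub), n_sweeps=sweeps_per_phase, duration_ms=base_dur,
            period_ms=baseline_period, **mua_kwargs)
        t, drug_sweeps, dtr = synth_mua_recording(
            seed=int(sub) + 1, n_sweeps=sweeps_per_phase, duration_ms=drug_dur,
            period_ms=drug_per, **mua_kwargs)
        out.append({"slice": s, "condition": condition, "t": t,
                    "baseline": base_sweeps, "drug": drug_sweeps,
                    "truth": {"baseline_duration": base_dur,
                              "drug_duration": drug_dur,
                              "baseline_period": baseline_period,
                              "drug_period": drug_per,
                              "realized_baseline_duration":
                                  float(np.mean(bt["realized_duration_ms"])),
                              "realized_drug_duration":
                                  float(np.mean(dtr["realized_duration_ms"])),
                              "stim_start": bt["stim_start"]}})
    return out


def synth_passive_sweeps(seed: int = 0, n_neurons: int = 5, n_reps: int = 3,
                         noise: float = 0.0, bridge_offset_mv: float = 0.0,
                         l_range=(0.1, 1.5), t_total: float = 600.0):
    """Current-pulse responses from known passive geometries.

    Geometries are drawn so the electrotonic length spans ``l_range``.
    Optional OU voltage noise and an instantaneous bridge offset during the
    pulse.  Returns records with (t, sweeps, true params).
    """
    rng = np.random.default_rng(seed)
    out = []
    tries = 0
    while len(out) < n_neurons and tries < 50 * n_neurons:
        tries += 1
        p = TCNeuronParams(
            diam_soma=rng.uniform(18, 42), diam_dend=rng.uniform(2, 9),
            l_dend=rng.uniform(150, 800), g_pas=10 ** rng.uniform(-4.6, -3.6),
            name=f"synthetic_passive_{len(out)}")
        lam = np.sqrt((p.diam_dend * 1e-4) * (p.g_pas ** -1) / (4 * 173.0))
        L = (p.l_dend * 1e-4) / lam
        if not l_range[0] <= L <= l_range[1]:
            continue
        tr = TCModel(p).run_current_pulse(amplitude_pa=-50.0, width_ms=10.0,
                                          v_hold=-70.0, t_total=t_total)
        sweeps = []
        i_on = int(np.searchsorted(tr.t, 100.0))
        i_off = int(np.searchsorted(tr.t, 110.0))
        for rep in range(n_reps):
            v = tr.v_soma.copy()
            if noise > 0:
                v = v + ou_noise(rng, len(v), tr.dt, noise)
            if bridge_offset_mv and rep % 2 == 0:
                # offset alternate repetitions so the slope histogram holds
                # both clean and bridge-affected sweeps
                v[i_on:i_off] += bridge_offset_mv
            sweeps.append(v)
        out.append({"t": tr.t, "sweeps": sweeps, "true_params": p,
                    "electrotonic_length": float(L),
                    "pulse_onset": 100.0, "pulse_width": 10.0, "i_p": 50.0})
    return out


def synth_dynamic_clamp_dataset(seed: int = 0,
                                generator: TCNeuronParams | None = None,
                                scales=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
                                holds=(-60.0, -65.0, -70.0), n_reps: int = 5,
                                noise: float = 0.3, conditions=CONDITIONS,
                                t_total: float = 10000.0, rec_dt: float = 1.0):
    """Dynamic-clamp-style sweeps over condition x scale x hold x repetition.

    Noiseless simulations of the generator neuron define the ground-truth
    LTS labels; each repetition adds independent OU voltage noise.  Returns
    a DataFrame sidecar (one row per sweep) and the raw sweep list.
    """
    rng = np.random.default_rng(seed)
    generator = generator or reference_neuron()
    model = TCModel(generator)
    rows, raw = [], []
    for cond in conditions:
        for scale in scales:
            k = condition_params(cond).with_scale(scale)
            for hold in holds:
                tr = model.run_ipsc_protocol(k, v_hold=hold, t_total=t_total,
                                             rec_dt=rec_dt)
                res0 = analyze_sweep(tr.t, tr.v_soma, tr.ipsc_onset, tr.g_syn)
                for rep in range(n_reps):
                    v = tr.v_soma + ou_noise(rng, len(tr.t), tr.dt, noise)
                    raw.append({"t": tr.t, "v": v, "g_syn": tr.g_syn,
                                "trace": tr})
                    rows.append({"condition": cond, "scale": scale,
                                 "v_hold": hold, "rep": rep,
                                 "sweep": len(raw) - 1,
                                 "true_has_lts": res0.has_lts,
                                 "true_has_burst": res0.has_burst,
                                 "true_latency": res0.latency,
                                 "true_peak_value": res0.peak_value,
                                 "ipsc_onset": tr.ipsc_onset})
    return pd.DataFrame(rows), raw


def synth_model_population(seed: int = 0, n: int = 24,
                           base: TCNeuronParams | None = None):
    """Heterogeneous cohort of model TC neurons around the reference set.

    Densities are drawn log-uniformly within documented ranges with the two
    cohort orderings enforced: dendritic T-channel density above somatic,
    and somatic A-type density high (above dendritic).  Geometry and leak
    get moderate jitter.  Seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    base = base or reference_neuron()
    cohort = []
    for i in range(n):
        dens = base.densities.copy()
        pt_d = base.densities[2, 0] * 10 ** rng.uniform(-0.25, 0.08)
        pt_s = min(base.densities[0, 0] * 10 ** rng.uniform(-0.3, 0.1),
                   0.9 * pt_d)
        ga_s = base.densities[0, 2] * 10 ** rng.uniform(-0.2, 0.3)
        ga_d = min(base.densities[1, 2] * 10 ** rng.uniform(-0.3, 0.3),
                   0.9 * ga_s)
        dens[0, 0] = pt_s
        dens[1, 0] = dens[2, 0] = pt_d
        dens[0, 2] = ga_s
        dens[1, 2] = dens[2, 2] = ga_d
        for col in (1, 3, 4):  # gbar_h, gbar_Kir, gbar_NaP
            dens[:, col] = base.densities[:, col] * 10 ** rng.uniform(-0.3, 0.3)
        p = replace(
            base,
            diam_soma=base.diam_soma * rng.uniform(0.85, 1.15),
            diam_dend=base.diam_dend * rng.uniform(0.85, 1.15),
            l_dend=base.l_dend * rng.uniform(0.85, 1.15),
            g_pas=base.g_pas * 10 ** rng.uniform(-0.05, 0.18),
            densities=dens, name=f"synthetic_cohort_{i}")
        cohort.append(p)
    return cohort
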