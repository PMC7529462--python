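"""Compiled time-stepping engine for single-neuron and network simulations.

Voltage is advanced with a linearized implicit (backward-Euler) update —
ionic currents are expanded to first order around the present voltage with
gates frozen at their freshly updated values, and the resulting per-cell
tridiagonal system is solved exactly — while gates follow staggered analytic
exponential updates toward their voltage-dependent steady states.  This
mirrors the stability behaviour of standard compartmental simulators at the
default 0.1 ms step.

Units: mV, ms, nA, uS (point conductances handled in nS at the surface),
mA/cm^2 for densities, cm^2 for areas, mM for calcium.

All kernels are ``numba.njit``-compiled; parameters arrive as flat float64
arrays built by :func:`build_chan_vec` from the frozen kinetics file.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import channels as _ch

__all__ = ["build_chan_vec", "run_single_tc", "run_network"]

# chan vector layout
(I_IT_SHIFT, I_IT_MV, I_IT_MS, I_IT_HV, I_IT_HS, I_IT_PHIM, I_IT_PHIH,
 I_IH_V, I_IH_S, I_IH_E,
 I_IA_PHI,
 I_KIR_V, I_KIR_S,
 I_NAP_V, I_NAP_S,
 I_NAK_TADJ,
 I_CA_DEPTH, I_CA_TAU, I_CA_REST,
 I_EK, I_ENA, I_CAO, I_XFAC,
 I_RT_MV, I_RT_MS, I_RT_HV, I_RT_HS, I_RT_PHIM, I_RT_PHIH,
 N_CHAN) = range(30)


def build_chan_vec(temperature: float | None = None) -> np.ndarray:
    """Pack the frozen channel kinetics into the engine's parameter vector."""
    P = _ch.PARAMS
    if temperature is None:
        temperature = P["ions"]["temperature"]
    c = np.zeros(N_CHAN)
    it = P["IT"]
    c[I_IT_SHIFT] = it["shift"]
    c[I_IT_MV], c[I_IT_MS] = it["m_vhalf"], it["m_slope"]
    c[I_IT_HV], c[I_IT_HS] = it["h_vhalf"], it["h_slope"]
    c[I_IT_PHIM] = it["q10_m"] ** ((temperature - it["t_ref"]) / 10.0)
    c[I_IT_PHIH] = it["q10_h"] ** ((temperature - it["t_ref"]) / 10.0)
    ih = P["Ih"]
    c[I_IH_V], c[I_IH_S], c[I_IH_E] = ih["vhalf"], ih["slope"], ih["e_rev"]
    ia = P["Ia"]
    c[I_IA_PHI] = ia["q10"] ** ((temperature - ia["t_ref"]) / 10.0)
    c[I_KIR_V], c[I_KIR_S] = P["IKir"]["vhalf"], P["IKir"]["slope"]
    c[I_NAP_V], c[I_NAP_S] = P["INaP"]["vhalf"], P["INaP"]["slope"]
    nk = P["NaK_spk"]
    c[I_NAK_TADJ] = nk["q10"] ** ((temperature - nk["t_ref"]) / 10.0)
    cad = P["Cadecay"]
    c[I_CA_DEPTH], c[I_CA_TAU], c[I_CA_REST] = cad["depth_um"], cad["tau_ms"], cad["ca_rest_mM"]
    ions = P["ions"]
    c[I_EK], c[I_ENA], c[I_CAO] = ions["e_k"], ions["e_na"], ions["cao_mM"]
    c[I_XFAC] = 2.0 * _ch.FARADAY * 1e-3 / (_ch.GAS_CONSTANT * (temperature + 273.15))
    rt = P["IT_RT"]
    c[I_RT_MV], c[I_RT_MS] = rt["m_vhalf"], rt["m_slope"]
    c[I_RT_HV], c[I_RT_HS] = rt["h_vhalf"], rt["h_slope"]
    c[I_RT_PHIM] = rt["q10_m"] ** ((temperature - rt["t_ref"]) / 10.0)
    c[I_RT_PHIH] = rt["q10_h"] ** ((temperature - rt["t_ref"]) / 10.0)
    return c


# ---------------------------------------------------------------------------
# njit kinetics helpers


@njit(cache=True, fastmath=False)
def _efun(x):
    if abs(x) < 1e-9:
        return 1.0 - x / 2.0 + x * x / 12.0
    return x / (math.exp(x) - 1.0)


@njit(cache=True)
def _ghk(v, cai, cao, xfac):
    x = xfac * v
    return 1e-3 * 2.0 * _ch_FARADAY * (cai * _efun(-x) - cao * _efun(x))


_ch_FARADAY = _ch.FARADAY


@njit(cache=True)
def _it_inf_tau(v, chan):
    vs = v + chan[I_IT_SHIFT]
    minf = 1.0 / (1.0 + math.exp(-(vs - chan[I_IT_MV]) / chan[I_IT_MS]))
    hinf = 1.0 / (1.0 + math.exp((vs - chan[I_IT_HV]) / chan[I_IT_HS]))
    taum = (0.612 + 1.0 / (math.exp(-(vs + 132.0) / 16.7)
                           + math.exp((vs + 16.8) / 18.2))) / chan[I_IT_PHIM]
    if vs < -80.0:
        tauh = math.exp((vs + 467.0) / 66.6) / chan[I_IT_PHIH]
    else:
        tauh = (28.0 + math.exp(-(vs + 22.0) / 10.5)) / chan[I_IT_PHIH]
    return minf, taum, hinf, tauh


@njit(cache=True)
def _rt_it_inf_tau(v, chan):
    minf = 1.0 / (1.0 + math.exp(-(v - chan[I_RT_MV]) / chan[I_RT_MS]))
    hinf = 1.0 / (1.0 + math.exp((v - chan[I_RT_HV]) / chan[I_RT_HS]))
    taum = (3.0 + 1.0 / (math.exp((v + 27.0) / 10.0)
                         + math.exp(-(v + 102.0) / 15.0))) / chan[I_RT_PHIM]
    tauh = (85.0 + 1.0 / (math.exp((v + 48.0) / 4.0)
                          + math.exp(-(v + 407.0) / 50.0))) / chan[I_RT_PHIH]
    return minf, taum, hinf, tauh


@njit(cache=True)
def _ih_inf_tau(v, chan):
    minf = 1.0 / (1.0 + math.exp((v - chan[I_IH_V]) / chan[I_IH_S]))
    taum = 1.0 / (math.exp(-14.59 - 0.086 * v) + math.exp(-1.87 + 0.0701 * v))
    return minf, taum


@njit(cache=True)
def _ia_inf_tau(v, chan):
    phi = chan[I_IA_PHI]
    m1 = 1.0 / (1.0 + math.exp(-(v + 60.0) / 8.5))
    m2 = 1.0 / (1.0 + math.exp(-(v + 36.0) / 20.0))
    taum = (1.0 / (math.exp((v + 35.8) / 19.7)
                   + math.exp(-(v + 79.7) / 12.7)) + 0.37) / phi
    hinf = 1.0 / (1.0 + math.exp((v + 78.0) / 6.0))
    slow = 1.0 / (math.exp((v + 46.0) / 5.0) + math.exp(-(v + 238.0) / 37.5))
    tauh1 = (slow if v < -63.0 else 19.0) / phi
    tauh2 = (slow if v < -73.0 else 60.0) / phi
    return m1, m2, taum, hinf, tauh1, tauh2


@njit(cache=True)
def _vtrap(x, y):
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True)
def _traub(v, vtraub, tadj):
    v2 = v - vtraub
    am = 0.32 * _vtrap(13.0 - v2, 4.0)
    bm = 0.28 * _vtrap(v2 - 40.0, 5.0)
    ah = 0.128 * math.exp((17.0 - v2) / 18.0)
    bh = 4.0 / (1.0 + math.exp((40.0 - v2) / 5.0))
    an = 0.032 * _vtrap(15.0 - v2, 5.0)
    bn = 0.5 * math.exp((10.0 - v2) / 40.0)
    return (am / (am + bm), 1.0 / ((am + bm) * tadj),
            ah / (ah + bh), 1.0 / ((ah + bh) * tadj),
            an / (an + bn), 1.0 / ((an + bn) * tadj))


@njit(cache=True)
def _exp_update(x, xinf, tau, dt):
    return xinf + (x - xinf) * math.exp(-dt / tau)


@njit(cache=True)
def _tc_comp_currents(v, mt, ht, mh, m1a, m2a, h1a, h2a, cai, dens, epas, gpas, chan):
    """Ionic current density (mA/cm^2) and slope conductance (S/cm^2) of a TC
    compartment at voltage v (gates frozen)."""
    ek = chan[I_EK]
    ena = chan[I_ENA]
    # ohmic channels: exact conductance form
    g_h = dens[1] * mh
    g_a = dens[2] * (0.6 * m1a ** 4 * h1a + 0.4 * m2a ** 4 * h2a)
    kir = 1.0 / (1.0 + math.exp((v - chan[I_KIR_V]) / chan[I_KIR_S]))
    g_kir = dens[3] * kir
    nap = 1.0 / (1.0 + math.exp(-(v - chan[I_NAP_V]) / chan[I_NAP_S]))
    g_nap = dens[4] * nap
    i = (g_h * (v - chan[I_IH_E]) + g_a * (v - ek) + g_kir * (v - ek)
         + g_nap * (v - ena) + gpas * (v - epas))
    g = g_h + g_a + g_kir + g_nap + gpas
    # T current via GHK: numerical slope
    po = mt * mt * ht
    if dens[0] > 0.0:
        it = dens[0] * po * _ghk(v, cai, chan[I_CAO], chan[I_XFAC])
        it_hi = dens[0] * po * _ghk(v + 0.5, cai, chan[I_CAO], chan[I_XFAC])
        it_lo = dens[0] * po * _ghk(v - 0.5, cai, chan[I_CAO], chan[I_XFAC])
        i += it
        g += (it_hi - it_lo)  # /1.0 mV
    else:
        it = 0.0
    return i, g, it


@njit(cache=True)
def _cai_step(cai, it, dt, chan):
    drive = -1e4 * it / (2.0 * _ch_FARADAY * chan[I_CA_DEPTH])
    if drive < 0.0:
        drive = 0.0
    return (cai + dt * (drive + chan[I_CA_REST] / chan[I_CA_TAU])) / (1.0 + dt / chan[I_CA_TAU])


# ---------------------------------------------------------------------------
# single three-compartment TC neuron


@njit(cache=True)
def run_single_tc(dt, n_steps, v0, areas, g12, g23, cm, gpas, epas, dens,
                  gna, gk, vtraub, chan, i_inj, g_syn, e_syn,
                  clamp_steps, v_clamp, rec_every):
    """Integrate one 3-compartment TC neuron.

    ``i_inj`` (nA) and ``g_syn`` (nS) are somatic input series of length
    ``n_steps``.  For the first ``clamp_steps`` steps the soma is voltage-
    clamped at ``v_clamp`` and the clamp current recorded.  Records every
    ``rec_every`` steps: V, mT, hT, cai per compartment, the somatic clamp
    current, and the total T current (nA).
    """
    ncomp = 3
    v = np.empty(ncomp)
    for k in range(ncomp):
        v[k] = v0
    mt = np.empty(ncomp); ht = np.empty(ncomp); mh = np.empty(ncomp)
    m1a = np.empty(ncomp); m2a = np.empty(ncomp)
    h1a = np.empty(ncomp); h2a = np.empty(ncomp)
    cai = np.empty(ncomp)
    for k in range(ncomp):
        mi, tm, hi, th = _it_inf_tau(v[k], chan)
        mt[k] = mi; ht[k] = hi
        mhi, _ = _ih_inf_tau(v[k], chan)
        mh[k] = mhi
        a1, a2, _, hia, _, _ = _ia_inf_tau(v[k], chan)
        m1a[k] = a1; m2a[k] = a2; h1a[k] = hia; h2a[k] = hia
        cai[k] = chan[I_CA_REST]
    msp = 0.0; hsp = 1.0; nsp = 0.0
    if gna > 0.0 or gk > 0.0:
        mi, _, hi, _, ni, _ = _traub(v[0], vtraub, chan[I_NAK_TADJ])
        msp = mi; hsp = hi; nsp = ni

    n_rec = n_steps // rec_every + 1
    v_rec = np.zeros((n_rec, ncomp))
    mt_rec = np.zeros((n_rec, ncomp))
    ht_rec = np.zeros((n_rec, ncomp))
    cai_rec = np.zeros((n_rec, ncomp))
    iclamp_rec = np.zeros(n_rec)
    it_rec = np.zeros(n_rec)

    c_nf = np.empty(ncomp)  # nF
    for k in range(ncomp):
        c_nf[k] = cm * areas[k] * 1e3

    i_ion = np.empty(ncomp)
    g_ion = np.empty(ncomp)
    it_d = np.empty(ncomp)
    iclamp = 0.0
    ir = 0
    for s in range(n_steps + 1):
        if s % rec_every == 0 and ir < n_rec:
            for k in range(ncomp):
                v_rec[ir, k] = v[k]
                mt_rec[ir, k] = mt[k]
                ht_rec[ir, k] = ht[k]
                cai_rec[ir, k] = cai[k]
            iclamp_rec[ir] = iclamp
            tot = 0.0
            for k in range(ncomp):
                tot += it_d[k] * areas[k] * 1e6 if s > 0 else 0.0
            it_rec[ir] = tot
            ir += 1
        if s == n_steps:
            break
        clamped = s < clamp_steps
        if clamped:
            v[0] = v_clamp
        # gate updates at current V
        for k in range(ncomp):
            mi, tm, hi, th = _it_inf_tau(v[k], chan)
            mt[k] = _exp_update(mt[k], mi, tm, dt)
            ht[k] = _exp_update(ht[k], hi, th, dt)
            mhi, tmh = _ih_inf_tau(v[k], chan)
            mh[k] = _exp_update(mh[k], mhi, tmh, dt)
            a1, a2, tma, hia, th1, th2 = _ia_inf_tau(v[k], chan)
            m1a[k] = _exp_update(m1a[k], a1, tma, dt)
            m2a[k] = _exp_update(m2a[k], a2, tma, dt)
            h1a[k] = _exp_update(h1a[k], hia, th1, dt)
            h2a[k] = _exp_update(h2a[k], hia, th2, dt)
        if gna > 0.0 or gk > 0.0:
            mi, tm, hi, th, ni, tn = _traub(v[0], vtraub, chan[I_NAK_TADJ])
            msp = _exp_update(msp, mi, tm, dt)
            hsp = _exp_update(hsp, hi, th, dt)
            nsp = _exp_update(nsp, ni, tn, dt)
        # ionic currents and linearization
        for k in range(ncomp):
            i, g, it = _tc_comp_currents(v[k], mt[k], ht[k], mh[k], m1a[k], m2a[k],
                                         h1a[k], h2a[k], cai[k], dens[k], epas, gpas, chan)
            if k == 0 and (gna > 0.0 or gk > 0.0):
                gns = gna * msp ** 3 * hsp
                gks = gk * nsp ** 4
                i += gns * (v[k] - chan[I_ENA]) + gks * (v[k] - chan[I_EK])
                g += gns + gks
            i_ion[k] = i * areas[k] * 1e6   # nA
            g_ion[k] = g * areas[k] * 1e6   # uS
            it_d[k] = it
            cai[k] = _cai_step(cai[k], it, dt, chan)
        gs = g_syn[s] * 1e-3  # nS -> uS
        # tridiagonal implicit solve
        a0 = c_nf[0] / dt + g_ion[0] + g12 + gs
        b01 = -g12
        a1d = c_nf[1] / dt + g_ion[1] + g12 + g23
        b12 = -g23
        a2d = c_nf[2] / dt + g_ion[2] + g23
        r0 = c_nf[0] / dt * v[0] - i_ion[0] + g_ion[0] * v[0] + i_inj[s] + gs * e_syn
        r1 = c_nf[1] / dt * v[1] - i_ion[1] + g_ion[1] * v[1]
        r2 = c_nf[2] / dt * v[2] - i_ion[2] + g_ion[2] * v[2]
        if clamped:
            # soma fixed; solve the dendritic 2x2
            r1c = r1 + g12 * v_clamp
            det = a1d * a2d - b12 * b12
            v1n = (r1c * a2d - b12 * r2) / det
            v2n = (a1d * r2 - b12 * r1c) / det
            iclamp = i_ion[0] + g12 * (v_clamp - v1n) + gs * (v_clamp - e_syn)
            v[0] = v_clamp
            v[1] = v1n
            v[2] = v2n
        else:
            # Thomas algorithm, 3 unknowns
            w1 = b01 / a0
            a1p = a1d - w1 * b01
            r1p = r1 - b01 / a0 * r0
            w2 = b12 / a1p
            a2p = a2d - w2 * b12
            r2p = r2 - b12 / a1p * r1p
            v2n = r2p / a2p
            v1n = (r1p - b12 * v2n) / a1p
            v0n = (r0 - b01 * v1n) / a0
            v[0] = v0n
            v[1] = v1n
            v[2] = v2n
            iclamp = 0.0
        if abs(v[0]) > 150.0 or abs(v[2]) > 150.0:
            # numerical blow-up: freeze and signal via NaN tail
            for k in range(ncomp):
                v[k] = np.nan
            for rr in range(ir, n_rec):
                for k in range(ncomp):
                    v_rec[rr, k] = np.nan
            break
    return v_rec, mt_rec, ht_rec, cai_rec, iclamp_rec, it_rec


# ---------------------------------------------------------------------------
# RT-TC network


@njit(cache=True)
def run_network(dt, n_steps,
                # TC layer
                areas, g12, g23, cm, gpas_tc, epas_tc, dens,
                gna_tc, gk_tc, vtraub_tc,
                # RT layer
                area_rt, gpas_rt, epas_rt, pt_rt, gna_rt, gk_rt, vtraub_rt, cm_rt,
                chan,
                # synapses
                rt_targets, amps18, dec18, tc_targets,
                ampa_amp, dec_ampa_r, dec_ampa_d, delay_steps, e_gaba,
                # stimulus: square pulse into listed RT cells
                stim_cells, stim_on, stim_off, stim_amp,
                # discrepancy tracking window (steps)
                disc_on, disc_off,
                # recording
                rec_every, max_spikes):
    """Integrate an RT-TC network; returns spikes, per-TC max open-probability
    discrepancy in the tracking window, and sampled traces.

    TC cells are indexed 0..n_tc-1 and RT cells n_tc..n_tc+n_rt-1 in the spike
    output.  ``rt_targets[j]`` lists TC indices inhibited by RT cell j (18-term
    GABA_B kernel, linear summation); ``tc_targets[i]`` lists RT cells excited
    by TC cell i (biexponential AMPA).  Sampled traces (every ``rec_every``
    steps): somatic V of every cell and the summed GABA_B conductance per TC.
    """
    n_tc = areas.shape[0]
    n_rt = area_rt.shape[0]
    # --- state
    vt = np.empty((n_tc, 3))
    mt = np.empty((n_tc, 3)); htg = np.empty((n_tc, 3)); mhg = np.empty((n_tc, 3))
    m1a = np.empty((n_tc, 3)); m2a = np.empty((n_tc, 3))
    h1a = np.empty((n_tc, 3)); h2a = np.empty((n_tc, 3))
    cai = np.empty((n_tc, 3))
    msp = np.empty(n_tc); hsp = np.empty(n_tc); nsp = np.empty(n_tc)
    for i in range(n_tc):
        for k in range(3):
            vt[i, k] = epas_tc[i]
            mi, tm, hi, th = _it_inf_tau(vt[i, k], chan)
            mt[i, k] = mi; htg[i, k] = hi
            mhi, _ = _ih_inf_tau(vt[i, k], chan)
            mhg[i, k] = mhi
            a1, a2, _, hia, _, _ = _ia_inf_tau(vt[i, k], chan)
            m1a[i, k] = a1; m2a[i, k] = a2; h1a[i, k] = hia; h2a[i, k] = hia
            cai[i, k] = chan[I_CA_REST]
        mi, _, hi, _, ni, _ = _traub(vt[i, 0], vtraub_tc, chan[I_NAK_TADJ])
        msp[i] = mi; hsp[i] = hi; nsp[i] = ni
    vr = np.empty(n_rt)
    mtr = np.empty(n_rt); htr = np.empty(n_rt)
    mspr = np.empty(n_rt); hspr = np.empty(n_rt); nspr = np.empty(n_rt)
    cair = np.empty(n_rt)
    for j in range(n_rt):
        vr[j] = epas_rt
        mi, _, hi, _ = _rt_it_inf_tau(vr[j], chan)
        mtr[j] = mi; htr[j] = hi
        mi, _, hi, _, ni, _ = _traub(vr[j], vtraub_rt, chan[I_NAK_TADJ])
        mspr[j] = mi; hspr[j] = hi; nspr[j] = ni
        cair[j] = chan[I_CA_REST]
    gb = np.zeros((n_tc, 18))
    amp_a = np.zeros(n_rt)  # rise state
    amp_b = np.zeros(n_rt)  # decay state
    buf_gb = np.zeros((delay_steps, n_tc))
    buf_am = np.zeros((delay_steps, n_rt))
    prev_vt = np.empty(n_tc)
    prev_vr = np.empty(n_rt)
    for i in range(n_tc):
        prev_vt[i] = vt[i, 0]
    for j in range(n_rt):
        prev_vr[j] = vr[j]

    spike_cell = np.empty(max_spikes, dtype=np.int64)
    spike_t = np.empty(max_spikes, dtype=np.float64)
    n_spk = 0
    max_disc = np.full(n_tc, -1.0)
    n_rec = (n_steps // rec_every + 1) if rec_every > 0 else 1
    v_rec = np.zeros((n_rec, n_tc + n_rt))
    gb_rec = np.zeros((n_rec, n_tc))
    c_tc = np.empty((n_tc, 3))
    for i in range(n_tc):
        for k in range(3):
            c_tc[i, k] = cm * areas[i, k] * 1e3
    c_rt = np.empty(n_rt)
    for j in range(n_rt):
        c_rt[j] = cm_rt * area_rt[j] * 1e3

    ir = 0
    for s in range(n_steps + 1):
        if rec_every > 0 and s % rec_every == 0 and ir < n_rec:
            for i in range(n_tc):
                v_rec[ir, i] = vt[i, 0]
                tot = 0.0
                for q in range(18):
                    tot += gb[i, q]
                gb_rec[ir, i] = tot
            for j in range(n_rt):
                v_rec[ir, n_tc + j] = vr[j]
            ir += 1
        if s == n_steps:
            break
        ptr = s % delay_steps
        # deliver delayed events, decay synaptic states
        for i in range(n_tc):
            c = buf_gb[ptr, i]
            for q in range(18):
                gb[i, q] = gb[i, q] * dec18[q]
                if c > 0.0:
                    gb[i, q] += c * amps18[q]
            buf_gb[ptr, i] = 0.0
        for j in range(n_rt):
            c = buf_am[ptr, j]
            amp_a[j] = amp_a[j] * dec_ampa_r
            amp_b[j] = amp_b[j] * dec_ampa_d
            if c > 0.0:
                amp_a[j] += c * ampa_amp
                amp_b[j] += c * ampa_amp
            buf_am[ptr, j] = 0.0
        out_ptr = (s + delay_steps - 1) % delay_steps  # slot for events arriving after delay
        # --- TC cells
        for i in range(n_tc):
            for k in range(3):
                vk = vt[i, k]
                mi, tm, hi, th = _it_inf_tau(vk, chan)
                mt[i, k] = _exp_update(mt[i, k], mi, tm, dt)
                htg[i, k] = _exp_update(htg[i, k], hi, th, dt)
                mhi, tmh = _ih_inf_tau(vk, chan)
                mhg[i, k] = _exp_update(mhg[i, k], mhi, tmh, dt)
                a1, a2, tma, hia, th1, th2 = _ia_inf_tau(vk, chan)
                m1a[i, k] = _exp_update(m1a[i, k], a1, tma, dt)
                m2a[i, k] = _exp_update(m2a[i, k], a2, tma, dt)
                h1a[i, k] = _exp_update(h1a[i, k], hia, th1, dt)
                h2a[i, k] = _exp_update(h2a[i, k], hia, th2, dt)
            mi, tm, hi, th, ni, tn = _traub(vt[i, 0], vtraub_tc, chan[I_NAK_TADJ])
            msp[i] = _exp_update(msp[i], mi, tm, dt)
            hsp[i] = _exp_update(hsp[i], hi, th, dt)
            nsp[i] = _exp_update(nsp[i], ni, tn, dt)
            # discrepancy tracking on the distal dendrite
            if disc_on <= s < disc_off:
                vk = vt[i, 2]
                mi, tm, hi, th = _it_inf_tau(vk, chan)
                d = mt[i, 2] * mt[i, 2] * htg[i, 2] - mi * mi * hi
                if d > max_disc[i]:
                    max_disc[i] = d
            ii = np.empty(3); gg = np.empty(3)
            for k in range(3):
                i_d, g_d, it = _tc_comp_currents(vt[i, k], mt[i, k], htg[i, k], mhg[i, k],
                                                 m1a[i, k], m2a[i, k], h1a[i, k], h2a[i, k],
                                                 cai[i, k], dens[i, k], epas_tc[i],
                                                 gpas_tc[i], chan)
                if k == 0:
                    gns = gna_tc[i] * msp[i] ** 3 * hsp[i]
                    gks = gk_tc[i] * nsp[i] ** 4
                    i_d += gns * (vt[i, 0] - chan[I_ENA]) + gks * (vt[i, 0] - chan[I_EK])
                    g_d += gns + gks
                ii[k] = i_d * areas[i, k] * 1e6
                gg[k] = g_d * areas[i, k] * 1e6
                cai[i, k] = _cai_step(cai[i, k], it, dt, chan)
            gtot = 0.0
            for q in range(18):
                gtot += gb[i, q]
            gs = gtot * 1e-3  # nS -> uS
            if gs < 0.0:
                gs = 0.0
            a0 = c_tc[i, 0] / dt + gg[0] + g12[i] + gs
            b01 = -g12[i]
            a1d = c_tc[i, 1] / dt + gg[1] + g12[i] + g23[i]
            b12 = -g23[i]
            a2d = c_tc[i, 2] / dt + gg[2] + g23[i]
            r0 = c_tc[i, 0] / dt * vt[i, 0] - ii[0] + gg[0] * vt[i, 0] + gs * e_gaba
            r1 = c_tc[i, 1] / dt * vt[i, 1] - ii[1] + gg[1] * vt[i, 1]
            r2 = c_tc[i, 2] / dt * vt[i, 2] - ii[2] + gg[2] * vt[i, 2]
            w1 = b01 / a0
            a1p = a1d - w1 * b01
            r1p = r1 - w1 * r0
            w2 = b12 / a1p
            a2p = a2d - w2 * b12
            r2p = r2 - w2 * r1p
            v2n = r2p / a2p
            v1n = (r1p - b12 * v2n) / a1p
            v0n = (r0 - b01 * v1n) / a0
            vt[i, 0] = v0n; vt[i, 1] = v1n; vt[i, 2] = v2n
            # spike detection at soma
            if prev_vt[i] < -30.0 <= v0n:
                if n_spk < max_spikes:
                    spike_cell[n_spk] = i
                    spike_t[n_spk] = (s + 1) * dt
                    n_spk += 1
                for q in range(tc_targets.shape[1]):
                    tgt = tc_targets[i, q]
                    if tgt >= 0:
                        buf_am[out_ptr, tgt] += 1.0
            prev_vt[i] = v0n
        # --- RT cells
        for j in range(n_rt):
            vj = vr[j]
            mi, tm, hi, th = _rt_it_inf_tau(vj, chan)
            mtr[j] = _exp_update(mtr[j], mi, tm, dt)
            htr[j] = _exp_update(htr[j], hi, th, dt)
            mi, tm, hi, th, ni, tn = _traub(vj, vtraub_rt, chan[I_NAK_TADJ])
            mspr[j] = _exp_update(mspr[j], mi, tm, dt)
            hspr[j] = _exp_update(hspr[j], hi, th, dt)
            nspr[j] = _exp_update(nspr[j], ni, tn, dt)
            po = mtr[j] * mtr[j] * htr[j]
            it = pt_rt * po * _ghk(vj, cair[j], chan[I_CAO], chan[I_XFAC])
            it_hi = pt_rt * po * _ghk(vj + 0.5, cair[j], chan[I_CAO], chan[I_XFAC])
            it_lo = pt_rt * po * _ghk(vj - 0.5, cair[j], chan[I_CAO], chan[I_XFAC])
            cair[j] = _cai_step(cair[j], it, dt, chan)
            gns = gna_rt * mspr[j] ** 3 * hspr[j]
            gks = gk_rt * nspr[j] ** 4
            i_d = (it + gns * (vj - chan[I_ENA]) + gks * (vj - chan[I_EK])
                   + gpas_rt[j] * (vj - epas_rt))
            g_d = (it_hi - it_lo) + gns + gks + gpas_rt[j]
            i_nA = i_d * area_rt[j] * 1e6
            g_uS = g_d * area_rt[j] * 1e6
            g_ampa = ampa_amp_g(amp_a[j], amp_b[j])  # nS
            gs = g_ampa * 1e-3
            i_stim = 0.0
            if stim_on <= s < stim_off:
                for q in range(stim_cells.shape[0]):
                    if stim_cells[q] == j:
                        i_stim = stim_amp
            a0 = c_rt[j] / dt + g_uS + gs
            r0 = c_rt[j] / dt * vj - i_nA + g_uS * vj + gs * 0.0 + i_stim
            vn = r0 / a0
            vr[j] = vn
            if prev_vr[j] < -30.0 <= vn:
                if n_spk < max_spikes:
                    spike_cell[n_spk] = n_tc + j
                    spike_t[n_spk] = (s + 1) * dt
                    n_spk += 1
                for q in range(rt_targets.shape[1]):
                    tgt = rt_targets[j, q]
                    if tgt >= 0:
                        buf_gb[out_ptr, tgt] += 1.0
            prev_vr[j] = vn
    return (spike_cell[:n_spk], spike_t[:n_spk], max_disc,
            v_rec[:ir], gb_rec[:ir])


@njit(cache=True)
def ampa_amp_g(a, b):
    g = b - a
    return g if g > 0.0 else 0.0
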