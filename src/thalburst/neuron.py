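"""Three-compartment thalamocortical neuron model and simulation protocols.

A TC relay neuron is reduced to one cylindrical somatic compartment (length =
diameter) in series with two cylindrical dendritic compartments of equal
diameter, each carrying half the total dendritic length.  Specific
capacitance (0.88 uF/cm^2) and axial resistivity (173 Ohm cm) are fixed;
geometry, uniform leak density and per-compartment active channel densities
vary across neurons.  Somatic point inputs (current in nA, GABA_B conductance
in nS with a -115 mV reversal) emulate the dynamic-clamp configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine
from .channels import IonConditions
from .gabab import GababKinetics, eval_conductance

__all__ = ["CM", "RA", "E_GABA", "TCNeuronParams", "SimTrace", "TCModel",
           "reference_neuron"]

CM = 0.88     # uF/cm^2, specific membrane capacitance
RA = 173.0    # Ohm cm, axial resistivity
E_GABA = -115.0  # mV, GABA_B (GIRK) reversal used in simulations

COMPARTMENTS = ("soma", "dend1", "dend2")
#: order of the per-compartment density vector
DENSITY_FIELDS = ("pbar_T", "gbar_h", "gbar_A", "gbar_Kir", "gbar_NaP")


@dataclass(frozen=True)
class TCNeuronParams:
    """Geometry, leak, and active channel densities of one model TC neuron.

    ``densities`` is a (3, 5) array: rows soma/dend1/dend2, columns
    (pbar_T [cm/s], gbar_h, gbar_A, gbar_Kir, gbar_NaP [S/cm^2]).
    """

    diam_soma: float          # um; somatic length == diameter
    diam_dend: float          # um
    l_dend: float             # um, total (split across the two compartments)
    g_pas: float              # S/cm^2, uniform
    e_pas: float = -70.0      # mV
    densities: np.ndarray = field(default_factory=lambda: np.zeros((3, 5)))
    gbar_na: float = 0.0      # S/cm^2, somatic fast Na (spiking runs only)
    gbar_k: float = 0.0       # S/cm^2, somatic fast K
    name: str = "tc"

    def __post_init__(self):
        if min(self.diam_soma, self.diam_dend, self.l_dend) <= 0:
            raise ValueError("geometry must be strictly positive")
        d = np.asarray(self.densities, dtype=float)
        if d.shape != (3, 5):
            raise ValueError("densities must have shape (3, 5)")
        if np.any(d < 0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "densities", d)

    # -- derived geometry -------------------------------------------------
    @property
    def areas(self) -> np.ndarray:
        """Lateral areas (cm^2) of soma, dend1, dend2."""
        a_soma = np.pi * self.diam_soma ** 2          # L = diam
        a_dend = np.pi * self.diam_dend * (self.l_dend / 2.0)
        return np.array([a_soma, a_dend, a_dend]) * 1e-8

    @property
    def axial_conductances(self) -> tuple[float, float]:
        """Series axial conductances (uS): soma-dend1 and dend1-dend2.

        Half-cylinder resistances from the axial resistivity and cylinder
        geometry, summed across the junction.
        """
        def half_r(diam_um, len_um):  # -> MOhm
            r_cm = diam_um / 2.0 * 1e-4
            l_cm = len_um / 2.0 * 1e-4
            return RA * l_cm / (np.pi * r_cm ** 2) / 1e6

        ld = self.l_dend / 2.0
        r12 = half_r(self.diam_soma, self.diam_soma) + half_r(self.diam_dend, ld)
        r23 = 2.0 * half_r(self.diam_dend, ld)
        return 1.0 / r12, 1.0 / r23

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def with_spiking(self, gbar_na: float = 0.09, gbar_k: float = 0.01) -> "TCNeuronParams":
        return replace(self, gbar_na=gbar_na, gbar_k=gbar_k)

    def passive_only(self) -> "TCNeuronParams":
        return replace(self, densities=np.zeros((3, 5)), gbar_na=0.0, gbar_k=0.0)

    def to_dict(self) -> dict:
        d = {"diam_soma": self.diam_soma, "diam_dend": self.diam_dend,
             "l_dend": self.l_dend, "g_pas": self.g_pas, "e_pas": self.e_pas,
             "gbar_na": self.gbar_na, "gbar_k": self.gbar_k, "name": self.name}
        for i, comp in enumerate(COMPARTMENTS):
            for j, f in enumerate(DENSITY_FIELDS):
                d[f"{f}_{comp}"] = float(self.densities[i, j])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TCNeuronParams":
        dens = np.array([[float(d[f"{f}_{comp}"]) for f in DENSITY_FIELDS]
                         for comp in COMPARTMENTS])
        return cls(diam_soma=float(d["diam_soma"]), diam_dend=float(d["diam_dend"]),
                   l_dend=float(d["l_dend"]), g_pas=float(d["g_pas"]),
                   e_pas=float(d.get("e_pas", -70.0)), densities=dens,
                   gbar_na=float(d.get("gbar_na", 0.0)), gbar_k=float(d.get("gbar_k", 0.0)),
                   name=str(d.get("name", "tc")))


@dataclass
class SimTrace:
    """Time-aligned record of one simulated (or emulated) sweep."""

    t: np.ndarray                  # ms
    v: np.ndarray                  # (n, 3) mV per compartment
    i_applied: np.ndarray          # nA at soma
    g_syn: np.ndarray              # nS at soma
    gates: dict                    # {"mT": (n,3), "hT": (n,3)}
    cai: np.ndarray                # (n, 3) mM
    ipsc_onset: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def v_soma(self) -> np.ndarray:
        return self.v[:, 0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (t, compartment, variable)."""
        rows = []
        for k, comp in enumerate(COMPARTMENTS):
            df = pd.DataFrame({"t": self.t, "compartment": comp})
            df["v"] = self.v[:, k]
            df["mT"] = self.gates["mT"][:, k]
            df["hT"] = self.gates["hT"][:, k]
            df["cai"] = self.cai[:, k]
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        return out.melt(id_vars=["t", "compartment"], var_name="variable",
                        value_name="value")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class TCModel:
    """Simulation handle for one three-compartment TC neuron.

    Wraps the compiled engine with the standard protocols: quasi-steady
    voltage clamp to find holding current, the dynamic-clamp-emulating IPSC
    protocol, and plain current pulses.
    """

    def __init__(self, params: TCNeuronParams, ions: IonConditions | None = None,
                 tauh_factor: float = 1.0, taum_factor: float = 1.0):
        self.params = params
        self.ions = ions or IonConditions()
        self._chan = engine.build_chan_vec(self.ions.temperature)
        # scale the T-channel inactivation/activation time constants
        # (kinetics-manipulation experiments); steady states are untouched
        self._chan[engine.I_IT_PHIH] /= tauh_factor
        self._chan[engine.I_IT_PHIM] /= taum_factor
        self.tauh_factor = tauh_factor
        from .channels import PARAMS
        self._vtraub = PARAMS["NaK_spk"]["vtraub_tc"]

    # -- low-level driver --------------------------------------------------
    def _run(self, dt, t_total, i_inj, g_syn, clamp_ms=0.0, v_clamp=-70.0,
             v0=-70.0, rec_every=1):
        p = self.params
        n_steps = int(round(t_total / dt))
        g12, g23 = p.axial_conductances
        out = engine.run_single_tc(
            dt, n_steps, v0, p.areas, g12, g23, CM, p.g_pas, p.e_pas,
            np.ascontiguousarray(p.densities), p.gbar_na, p.gbar_k, self._vtraub,
            self._chan, np.ascontiguousarray(i_inj), np.ascontiguousarray(g_syn),
            E_GABA, int(round(clamp_ms / dt)), v_clamp, rec_every)
        v_rec, mt, ht, cai, iclamp, it = out
        t = np.arange(v_rec.shape[0]) * dt * rec_every
        return t, v_rec, mt, ht, cai, iclamp, it

    # -- protocols ---------------------------------------------------------
    def find_holding_current(self, v_hold: float, dt: float = 0.1) -> tuple[float, bool]:
        """Somatic clamp current after a 2 s clamp at ``v_hold`` (from -70 mV).

        Returns ``(current_nA, converged)``; ``converged`` is False when the
        clamp current still drifts by more than 1 pA over the last 100 ms.
        """
        if not -90.0 <= v_hold <= -50.0:
            raise ValueError("v_hold outside the validated range [-90, -50] mV")
        n = int(round(2000.0 / dt))
        zeros = np.zeros(n + 1)
        t, _, _, _, _, iclamp, _ = self._run(dt, 2000.0, zeros, zeros,
                                             clamp_ms=2000.0, v_clamp=v_hold,
                                             rec_every=max(1, int(round(1.0 / dt))))
        drift = abs(iclamp[-1] - iclamp[-101])
        return float(iclamp[-1]), bool(drift <= 1e-3)

    def run_ipsc_protocol(self, waveform: GababKinetics, v_hold: float = -70.0,
                          dt: float = 0.1, t_total: float = 10000.0,
                          rec_dt: float = 1.0, pulse_onset: float = 2100.0,
                          ipsc_onset: float = 3000.0) -> SimTrace:
        """Dynamic-clamp emulation: 2 s somatic clamp at ``v_hold``, holding
        current thereafter, a -50 pA/10 ms pulse at ~2.1 s, and the GABA_B
        conductance waveform from 3 s (reversal -115 mV)."""
        i_hold, _ = self.find_holding_current(v_hold, dt)
        n = int(round(t_total / dt))
        tt = np.arange(n + 1) * dt
        i_inj = np.full(n + 1, i_hold)
        i_inj[(tt >= pulse_onset) & (tt < pulse_onset + 10.0)] += -0.050
        g_syn = eval_conductance(waveform, tt, onset=ipsc_onset)
        rec_every = max(1, int(round(rec_dt / dt)))
        t, v, mt, ht, cai, _, it = self._run(dt, t_total, i_inj, g_syn,
                                             clamp_ms=2000.0, v_clamp=v_hold,
                                             rec_every=rec_every)
        if np.isnan(v[:, 0]).any():
            raise FloatingPointError("simulation diverged (|V| > 150 mV)")
        sl = slice(0, None, rec_every)
        return SimTrace(t=t, v=v, i_applied=i_inj[sl][: len(t)],
                        g_syn=g_syn[sl][: len(t)],
                        gates={"mT": mt, "hT": ht}, cai=cai,
                        ipsc_onset=ipsc_onset,
                        meta={"v_hold": v_hold, "i_hold": i_hold, "dt_sim": dt,
                              "condition": waveform.condition,
                              "scale": waveform.scale, "i_t": it})

    def run_current_pulse(self, amplitude_pa: float = -50.0, width_ms: float = 10.0,
                          v_hold: float = -70.0, dt: float = 0.1,
                          t_total: float = 1100.0, settle_ms: float = 1000.0,
                          rec_dt: float = 0.1) -> SimTrace:
        """Holding epoch then a rectangular somatic current pulse."""
        if width_ms <= 0:
            raise ValueError("pulse width must be positive")
        i_hold, _ = self.find_holding_current(v_hold, dt)
        n = int(round((settle_ms + t_total) / dt))
        tt = np.arange(n + 1) * dt
        i_inj = np.full(n + 1, i_hold)
        on = settle_ms + 100.0
        i_inj[(tt >= on) & (tt < on + width_ms)] += amplitude_pa * 1e-3
        g_syn = np.zeros(n + 1)
        rec_every = max(1, int(round(rec_dt / dt)))
        t, v, mt, ht, cai, _, _ = self._run(dt, settle_ms + t_total, i_inj, g_syn,
                                            clamp_ms=settle_ms, v_clamp=v_hold,
                                            rec_every=rec_every)
        sl = slice(0, None, rec_every)
        keep = t >= settle_ms
        return SimTrace(t=t[keep] - settle_ms, v=v[keep], i_applied=i_inj[sl][: len(t)][keep],
                        g_syn=g_syn[sl][: len(t)][keep], gates={"mT": mt[keep], "hT": ht[keep]},
                        cai=cai[keep], ipsc_onset=None,
                        meta={"pulse_onset": 100.0, "pulse_width": width_ms,
                              "pulse_pa": amplitude_pa, "v_hold": v_hold,
                              "i_hold": i_hold})


def reference_neuron() -> TCNeuronParams:
    """A synthetic representative well-fitted TC neuron.

    Constructed (not fitted to any recording) so that its rebound behaviour
    matches the well-fitted cohort's signature at 200 % amplitude: a
    low-threshold spike after the GAT1- and GAT3-blockade waveforms but not
    after the control or dual-blockade waveforms, with dendritic T-channel
    density high relative to the soma and somatic A-type density high.
    """
    dens = np.array([
        # pbar_T,  gbar_h,  gbar_A,  gbar_Kir, gbar_NaP
        [2.0e-4, 2.2e-5, 4.0e-2, 2.0e-4, 5.5e-6],   # soma
        [5.0e-4, 2.2e-5, 5.5e-3, 2.0e-4, 5.5e-6],   # dend1
        [5.0e-4, 2.2e-5, 5.5e-3, 2.0e-4, 5.5e-6],   # dend2
    ])
    return TCNeuronParams(diam_soma=32.0, diam_dend=6.5, l_dend=500.0,
                          g_pas=1.5e-4, e_pas=-70.0, densities=dens,
                          name="reference")
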