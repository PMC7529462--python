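"""Voltage- and calcium-dependent membrane current kinetics.

Implements the channel set of the three-compartment thalamocortical (TC)
relay neuron — the low-threshold T-type calcium current (GHK flux, m^2 h),
the hyperpolarization-activated cation current Ih, the fast transient
potassium current IA, the inward rectifier IKir, the persistent sodium
current INaP, passive leak, Traub-style fast Na/K spiking currents, and
first-order submembranal calcium extrusion — plus the reticular-cell (RT)
T-current variant.  Kinetic coefficients are frozen in
``data/channel_kinetics.yaml`` and loaded at import.

These are plain NumPy implementations used for steady-state evaluation,
oracles, and post-hoc analysis; the time-stepping versions live in the
compiled engine and share the same parameter file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "PARAMS",
    "IonConditions",
    "FARADAY",
    "GAS_CONSTANT",
    "gating_steady_taus",
    "ghk_flux",
    "channel_current",
    "update_calcium",
    "traub_rates",
]

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.3134  # J/(mol K)

CHANNELS = ("IT", "Ih", "IA", "IKir", "INaP", "NaK_spk", "IT_RT")


def _load_params() -> dict:
    ref = importlib.resources.files("thalburst.data") / "channel_kinetics.yaml"
    return yaml.safe_load(ref.read_text())


#: Frozen kinetic coefficients (see data/channel_kinetics.yaml).
PARAMS = _load_params()


@dataclass(frozen=True)
class IonConditions:
    """Fixed ionic conditions for all simulations."""

    e_k: float = PARAMS["ions"]["e_k"]
    e_na: float = PARAMS["ions"]["e_na"]
    cao: float = PARAMS["ions"]["cao_mM"]
    cai0: float = PARAMS["ions"]["cai0_mM"]
    temperature: float = PARAMS["ions"]["temperature"]


# ---------------------------------------------------------------------------
# gating kinetics


def _it_gates(v, p, temperature):
    vs = np.asarray(v, dtype=float) + p["shift"]
    phim = p["q10_m"] ** ((temperature - p["t_ref"]) / 10.0)
    phih = p["q10_h"] ** ((temperature - p["t_ref"]) / 10.0)
    minf = 1.0 / (1.0 + np.exp(-(vs - p["m_vhalf"]) / p["m_slope"]))
    hinf = 1.0 / (1.0 + np.exp((vs - p["h_vhalf"]) / p["h_slope"]))
    if p is PARAMS["IT"]:
        taum = (0.612 + 1.0 / (np.exp(-(vs + 132.0) / 16.7)
                               + np.exp((vs + 16.8) / 18.2))) / phim
        tauh = np.where(
            vs < -80.0,
            np.exp((vs + 467.0) / 66.6),
            28.0 + np.exp(-(vs + 22.0) / 10.5),
        ) / phih
    else:  # reticular variant: slower activation and much slower inactivation
        taum = (3.0 + 1.0 / (np.exp((vs + 27.0) / 10.0)
                             + np.exp(-(vs + 102.0) / 15.0))) / phim
        tauh = (85.0 + 1.0 / (np.exp((vs + 48.0) / 4.0)
                              + np.exp(-(vs + 407.0) / 50.0))) / phih
    return {"m_inf": minf, "tau_m": taum, "h_inf": hinf, "tau_h": tauh}


def _ih_gates(v, p):
    v = np.asarray(v, dtype=float)
    minf = 1.0 / (1.0 + np.exp((v - p["vhalf"]) / p["slope"]))
    taum = 1.0 / (np.exp(-14.59 - 0.086 * v) + np.exp(-1.87 + 0.0701 * v))
    return {"m_inf": minf, "tau_m": taum}


def _ia_gates(v, p, temperature):
    v = np.asarray(v, dtype=float)
    phi = p["q10"] ** ((temperature - p["t_ref"]) / 10.0)
    m1 = 1.0 / (1.0 + np.exp(-(v + 60.0) / 8.5))
    m2 = 1.0 / (1.0 + np.exp(-(v + 36.0) / 20.0))
    taum = (1.0 / (np.exp((v + 35.8) / 19.7) + np.exp(-(v + 79.7) / 12.7)) + 0.37) / phi
    hinf = 1.0 / (1.0 + np.exp((v + 78.0) / 6.0))
    slow = 1.0 / (np.exp((v + 46.0) / 5.0) + np.exp(-(v + 238.0) / 37.5))
    tauh1 = np.where(v < -63.0, slow, 19.0) / phi
    tauh2 = np.where(v < -73.0, slow, 60.0) / phi
    return {"m1_inf": m1, "tau_m": taum, "m2_inf": m2,
            "h_inf": hinf, "tau_h1": tauh1, "tau_h2": tauh2}


def gating_steady_taus(channel: str, v, temperature: float | None = None) -> dict:
    """Steady-state values and time constants of a channel's gates at ``v``.

    Instantaneous gates (IKir, INaP activation) report only ``*_inf``.
    Temperature defaults to the simulation temperature (33 deg C); the cited
    per-channel Q10 corrections are applied.
    """
    if temperature is None:
        temperature = PARAMS["ions"]["temperature"]
    if channel == "IT":
        return _it_gates(v, PARAMS["IT"], temperature)
    if channel == "IT_RT":
        return _it_gates(v, PARAMS["IT_RT"], temperature)
    if channel == "Ih":
        return _ih_gates(v, PARAMS["Ih"])
    if channel == "IA":
        return _ia_gates(v, PARAMS["Ia"], temperature)
    if channel == "IKir":
        p = PARAMS["IKir"]
        return {"m_inf": 1.0 / (1.0 + np.exp((np.asarray(v, float) - p["vhalf"]) / p["slope"]))}
    if channel == "INaP":
        p = PARAMS["INaP"]
        return {"m_inf": 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - p["vhalf"]) / p["slope"]))}
    if channel == "NaK_spk":
        return traub_rates(v, PARAMS["NaK_spk"]["vtraub_tc"], temperature)
    raise KeyError(f"unknown channel {channel!r}; valid: {CHANNELS}")


def traub_rates(v, vtraub: float, temperature: float | None = None) -> dict:
    """Traub-style fast Na/K gate kinetics (m, h, n) with threshold shift."""
    if temperature is None:
        temperature = PARAMS["ions"]["temperature"]
    p = PARAMS["NaK_spk"]
    tadj = p["q10"] ** ((temperature - p["t_ref"]) / 10.0)
    v2 = np.asarray(v, dtype=float) - vtraub

    def _vtrap(x, y):
        # x/(exp(x/y)-1) with the removable singularity handled
        x = np.asarray(x, dtype=float)
        small = np.abs(x / y) < 1e-6
        xs = np.where(small, y, x)  # safe denominator for the vector branch
        return np.where(small, y * (1.0 - x / y / 2.0),
                        xs / (np.exp(xs / y) - 1.0))

    am = 0.32 * _vtrap(13.0 - v2, 4.0)
    bm = 0.28 * _vtrap(v2 - 40.0, 5.0)
    ah = 0.128 * np.exp((17.0 - v2) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - v2) / 5.0))
    an = 0.032 * _vtrap(15.0 - v2, 5.0)
    bn = 0.5 * np.exp((10.0 - v2) / 40.0)
    out = {}
    for name, a, b in (("m", am, bm), ("h", ah, bh), ("n", an, bn)):
        out[f"{name}_inf"] = a / (a + b)
        out[f"tau_{name}"] = 1.0 / ((a + b) * tadj)
    return out


# ---------------------------------------------------------------------------
# currents


def ghk_flux(v, cai, cao, temperature: float | None = None):
    """Goldman-Hodgkin-Katz driving term for Ca2+ (mA/cm^2 per cm/s).

    Multiplied by a permeability (cm/s) and an open probability this yields a
    current density.  Finite at v = 0 (second-order series for small
    arguments).  Concentrations in mM.
    """
    cai = np.asarray(cai, dtype=float)
    cao = np.asarray(cao, dtype=float)
    if np.any(cai <= 0) or np.any(cao <= 0):
        raise ValueError("concentrations must be positive")
    if temperature is None:
        temperature = PARAMS["ions"]["temperature"]
    z = 2.0
    x = z * FARADAY * np.asarray(v, dtype=float) * 1e-3 / (GAS_CONSTANT * (temperature + 273.15))

    def efun(x):
        x = np.asarray(x, dtype=float)
        small = np.abs(x) < 1e-9
        xs = np.where(small, 1.0, x)
        return np.where(small, 1.0 - x / 2.0 + x * x / 12.0, xs / (np.exp(xs) - 1.0))

    # 1e-3 converts (C/mol)*(mM) = C*mol/(mol*m^3) bookkeeping into mA s/cm^3
    return 1e-3 * z * FARADAY * (cai * efun(-x) - cao * efun(x))


def channel_current(channel: str, state: dict, v, densities: dict,
                    ions: IonConditions | None = None, cai=None):
    """Current density (mA/cm^2) of one channel given its gating state.

    ``state`` carries the instantaneous gate values (e.g. ``{"m": .., "h": ..}``
    for IT); instantaneous channels ignore it and use steady states at ``v``.
    ``densities`` maps the channel to its maximal density (``pbar_T`` in cm/s
    for IT/IT_RT, ``gbar_*`` in S/cm^2 otherwise, ``g_pas`` for leak).
    """
    ions = ions or IonConditions()
    v = np.asarray(v, dtype=float)
    if channel in ("IT", "IT_RT"):
        pbar = densities.get("pbar_T", 0.0)
        cai = ions.cai0 if cai is None else cai
        return pbar * state["m"] ** 2 * state["h"] * ghk_flux(v, cai, ions.cao, ions.temperature)
    if channel == "Ih":
        return densities.get("gbar_h", 0.0) * state["m"] * (v - PARAMS["Ih"]["e_rev"])
    if channel == "IA":
        po = 0.6 * state["m1"] ** 4 * state["h1"] + 0.4 * state["m2"] ** 4 * state["h2"]
        return densities.get("gbar_A", 0.0) * po * (v - ions.e_k)
    if channel == "IKir":
        minf = gating_steady_taus("IKir", v)["m_inf"]
        return densities.get("gbar_Kir", 0.0) * minf * (v - ions.e_k)
    if channel == "INaP":
        minf = gating_steady_taus("INaP", v)["m_inf"]
        return densities.get("gbar_NaP", 0.0) * minf * (v - ions.e_na)
    if channel == "leak":
        return densities.get("g_pas", 0.0) * (v - densities.get("e_pas", -70.0))
    if channel == "NaK_spk":
        i_na = densities.get("gbar_na", 0.0) * state["m"] ** 3 * state["h"] * (v - ions.e_na)
        i_k = densities.get("gbar_k", 0.0) * state["n"] ** 4 * (v - ions.e_k)
        return i_na + i_k
    raise KeyError(f"unknown channel {channel!r}")


def update_calcium(cai: float, i_t: float, dt: float) -> float:
    """One step of submembranal calcium decay (first-order shell model).

    Inward Ca current feeds a thin shell (influx clipped at zero for outward
    current); the shell relaxes toward resting calcium with the extrusion
    time constant.  Semi-implicit update, exact for constant influx.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = PARAMS["Cadecay"]
    drive = max(0.0, -1e4 * i_t / (2.0 * FARADAY * p["depth_um"]))
    return (cai + dt * (drive + p["ca_rest_mM"] / p["tau_ms"])) / (1.0 + dt / p["tau_ms"])
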