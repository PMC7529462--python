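"""GABA_B receptor conductance waveforms.

The inhibitory postsynaptic conductance evoked by reticular-thalamic GABA
release onto thalamocortical neurons is modelled as a product of an eighth-
power rising exponential and a double-exponential decay,

    g(t) = A * (1 - exp(-t/tau_rise))**8
             * (w * exp(-t/tau_fall_fast) + (1 - w) * exp(-t/tau_fall_slow)),

with one parameter row per pharmacological condition (control and blockade of
the GABA transporters GAT1, GAT3, or both).  GAT1 blockade mainly raises the
amplitude; GAT3 and dual blockade also slow the decay, dual blockade
dramatically so.  Waveforms are expressed in nS and are used both as
dynamic-clamp-style somatic conductance commands and (expanded into pure
exponentials, see :func:`exp_terms`) as linearly summing synaptic kernels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import comb

import numpy as np

__all__ = [
    "CONDITIONS",
    "GababKinetics",
    "condition_params",
    "eval_conductance",
    "vary_kinetics",
    "exp_terms",
    "eval_exp_terms",
    "waveform_to_csv",
    "kinetics_table_from_config",
]

#: Condition labels in canonical order.
CONDITIONS = ("Control", "GAT1-Block", "GAT3-Block", "Dual-Block")

# Fitted waveform parameters per pharmacological condition:
# A (nS), tau_rise (ms), tau_fall_fast (ms), tau_fall_slow (ms), w.
_TABLE = {
    "Control": (16.00, 52.00, 90.10, 1073.20, 0.952),
    "GAT1-Block": (24.00, 52.00, 90.10, 1073.20, 0.952),
    "GAT3-Block": (8.88, 38.63, 273.40, 1022.00, 0.775),
    "Dual-Block": (6.32, 39.88, 65.80, 2600.00, 0.629),
}

#: Temperature coefficient for the receptor kinetics.
Q10 = 2.1
#: Temperature (deg C) at which the waveform parameters were measured.
T_EXP = 33.0


@dataclass(frozen=True)
class GababKinetics:
    """Parameters of one GABA_B IPSC conductance waveform.

    ``scale`` is a dimensionless amplitude multiplier (dynamic-clamp
    experiments used 0.25-8.0); the effective amplitude is ``scale * A``.
    """

    A: float
    tau_rise: float
    tau_fall_fast: float
    tau_fall_slow: float
    w: float
    scale: float = 1.0
    condition: str = "Control"

    def __post_init__(self) -> None:
        if min(self.tau_rise, self.tau_fall_fast, self.tau_fall_slow) <= 0:
            raise ValueError("all time constants must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("decay weight w must lie in [0, 1]")
        if self.A < 0:
            raise ValueError("amplitude coefficient A must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def with_scale(self, scale: float) -> "GababKinetics":
        return replace(self, scale=scale)

    def at_temperature(self, temperature: float) -> "GababKinetics":
        """Apply the Q10 correction, dividing all time constants by
        ``Q10 ** ((temperature - 33) / 10)``.  Identity at 33 deg C."""
        f = Q10 ** ((temperature - T_EXP) / 10.0)
        return replace(
            self,
            tau_rise=self.tau_rise / f,
            tau_fall_fast=self.tau_fall_fast / f,
            tau_fall_slow=self.tau_fall_slow / f,
        )


def condition_params(condition: str) -> GababKinetics:
    """Return the fitted waveform parameters for one condition (scale 1)."""
    try:
        A, tr, tff, tfs, w = _TABLE[condition]
    except KeyError:
        raise KeyError(
            f"unknown condition {condition!r}; valid labels: {list(CONDITIONS)}"
        ) from None
    return GababKinetics(A, tr, tff, tfs, w, scale=1.0, condition=condition)


def eval_conductance(k: GababKinetics, t_grid: np.ndarray, onset: float = 0.0) -> np.ndarray:
    """Evaluate the conductance waveform (nS) on ``t_grid`` (ms).

    Zero before ``onset``; afterwards the eighth-power-rise, biexponential-
    decay product scaled by ``k.scale``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or (t_grid.size > 1 and np.any(np.diff(t_grid) <= 0)):
        raise ValueError("t_grid must be a monotone increasing 1-D array")
    s = t_grid - onset
    g = np.zeros_like(s)
    m = s > 0
    sp = s[m]
    rise = (1.0 - np.exp(-sp / k.tau_rise)) ** 8
    decay = k.w * np.exp(-sp / k.tau_fall_fast) + (1.0 - k.w) * np.exp(-sp / k.tau_fall_slow)
    g[m] = k.scale * k.A * rise * decay
    return g


def _charge(k: GababKinetics, dt: float = 0.1) -> float:
    """Trapezoidal area under the waveform (nS*ms) over >= 10 tau_fall_slow."""
    t_end = 10.0 * max(k.tau_fall_slow, k.tau_fall_fast, k.tau_rise)
    t = np.arange(0.0, t_end + dt, dt)
    return float(np.trapezoid(eval_conductance(k, t), t))


def vary_kinetics(
    k: GababKinetics,
    time_factor: float = 1.0,
    amp_factor: float = 1.0,
    preserve_charge: bool = False,
) -> GababKinetics:
    """Rescale the waveform kinetics and/or amplitude.

    ``time_factor`` multiplies all three time constants (a shape-preserving
    sweep of the overall kinetics); ``amp_factor`` multiplies the amplitude.
    With ``preserve_charge`` the amplitude is instead rescaled so the area
    under the curve is unchanged (incompatible with ``amp_factor != 1``).
    """
    if time_factor <= 0 or amp_factor <= 0:
        raise ValueError("factors must be positive")
    if preserve_charge and amp_factor != 1.0:
        raise ValueError("preserve_charge contradicts an explicit amp_factor")
    out = replace(
        k,
        tau_rise=k.tau_rise * time_factor,
        tau_fall_fast=k.tau_fall_fast * time_factor,
        tau_fall_slow=k.tau_fall_slow * time_factor,
        A=k.A * amp_factor,
    )
    if preserve_charge:
        out = replace(out, A=out.A * _charge(k) / _charge(out))
    return out


def exp_terms(k: GababKinetics) -> tuple[np.ndarray, np.ndarray]:
    """Expand the waveform into pure exponentials for linear summation.

    The eighth-power rise expands binomially,
    ``(1 - e**(-t/tr))**8 = sum_j C(8,j) (-1)**j e**(-j t/tr)``, and crossing
    the j = 1..8 terms with the two decay exponentials (the j = 0 row leaves
    the two bare decays) gives 18 terms ``a_i * exp(-t/tau_i)``.

    Returns ``(amplitudes_nS, taus_ms)``, each of length 18.
    """
    amps, taus = [], []
    for j in range(9):
        c = comb(8, j) * (-1) ** j
        for wgt, tau_d in ((k.w, k.tau_fall_fast), (1.0 - k.w, k.tau_fall_slow)):
            a = k.scale * k.A * c * wgt
            # 1/tau = j/tau_rise + 1/tau_decay
            tau = 1.0 / (j / k.tau_rise + 1.0 / tau_d)
            amps.append(a)
            taus.append(tau)
    return np.asarray(amps), np.asarray(taus)


def eval_exp_terms(amps: np.ndarray, taus: np.ndarray, t_grid: np.ndarray,
                   onset: float = 0.0) -> np.ndarray:
    """Evaluate an exponential-term expansion on a time grid (oracle helper)."""
    s = np.asarray(t_grid, dtype=float)[:, None] - onset
    out = np.where(s > 0, amps[None, :] * np.exp(-np.clip(s, 0, None) / taus[None, :]), 0.0)
    return out.sum(axis=1)


def waveform_to_csv(k: GababKinetics, path, t_end: float = 8000.0, dt: float = 0.1,
                    onset: float = 0.0) -> None:
    """Export as two-column CSV (time_ms, conductance_nS)."""
    t = np.arange(0.0, t_end + dt, dt)
    g = eval_conductance(k, t, onset)
    np.savetxt(path, np.column_stack([t, g]), delimiter=",",
               header="time_ms,conductance_nS", comments="")


def kinetics_table_from_config(path) -> dict[str, GababKinetics]:
    """Load a condition table from a JSON/YAML file mirroring the built-in one.

    Each entry maps a condition label to the five waveform parameters
    (``A``, ``tau_rise``, ``tau_fall_fast``, ``tau_fall_slow``, ``w``).
    """
    text = open(path).read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        raw = yaml.safe_load(text)
    return {
        name: GababKinetics(condition=name, scale=float(row.get("scale", 1.0)),
                            **{f: float(row[f]) for f in
                               ("A", "tau_rise", "tau_fall_fast", "tau_fall_slow", "w")})
        for name, row in raw.items()
    }
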