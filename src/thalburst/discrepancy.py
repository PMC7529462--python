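"""T-channel open-probability discrepancy analysis.

The T channel opens as m^2 h.  Activation (m) is fast and tracks its steady
state; inactivation (h) is roughly ten-fold slower and lags behind.  The
*open probability discrepancy* d(t) = mT^2 hT - mT,inf^2 hT,inf quantifies
how far the instantaneous open probability exceeds the steady-state open
probability at the present voltage; large positive discrepancy is the
signature of rebound LTS generation, and a threshold of 1e-2 empirically
separates LTS-producing from LTS-lacking responses.

The *decision point* is where the log10-discrepancy curve reaches zero (or
maximal negative) concavity during the first post-hyperpolarization voltage
rise; the slope there predicts whether the trajectory will cross threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .channels import gating_steady_taus
from .neuron import SimTrace

__all__ = ["LTS_DISCREPANCY_THRESHOLD", "DiscrepancySeries",
           "compute_discrepancy", "find_decision_point", "predict_lts"]

#: Empirical LTS threshold on the open-probability discrepancy.
LTS_DISCREPANCY_THRESHOLD = 1e-2

_COMP_INDEX = {"soma": 0, "dend1": 1, "dend2": 2}


@dataclass
class DiscrepancySeries:
    """Open-probability discrepancy of one sweep, resampled to 1 ms."""

    t: np.ndarray          # ms
    d: np.ndarray          # mT^2 hT - mT,inf^2 hT,inf
    v: np.ndarray          # mV (same compartment)
    log_d: np.ndarray      # log10(d) where d > 0, NaN elsewhere
    slope: np.ndarray      # d/dt log_d (1/ms)
    concavity: np.ndarray  # d2/dt2 log_d (1/ms^2)
    compartment: str = "dend2"
    meta: dict = field(default_factory=dict)

    @property
    def max_d(self) -> float:
        return float(np.nanmax(self.d)) if self.d.size else np.nan


def _resample(t, y, dt_out):
    t_out = np.arange(t[0], t[-1] + dt_out / 2, dt_out)
    return t_out, np.interp(t_out, t, y)


def compute_discrepancy(trace: SimTrace, compartment: str = "dend2",
                        resample_ms: float = 1.0,
                        tauh_factor: float | None = None) -> DiscrepancySeries:
    """Pointwise discrepancy with steady states evaluated at the
    instantaneous voltage; slope/concavity of log10 d on a 1 ms grid.

    ``tauh_factor`` is accepted for signature symmetry with the kinetics
    manipulations but does not enter: time-constant scaling leaves the
    steady-state curves unchanged.
    """
    if "mT" not in trace.gates or "hT" not in trace.gates:
        raise ValueError("trace carries no T-channel gate series")
    k = _COMP_INDEX[compartment]
    v = trace.v[:, k]
    mt = trace.gates["mT"][:, k]
    ht = trace.gates["hT"][:, k]
    ss = gating_steady_taus("IT", v)
    d = mt ** 2 * ht - ss["m_inf"] ** 2 * ss["h_inf"]

    t1, d1 = _resample(trace.t, d, resample_ms)
    _, v1 = _resample(trace.t, v, resample_ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_d = np.where(d1 > 0, np.log10(np.where(d1 > 0, d1, 1.0)), np.nan)
    # ~3 ms smoothing then central differences on the resampled grid
    sm = log_d.copy()
    ok = np.isfinite(sm)
    n_sm = max(3, int(round(3.0 / resample_ms)) | 1)
    if ok.sum() > n_sm:
        sm[ok] = uniform_filter1d(sm[ok], size=n_sm, mode="nearest")
    slope = np.full_like(sm, np.nan)
    conc = np.full_like(sm, np.nan)
    slope[1:-1] = (sm[2:] - sm[:-2]) / (2 * resample_ms)
    conc[1:-1] = (sm[2:] - 2 * sm[1:-1] + sm[:-2]) / resample_ms ** 2
    return DiscrepancySeries(t=t1, d=d1, v=v1, log_d=log_d, slope=slope,
                             concavity=conc, compartment=compartment,
                             meta=dict(trace.meta))


def first_rebound_window(series: DiscrepancySeries, ipsc_onset: float) -> tuple:
    """(t_start, t_end) spanning the first post-hyperpolarization voltage
    rise: from the voltage minimum after IPSC onset to the first subsequent
    local voltage maximum (sweep end if none)."""
    sel = series.t >= ipsc_onset
    t = series.t[sel]
    v = series.v[sel]
    i_min = int(np.argmin(v))
    pk, _ = find_peaks(v[i_min:])
    i_max = i_min + (int(pk[0]) if pk.size else len(v) - 1 - i_min)
    return float(t[i_min]), float(t[i_max])


def find_decision_point(series: DiscrepancySeries,
                        window: tuple | None = None) -> dict:
    """Decision point of the log-discrepancy curve within ``window``.

    First zero crossing of the concavity if one exists, else the time of
    maximal (least negative) concavity.  Returns the discrepancy slope and
    the voltage slope there; all-NaN when the discrepancy is never positive
    in the window (no decision point).
    """
    if window is None:
        window = (series.t[0], series.t[-1])
    sel = (series.t >= window[0]) & (series.t <= window[1])
    t = series.t[sel]
    conc = series.concavity[sel]
    slope = series.slope[sel]
    v = series.v[sel]
    ok = np.isfinite(conc)
    absent = {"t_dp": np.nan, "slope_at_dp": np.nan, "max_concavity": np.nan,
              "voltage_slope_at_dp": np.nan, "found": False}
    if ok.sum() < 3:
        return absent
    idx = np.flatnonzero(ok)
    c = conc[idx]
    # decision point: the first crossing where the concavity rises through
    # zero (the curve committing to accelerating growth); a curve that only
    # saturates (falling crossing) contributes its inflection -- the falling
    # crossing nearest the slope maximum; a strictly concave curve its point
    # of maximal concavity
    rising = np.flatnonzero(np.diff(np.sign(c)) > 0)
    falling = np.flatnonzero(np.diff(np.sign(c)) < 0)
    if rising.size:
        i = idx[int(rising[0]) + 1]
    elif falling.size:
        sl = slope[idx]
        i_infl = int(np.nanargmax(sl))
        i = idx[int(falling[np.argmin(np.abs(falling - i_infl))]) + 1]
    else:
        i = idx[int(np.argmax(c))]
    dv = np.gradient(v, t)
    return {"t_dp": float(t[i]), "slope_at_dp": float(slope[i]),
            "max_concavity": float(np.nanmax(c)),
            "voltage_slope_at_dp": float(dv[i]), "found": True}


def predict_lts(series: DiscrepancySeries,
                threshold: float = LTS_DISCREPANCY_THRESHOLD) -> bool:
    """True iff the discrepancy exceeds ``threshold`` at any time."""
    return bool(np.nanmax(series.d) > threshold) if series.d.size else False
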