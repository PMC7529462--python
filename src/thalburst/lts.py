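"""Detection and featurization of low-threshold spikes (LTS) and bursts.

An LTS is the slow (~50 ms), broad calcium-dependent depolarization that can
follow strong inhibition in thalamocortical neurons; a burst is an LTS
crowned by fast action potentials.  Detection operates identically on
recorded and simulated sweeps: the voltage is median-filtered (30 ms) to
strip action potentials and moving-average-filtered (30 ms); the LTS
candidate is the local maximum of the doubly filtered trace with the most
negative second derivative between the IPSC peak and 7 s after IPSC onset,
and is accepted as an LTS when its prominence exceeds the pre-IPSC baseline
noise, its second derivative is below threshold (default -2.3 V/s^2, or a
threshold fitted from the candidate population), and — if spikes ride on
it — the peak follows the first spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import argrelextrema, find_peaks, peak_prominences

__all__ = [
    "DEFAULT_D2_THRESHOLD",
    "LTSCandidate",
    "LTSResult",
    "detect_lts_candidate",
    "fit_second_derivative_threshold",
    "classify_and_featurize",
    "analyze_sweep",
    "summarize_probabilities",
]

#: Default second-derivative threshold (V/s^2).
DEFAULT_D2_THRESHOLD = -2.3

FILTER_MS = 30.0       # median and moving-average window
SEARCH_END_MS = 7000.0  # LTS search horizon after IPSC onset
IPSC_PEAK_WINDOW_MS = 300.0
SPIKE_REL_THRESHOLD_MV = 10.0


def _odd(n: int) -> int:
    return max(3, n | 1)


def _double_filter(v: np.ndarray, dt: float, window_ms: float = FILTER_MS) -> np.ndarray:
    n = _odd(int(round(window_ms / dt)))
    vm = median_filter(v, size=n, mode="reflect")
    return uniform_filter1d(vm, size=n, mode="reflect")


def _derivatives(vf: np.ndarray, dt: float, window_ms: float = FILTER_MS):
    """First differences -> smoothed first derivative -> second difference.

    Returns (d1, d2) in V/s and V/s^2, index-aligned with ``vf`` (edges
    padded by repetition).
    """
    n = _odd(int(round(window_ms / dt)))
    d1 = np.diff(vf) / dt                     # mV/ms == V/s
    d1f = uniform_filter1d(d1, size=n, mode="reflect")
    d2 = np.diff(d1f) / dt * 1e3              # V/s per ms -> V/s^2
    d1a = np.concatenate([d1f[:1], d1f])
    d2a = np.concatenate([d2[:1], d2, d2[-1:]])
    return d1a, d2a


@dataclass(frozen=True)
class LTSCandidate:
    index: int
    peak_time: float          # ms (same clock as the sweep)
    peak_value_filtered: float
    peak_2nd_deriv: float     # V/s^2
    window: tuple             # (t_start, t_end) of the search window


@dataclass
class LTSResult:
    """Per-sweep LTS/burst decision and features."""

    has_lts: bool
    has_burst: bool = False
    peak_time: float = np.nan       # ms
    latency: float = np.nan         # ms from IPSC onset
    peak_value: float = np.nan      # mV
    max_slope: float = np.nan       # V/s
    n_spikes: int = 0
    peak_2nd_deriv: float = np.nan  # V/s^2
    peak_prominence: float = np.nan
    overruled: bool = False         # imported legacy labels only
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("has_lts", "has_burst", "peak_time", "latency", "peak_value",
              "max_slope", "n_spikes", "peak_2nd_deriv", "overruled")}
        d.update(self.meta)
        return d


def detect_lts_candidate(t: np.ndarray, v: np.ndarray, ipsc_onset: float,
                         g_syn: np.ndarray | None = None) -> LTSCandidate | None:
    """Locate the LTS candidate in one sweep.

    The search window opens at the IPSC peak (maximum of ``g_syn`` within
    300 ms of onset; onset itself when no conductance trace is supplied) and
    closes 7 s after onset or at the sweep end.  Returns ``None`` when the
    doubly filtered trace has no interior local maximum in the window.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    dt = t[1] - t[0]
    vf = _double_filter(v, dt)
    _, d2 = _derivatives(vf, dt)

    if g_syn is not None and np.any(np.asarray(g_syn) > 0):
        wp = (t >= ipsc_onset) & (t <= ipsc_onset + IPSC_PEAK_WINDOW_MS)
        t_peak_ipsc = t[wp][np.argmax(np.asarray(g_syn)[wp])]
    else:
        t_peak_ipsc = ipsc_onset
    t_end = min(ipsc_onset + SEARCH_END_MS, t[-1])
    lo = int(np.searchsorted(t, t_peak_ipsc))
    hi = int(np.searchsorted(t, t_end, side="right"))
    if hi - lo < 3:
        return None
    seg = vf[lo:hi]
    maxima, _ = find_peaks(seg)  # interior local maxima; plateaus collapsed
    if maxima.size == 0:
        return None
    idx = maxima + lo
    best = idx[np.argmin(d2[idx])]  # argmin returns the earliest on ties
    return LTSCandidate(index=int(best), peak_time=float(t[best]),
                        peak_value_filtered=float(vf[best]),
                        peak_2nd_deriv=float(d2[best]),
                        window=(float(t_peak_ipsc), float(t_end)))


def fit_second_derivative_threshold(cand_d2: np.ndarray, random_state: int = 0,
                                    fallback: float = DEFAULT_D2_THRESHOLD) -> float:
    """Threshold from a 3-component Gaussian-mixture fit of candidate second
    derivatives: the pdf minimum between the two lowest-mean components.

    Falls back to the fixed default on degenerate fits (overlapping
    components or too few candidates).
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(cand_d2, float).reshape(-1, 1)
    x = x[np.isfinite(x[:, 0])]
    if len(x) < 10:
        return fallback
    try:
        gm = GaussianMixture(n_components=3, random_state=random_state,
                             n_init=3).fit(x)
    except ValueError:
        return fallback
    order = np.argsort(gm.means_[:, 0])
    m1, m2 = gm.means_[order[0], 0], gm.means_[order[1], 0]
    s1 = np.sqrt(gm.covariances_[order[0]].ravel()[0])
    s2 = np.sqrt(gm.covariances_[order[1]].ravel()[0])
    if m2 - m1 < max(s1, s2):   # components not separated: unimodal-ish
        return fallback
    grid = np.linspace(m1, m2, 512)
    pdf = np.exp(gm.score_samples(grid.reshape(-1, 1)))
    interior = pdf[1:-1]
    if interior.min() >= min(pdf[0], pdf[-1]):
        return fallback
    return float(grid[1 + np.argmin(interior)])


def _slope_filter_window(v_seg: np.ndarray, dt: float, target_mv: float = 3.0) -> int:
    """Moving-average window (samples, 1-30 ms) whose maximum within-window
    voltage range on the rising phase is closest to ``target_mv``."""
    best_n, best_err = _odd(int(round(1.0 / dt))), np.inf
    for w_ms in np.arange(1.0, 31.0, 1.0):
        n = _odd(int(round(w_ms / dt)))
        if n >= len(v_seg):
            break
        rng = (pd.Series(v_seg).rolling(n).max() - pd.Series(v_seg).rolling(n).min()).max()
        err = abs(rng - target_mv)
        if err < best_err:
            best_n, best_err = n, err
    return best_n


def classify_and_featurize(t: np.ndarray, v: np.ndarray, ipsc_onset: float,
                           candidate: LTSCandidate | None,
                           threshold: float = DEFAULT_D2_THRESHOLD) -> LTSResult:
    """Apply the three LTS criteria and compute features of the accepted LTS.

    Criteria: (1) peak prominence above the standard deviation of the
    filtered pre-IPSC baseline; (2) peak second derivative more negative than
    ``threshold``; (3) with riding spikes, the peak must follow the first
    spike.  The feature window is bounded by the first filtered-trace local
    minima on each side of the peak; the maximum slope is recomputed on a
    re-filtered trace whose window corresponds to a ~3 mV amplitude change.
    """
    if candidate is None:
        return LTSResult(has_lts=False)
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    dt = t[1] - t[0]
    vf = _double_filter(v, dt)
    i_pk = candidate.index

    base = vf[t < ipsc_onset]
    base_sd = float(base.std()) if base.size else 0.0
    prom = float(peak_prominences(vf, [i_pk])[0][0])

    # feature window: first local minima flanking the peak
    minima = argrelextrema(vf, np.less_equal, order=1)[0]
    left = minima[minima < i_pk]
    right = minima[minima > i_pk]
    i_lo = int(left[-1]) if left.size else 0
    i_hi = int(right[0]) if right.size else len(vf) - 1

    peak_value = float(vf[i_pk])
    # riding action potentials: raw-trace peaks 10 mV above the LTS amplitude
    seg_raw = v[i_lo:i_hi + 1]
    spk_idx, _ = find_peaks(seg_raw, height=peak_value + SPIKE_REL_THRESHOLD_MV)
    n_spikes = int(len(spk_idx))
    first_spike_t = float(t[i_lo + spk_idx[0]]) if n_spikes else np.nan

    crit1 = prom > base_sd
    crit2 = candidate.peak_2nd_deriv < threshold
    crit3 = (n_spikes == 0) or (candidate.peak_time > first_spike_t)
    has_lts = bool(crit1 and crit2 and crit3)
    if not has_lts:
        return LTSResult(has_lts=False, peak_time=candidate.peak_time,
                         peak_2nd_deriv=candidate.peak_2nd_deriv,
                         peak_prominence=prom,
                         meta={"crit_prominence": crit1, "crit_d2": crit2,
                               "crit_spike_order": crit3})

    # maximum slope on the rising phase, window tuned to ~3 mV change
    rise = v[i_lo:i_pk + 1]
    if len(rise) > 4:
        n_w = _slope_filter_window(rise, dt)
        n_med = _odd(int(round(FILTER_MS / dt)))
        vs = uniform_filter1d(median_filter(v, size=n_med, mode="reflect"),
                              size=n_w, mode="reflect")
        max_slope = float(np.max(np.diff(vs[i_lo:i_pk + 1]) / dt))
    else:
        max_slope = np.nan
    return LTSResult(
        has_lts=True, has_burst=n_spikes >= 1,
        peak_time=candidate.peak_time,
        latency=candidate.peak_time - ipsc_onset,
        peak_value=peak_value, max_slope=max_slope, n_spikes=n_spikes,
        peak_2nd_deriv=candidate.peak_2nd_deriv, peak_prominence=prom)


def analyze_sweep(t, v, ipsc_onset, g_syn=None,
                  threshold: float = DEFAULT_D2_THRESHOLD) -> LTSResult:
    """Candidate detection + classification in one call."""
    cand = detect_lts_candidate(t, v, ipsc_onset, g_syn)
    return classify_and_featurize(t, v, ipsc_onset, cand, threshold)


def summarize_probabilities(frame: pd.DataFrame,
                            by=("condition", "scale")) -> pd.DataFrame:
    """Per-group LTS/burst probabilities and responsive-sweep feature means.

    ``frame`` holds one row per sweep with at least ``has_lts``/``has_burst``
    plus the grouping keys; feature means are taken over LTS-positive sweeps
    (burst features over burst-positive sweeps).
    """
    if frame.empty:
        raise ValueError("empty result set")
    by = list(by)
    rows = []
    for key, g in frame.groupby(by):
        if g.empty:
            raise ValueError(f"empty group {key}")
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec["n_sweeps"] = len(g)
        rec["lts_probability"] = float(g["has_lts"].mean())
        rec["burst_probability"] = float(g["has_burst"].mean())
        pos = g[g["has_lts"].astype(bool)]
        for f in ("latency", "peak_value", "max_slope", "peak_2nd_deriv"):
            if f in g.columns:
                rec[f"mean_{f}"] = float(pos[f].mean()) if len(pos) else np.nan
        if "n_spikes" in g.columns:
            bpos = g[g["has_burst"].astype(bool)]
            rec["mean_spikes_per_burst"] = (float(bpos["n_spikes"].mean())
                                            if len(bpos) else np.nan)
            bl = bpos["latency"].mean() if len(bpos) else np.nan
            rec["mean_burst_latency"] = float(bl) if bl == bl else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
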