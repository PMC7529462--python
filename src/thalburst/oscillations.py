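"""Oscillation detection and quantification for multiunit sweeps and rasters.

Evoked epileptiform oscillations — in extracellular multiunit recordings
from the ventrobasal thalamus and in simulated RT-TC network rasters — are
quantified by: spike detection (slope threshold scaled by a slice-dependent
signal-to-noise ratio), burst grouping on a spike histogram, oscillation
duration (end of last evoked burst), oscillation period (multi-peak
autocorrelation lag fit), and the oscillatory index comparing secondary to
primary autocorrelation peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks

__all__ = [
    "OscillationMetrics", "detect_mua_spikes", "group_bursts",
    "estimate_period", "oscillatory_index", "phase_average",
    "trial_oscillation", "network_metrics", "relative_change",
]


@dataclass
class OscillationMetrics:
    """Per-network oscillation summary over a trial grid."""

    oscillation_probability: float
    mean_duration: float          # ms, over oscillating trials
    mean_period: float            # ms
    mean_oscillatory_index: float
    percent_active_tc: float      # %
    half_activation_latency: float  # ms
    n_trials: int
    per_trial: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# multiunit spike detection


def detect_mua_spikes(t: np.ndarray, sweeps: list[np.ndarray], stim_start: float,
                      band=(100.0, 1000.0), artifact_blank_ms: float = 25.0):
    """Slope-threshold spike detection on raw extracellular sweeps.

    Per sweep i: baseline slope noise alpha_i (RMS of the slope vector
    before stimulation) and maximum slope beta_i (>= 25 ms post-stimulus).
    The slice signal-to-noise ratio r = 1 + 0.1 (beta/alpha - 1) is formed
    from the sweep-averaged alpha and beta, and spikes are slope-vector
    local maxima at least 25 ms after the stimulus exceeding r * alpha_i.

    Returns (spike_times_per_sweep, info dict with alpha, beta, r).
    """
    t = np.asarray(t, float)
    if not np.any(t < stim_start):
        raise ValueError("no pre-stimulus baseline region in sweep")
    dt = t[1] - t[0]
    fs = 1000.0 / dt  # Hz
    hi = min(band[1], 0.45 * fs)
    b, a = butter(2, [band[0] / (fs / 2), hi / (fs / 2)], btype="band")
    slopes, alphas, betas = [], [], []
    for v in sweeps:
        filt = filtfilt(b, a, np.asarray(v, float))
        sl = np.diff(filt) / dt
        ts = t[1:]
        alphas.append(np.sqrt(np.mean(sl[ts < stim_start] ** 2)))
        betas.append(np.max(sl[ts >= stim_start + artifact_blank_ms]))
        slopes.append((ts, sl))
    alpha_bar = float(np.mean(alphas))
    beta_bar = float(np.mean(betas))
    r = 1.0 + 0.1 * (beta_bar / alpha_bar - 1.0)
    out = []
    for (ts, sl), alpha_i in zip(slopes, alphas):
        theta = r * alpha_i
        pk, _ = find_peaks(sl, height=theta)
        keep = ts[pk] >= stim_start + artifact_blank_ms
        out.append(ts[pk][keep])
    return out, {"alpha": alpha_bar, "beta": beta_bar, "r": r,
                 "alpha_i": alphas, "theta_i": [r * ai for ai in alphas]}


# ---------------------------------------------------------------------------
# bursts and duration


def group_bursts(spike_times, stim_start: float, bin_ms: float = 10.0,
                 min_rate_hz: float = 100.0, min_burst_ms: float = 60.0,
                 max_delay_ms: float = 2000.0, max_interval_ms: float = 2000.0):
    """Group spikes into evoked bursts on a spike histogram.

    Consecutive bins at or above the minimum rate are joined into bursts;
    bursts shorter than ``min_burst_ms`` are discarded; the evoked chain must
    start within ``max_delay_ms`` of the stimulus and tolerates inter-burst
    gaps up to ``max_interval_ms``.  Returns ``(bursts, duration_ms)`` with
    bursts as (start, end) pairs and duration measured from the stimulus to
    the end of the last chained burst (0 when none).
    """
    s = np.sort(np.asarray(spike_times, float))
    s = s[s >= stim_start]
    if s.size == 0:
        return [], 0.0
    n_bins = int(np.ceil((s[-1] - stim_start) / bin_ms)) + 1
    counts, edges = np.histogram(s, bins=n_bins,
                                 range=(stim_start, stim_start + n_bins * bin_ms))
    min_count = min_rate_hz * bin_ms / 1000.0
    active = counts >= max(min_count, 1e-9)
    bursts = []
    i = 0
    while i < len(active):
        if active[i]:
            j = i
            while j + 1 < len(active) and active[j + 1]:
                j += 1
            t0, t1 = edges[i], edges[j + 1]
            if t1 - t0 >= min_burst_ms:
                bursts.append((float(t0), float(t1)))
            i = j + 1
        else:
            i += 1
    # chain rule: start within max_delay, gaps within max_interval
    chained = []
    for bst in bursts:
        if not chained:
            if bst[0] - stim_start <= max_delay_ms:
                chained.append(bst)
        elif bst[0] - chained[-1][1] <= max_interval_ms:
            chained.append(bst)
        else:
            break
    duration = (chained[-1][1] - stim_start) if chained else 0.0
    return chained, float(duration)


# ---------------------------------------------------------------------------
# autocorrelation, period, oscillatory index


def _filtered_acf(spike_times, stim_start: float, duration: float,
                  bin_ms: float, ma_ms: float = 100.0):
    """Moving-average-filtered autocorrelation of mean-removed binned spikes,
    normalized so the primary (zero-lag) value is 1.  Lags beyond the
    oscillation duration are dropped."""
    s = np.sort(np.asarray(spike_times, float))
    s = s[(s >= stim_start)]
    if s.size < 2 or duration <= 0:
        return None, None
    n_bins = max(2, int(np.ceil(duration / bin_ms)))
    counts, _ = np.histogram(s, bins=n_bins, range=(stim_start, stim_start + duration))
    x = counts - counts.mean()
    acf = np.correlate(x, x, mode="full")[len(x) - 1:]
    if acf[0] <= 0:
        return None, None
    n_ma = max(1, int(round(ma_ms / bin_ms)) | 1)
    facf = uniform_filter1d(acf.astype(float), size=n_ma, mode="nearest")
    facf = facf / facf[0]
    lags = np.arange(len(facf)) * bin_ms
    keep = lags < duration
    return lags[keep], facf[keep]


def _acf_peaks(lags, facf, prominence_frac: float = 0.02,
               secondary_prom_frac: float | None = None):
    """Non-primary fACF peaks.  ``prominence_frac`` is relative to the
    primary (zero-lag) amplitude; with ``secondary_prom_frac`` peaks are
    instead thresholded relative to the largest secondary peak."""
    if secondary_prom_frac is None:
        pk, _ = find_peaks(facf, prominence=prominence_frac * facf[0])
        return pk[(lags[pk] > 0) & (facf[pk] > 0)]
    pk, props = find_peaks(facf, prominence=0.0)
    keep = (lags[pk] > 0) & (facf[pk] > 0)
    pk, proms = pk[keep], props["prominences"][keep]
    if pk.size == 0:
        return pk
    largest = proms[int(np.argmax(facf[pk]))]
    return pk[proms >= secondary_prom_frac * largest]


def period_distance(delta: float, peak_lags: np.ndarray) -> float:
    """f(delta) = sum_j |p_j - q_j(delta)| with q_j the closest multiple."""
    mult = np.round(peak_lags / delta)
    return float(np.sum(np.abs(peak_lags - mult * delta)))


def estimate_period(spike_times, stim_start: float, duration: float,
                    bin_ms: float = 10.0, prominence_frac: float = 0.02,
                    secondary_prom_frac: float | None = None,
                    grid_ms: float = 0.1):
    """Oscillation period: the lag delta minimizing the distance between the
    fACF peak lags and their closest multiples of delta.

    The search starts from the spacing of the first two peaks (the zero-lag
    primary and the first secondary) and is confined to [2/3, 3/2] of it,
    scanned densely.  Returns NaN when fewer than two peaks exist.
    """
    lags, facf = _filtered_acf(spike_times, stim_start, duration, bin_ms)
    if lags is None:
        return np.nan
    pk = _acf_peaks(lags, facf, prominence_frac, secondary_prom_frac)
    if pk.size < 1:
        return np.nan
    peak_lags = np.concatenate([[0.0], lags[pk]])
    if len(peak_lags) < 2:
        return np.nan
    delta0 = peak_lags[1] - peak_lags[0]
    grid = np.arange(2.0 * delta0 / 3.0, 1.5 * delta0 + grid_ms, grid_ms)
    vals = [period_distance(d, peak_lags[1:]) for d in grid]
    return float(grid[int(np.argmin(vals))])


def oscillatory_index(spike_times, stim_start: float, duration: float,
                      bin_ms: float = 10.0, prominence_frac: float = 0.02,
                      secondary_prom_frac: float | None = None) -> float:
    """OI = (A_peak2 - A_trough) / (A_peak1 - A_trough); 0 without a
    secondary peak.  A_peak2 is the non-primary peak with the largest fACF
    value; A_trough the fACF minimum between primary and secondary peaks."""
    lags, facf = _filtered_acf(spike_times, stim_start, duration, bin_ms)
    if lags is None:
        return 0.0
    pk = _acf_peaks(lags, facf, prominence_frac, secondary_prom_frac)
    if pk.size == 0:
        return 0.0
    i2 = pk[int(np.argmax(facf[pk]))]
    a1 = facf[0]
    a2 = facf[i2]
    a_tr = float(facf[1:i2].min()) if i2 > 1 else a2
    if a1 - a_tr <= 0:
        return 0.0
    return float((a2 - a_tr) / (a1 - a_tr))


def phase_average(values, n_select: int = 5, tolerance: float = 0.4):
    """Representative mean of end-of-phase sweep metrics.

    Greedily removes the value farthest from the running group mean until
    ``n_select`` remain and all lie within ``tolerance`` (fraction) of the
    group mean; falls back (flagged) to the plain mean of the last
    ``n_select`` values when no qualifying subset emerges.
    """
    vals = np.asarray(values, float)
    if vals.size < n_select:
        raise ValueError(f"need at least {n_select} values")
    group = sorted(vals.tolist())  # selection is order-free; sort for determinism
    while len(group) > n_select:
        g = np.asarray(group)
        group.pop(int(np.argmax(np.abs(g - g.mean()))))
    g = np.asarray(group)
    scale = abs(g.mean())
    ok = np.all(np.abs(g - g.mean()) <= tolerance * scale) if scale > 0 else np.all(g == 0)
    if not ok:
        return float(np.mean(vals[-n_select:])), True
    return float(g.mean()), False


# ---------------------------------------------------------------------------
# network-level metrics


def trial_oscillation(spike_times, stim_start: float, bin_ms: float = 100.0,
                      min_rate_hz: float = 100.0,
                      secondary_prom_frac: float = 0.5) -> dict:
    """Burst/period/OI summary of one pooled-network trial."""
    bursts, duration = group_bursts(spike_times, stim_start, bin_ms=bin_ms,
                                    min_rate_hz=min_rate_hz)
    oscillated = len(bursts) >= 3
    period = np.nan
    oi = np.nan
    if oscillated:
        period = estimate_period(spike_times, stim_start, duration,
                                 bin_ms=bin_ms,
                                 secondary_prom_frac=secondary_prom_frac)
        oi = oscillatory_index(spike_times, stim_start, duration,
                               bin_ms=bin_ms,
                               secondary_prom_frac=secondary_prom_frac)
    return {"n_bursts": len(bursts), "duration": duration,
            "oscillated": oscillated, "period": period,
            "oscillatory_index": oi}


def network_metrics(trials: list[dict], tc_first_spike_lists: list[np.ndarray],
                    n_tc: int, stim_start: float) -> OscillationMetrics:
    """Aggregate per-trial summaries into per-network oscillation metrics.

    ``tc_first_spike_lists`` holds, per trial, the first post-stimulus spike
    time of each TC cell that fired.  Oscillation probability counts trials
    with at least three bursts; means are over oscillating trials; the half
    activation latency is the median first-spike latency of the finally
    active TC set.
    """
    osc = [tr for tr in trials if tr["oscillated"]]
    prob = len(osc) / len(trials) if trials else 0.0

    def _mean(key):
        vals = [tr[key] for tr in osc if np.isfinite(tr[key])]
        return float(np.mean(vals)) if vals else np.nan

    pct, half = [], []
    for first in tc_first_spike_lists:
        first = np.asarray(first, float)
        pct.append(100.0 * first.size / n_tc)
        if first.size:
            lat = np.sort(first - stim_start)
            half.append(float(lat[(first.size - 1) // 2]))
    return OscillationMetrics(
        oscillation_probability=float(prob),
        mean_duration=_mean("duration"),
        mean_period=_mean("period"),
        mean_oscillatory_index=_mean("oscillatory_index"),
        percent_active_tc=float(np.mean(pct)) if pct else 0.0,
        half_activation_latency=float(np.mean(half)) if half else np.nan,
        n_trials=len(trials), per_trial=trials)


def relative_change(baseline, drug) -> float:
    """Mean relative change (%) across paired per-slice phase averages."""
    b = np.asarray(baseline, float)
    d = np.asarray(drug, float)
    return float(np.mean(d / b - 1.0) * 100.0)


def analyze_mua_phase(t, sweeps, stim_start: float):
    """Duration/period/OI for each sweep of one recording phase."""
    spikes, info = detect_mua_spikes(t, sweeps, stim_start)
    rows = []
    for s in spikes:
        bursts, dur = group_bursts(s, stim_start)
        rows.append({"duration": dur,
                     "period": estimate_period(s, stim_start, dur),
                     "oscillatory_index": oscillatory_index(s, stim_start, dur),
                     "n_bursts": len(bursts)})
    return rows, info


def experiment_relative_changes(slices: list[dict]) -> dict:
    """Mean relative changes of oscillation duration and period from baseline
    to drug phase across an experiment's slices.

    Each slice record carries raw sweeps for both phases (see the synthetic
    experiment generator or the equivalent CSV reader); phase values are the
    outlier-robust phase averages of the last sweeps of each phase.
    """
    base_d, drug_d, base_p, drug_p = [], [], [], []
    for rec in slices:
        stim = rec["truth"]["stim_start"] if "truth" in rec else rec["stim_start"]
        vals = {}
        for phase in ("baseline", "drug"):
            rows, _ = analyze_mua_phase(rec["t"], rec[phase], stim)
            durs = [r["duration"] for r in rows]
            pers = [r["period"] for r in rows if np.isfinite(r["period"])]
            vals[phase] = (phase_average(durs)[0],
                           phase_average(pers)[0] if len(pers) >= 5
                           else float(np.mean(pers)) if pers else np.nan)
        base_d.append(vals["baseline"][0])
        drug_d.append(vals["drug"][0])
        base_p.append(vals["baseline"][1])
        drug_p.append(vals["drug"][1])
    out = {"duration_change_pct": relative_change(base_d, drug_d),
           "n_slices": len(slices)}
    if np.all(np.isfinite(base_p)) and np.all(np.isfinite(drug_p)):
        out["period_change_pct"] = relative_change(base_p, drug_p)
    else:
        out["period_change_pct"] = np.nan
    return out
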