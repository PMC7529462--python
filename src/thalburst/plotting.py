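"""Basic trace and raster previews."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trace", "plot_raster", "plot_discrepancy"]


def plot_trace(trace, ax=None, compartment: int = 0):
    """Somatic (or chosen-compartment) voltage with the IPSC command."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.t / 1000.0, trace.v[:, compartment], lw=0.8, color="k")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("V (mV)")
    if np.any(trace.g_syn > 0):
        ax2 = ax.twinx()
        ax2.plot(trace.t / 1000.0, trace.g_syn, lw=0.8, color="tab:red",
                 alpha=0.6)
        ax2.set_ylabel("g_GABAB (nS)", color="tab:red")
    return ax


def plot_raster(spike_cell, spike_t, n_tc: int, ax=None, stim_window=None):
    """Network spike raster; TC cells below the axis break, RT cells above."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    spike_cell = np.asarray(spike_cell)
    spike_t = np.asarray(spike_t) / 1000.0
    tc = spike_cell < n_tc
    ax.plot(spike_t[tc], spike_cell[tc], "|", ms=3, color="tab:blue",
            label="TC")
    ax.plot(spike_t[~tc], spike_cell[~tc], "|", ms=3, color="tab:orange",
            label="RT")
    if stim_window is not None:
        ax.axvspan(stim_window[0] / 1000.0, stim_window[1] / 1000.0,
                   color="red", alpha=0.15)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell index")
    ax.legend(loc="upper right", frameon=False)
    return ax


def plot_discrepancy(series, ax=None, threshold: float = 1e-2):
    """log10 open-probability discrepancy over time with the LTS threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(series.t / 1000.0, series.log_d, lw=0.8, color="k")
    ax.axhline(np.log10(threshold), ls=":", color="g")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("log10 discrepancy")
    return ax
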