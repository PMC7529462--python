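"""Tabular I/O, schema validation, and the paired-test statistics gate."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["SWEEP_SCHEMA", "SPIKE_SCHEMA", "write_sweeps", "read_sweeps",
           "write_spikes", "read_spikes", "paired_test_gate",
           "params_to_json", "params_from_json"]

#: long-format sweep table: one row per (sweep, t)
SWEEP_SCHEMA = ("sweep", "t", "v")
#: spike table: one row per spike
SPIKE_SCHEMA = ("cell_type", "cell_index", "spike_time_ms")


def _check_schema(df: pd.DataFrame, schema, aliases: dict | None = None) -> pd.DataFrame:
    if aliases:
        df = df.rename(columns={v: k for k, v in aliases.items()})
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(
            f"missing columns {missing}; found {list(df.columns)}"
            + (f" (aliases applied: {aliases})" if aliases else ""))
    return df[list(schema) + [c for c in df.columns if c not in schema]]


def write_sweeps(path, t, sweeps, extra: dict | None = None) -> None:
    """Write a list of sweeps as a long-format CSV (sweep, t, v [, extras])."""
    frames = []
    for i, v in enumerate(sweeps):
        df = pd.DataFrame({"sweep": i, "t": np.asarray(t, float),
                           "v": np.asarray(v, float)})
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for k, vals in (extra or {}).items():
        out[k] = np.tile(np.asarray(vals), len(sweeps))
    out.to_csv(path, index=False, float_format="%.6g")


def read_sweeps(path, aliases: dict | None = None):
    """Read a long-format sweep CSV back into (t, sweeps).

    ``aliases`` maps schema names to the file's column names, letting
    externally exported tables (different headers) load through the same
    reader.
    """
    df = _check_schema(pd.read_csv(path), SWEEP_SCHEMA, aliases)
    t = None
    sweeps = []
    for _, g in df.groupby("sweep", sort=True):
        if t is None:
            t = g["t"].to_numpy()
        sweeps.append(g["v"].to_numpy())
    return t, sweeps


def write_spikes(path, spike_frame: pd.DataFrame) -> None:
    _check_schema(spike_frame, SPIKE_SCHEMA).to_csv(path, index=False,
                                                    float_format="%.4f")


def read_spikes(path, aliases: dict | None = None) -> pd.DataFrame:
    return _check_schema(pd.read_csv(path), SPIKE_SCHEMA, aliases)


def params_to_json(params_list, path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in params_list], fh, indent=1)


def params_from_json(path):
    from .neuron import TCNeuronParams

    with open(path) as fh:
        return [TCNeuronParams.from_dict(d) for d in json.load(fh)]


def paired_test_gate(group_a, group_b, alpha: float = 0.05) -> dict:
    """Normality-gated paired comparison between two matched groups.

    Normality of the differences to the within-subject mean is assessed per
    group with three omnibus tests (Lilliefors, Anderson-Darling,
    Jarque-Bera); when the geometric mean of the three p-values is at least
    0.05 for every group, a paired t-test is used, otherwise the Wilcoxon
    signed-rank test.  Two-tailed.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired groups must be 1-D and equally sized")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    from statsmodels.stats.diagnostic import lilliefors, normal_ad

    if np.allclose(a, b):
        return {"test": "paired_t", "statistic": 0.0, "p": 1.0,
                "normal": True, "gate_p": [1.0, 1.0]}
    subj_mean = (a + b) / 2.0
    normal = True
    gate_p = []
    for g in (a - subj_mean, b - subj_mean):
        if np.allclose(g, g[0]):
            gate_p.append(1.0)  # degenerate: no evidence against normality
            continue
        p_lf = lilliefors(g)[1]
        p_ad = normal_ad(g)[1]
        p_jb = sstats.jarque_bera(g).pvalue
        gm = float(np.exp(np.mean(np.log([max(p, 1e-300)
                                          for p in (p_lf, p_ad, p_jb)]))))
        gate_p.append(gm)
        if gm < alpha:
            normal = False
    if normal:
        res = sstats.ttest_rel(a, b)
        test = "paired_t"
    else:
        if np.allclose(a, b):
            return {"test": "wilcoxon", "statistic": 0.0, "p": 1.0,
                    "normal": normal, "gate_p": gate_p}
        res = sstats.wilcoxon(a, b)
        test = "wilcoxon"
    return {"test": test, "statistic": float(res.statistic),
            "p": float(res.pvalue), "normal": normal, "gate_p": gate_p}
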