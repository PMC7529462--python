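"""Fitting TC-neuron parameters to IPSC-response sweeps.

The optimizer minimizes a weighted multi-objective error between simulated
and target voltage responses across a set of GABA_B IPSC waveforms:

    E_total = (w_m E_m + w_sw E_sw + w_a E_a + w_t E_t + w_sl E_sl) / sum(w)

where E_m penalizes LTS presence/absence mismatches (18 for a missed LTS,
6 for a falsely produced one), E_sw is the voltage RMSE inside the fit
window (0-1.8 s after IPSC onset), and E_a / E_t / E_sl are LTS amplitude,
latency and maximum-slope errors over LTS-matching traces.  Minimization
uses a modified Nelder-Mead simplex operating in an unconstrained space
reached by mapping each bounded parameter linearly to [-1, 1] and through
the tangent transform to the real line; fast Na/K currents are excluded and
targets are median-filtered to remove spikes, emphasizing the LTS envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import median_filter

from .lts import analyze_sweep
from .neuron import TCModel, TCNeuronParams
from .gabab import GababKinetics

__all__ = ["FitWeights", "SimplexConfig", "total_error",
           "nelder_mead_bounded", "IpscResponseModel", "IpscFitResults",
           "ParamSpec", "rank_and_select", "default_schedule"]

MISSED_LTS_PENALTY = 18.0
FALSE_LTS_PENALTY = 6.0
FIT_WINDOW_MS = 1800.0


@dataclass(frozen=True)
class FitWeights:
    w_m: float = 1.0     # LTS match
    w_sw: float = 1.0    # sweep voltage RMSE
    w_a: float = 1.0     # LTS amplitude
    w_t: float = 1.0     # LTS latency
    w_sl: float = 1.0    # LTS maximum slope
    sweep_weights: tuple | None = None

    def __post_init__(self):
        if max(self.w_m, self.w_sw, self.w_a, self.w_t, self.w_sl) <= 0:
            raise ValueError("at least one weight must be positive")


@dataclass(frozen=True)
class SimplexConfig:
    refl: float = 1.0       # reflection
    expan: float = 2.0      # expansion
    contr: float = 0.75     # contraction
    shrink: float = 0.8     # shrinkage
    init_spread: float = 2.0 / 3.0  # vertex displacement, fraction of range
    max_iter: int = 2000
    max_evals: int = 4000
    rel_err_tol: float = 0.1
    rel_param_tol: float = 0.1

    def __post_init__(self):
        assert self.refl > 0 and self.expan > 1
        assert 0 < self.contr < 1 and 0 < self.shrink < 1


def _trace_average(values: np.ndarray, weights: np.ndarray | None) -> float:
    """Plain mean for equal weights; weighted root-mean-square otherwise."""
    values = np.asarray(values, float)
    if values.size == 0:
        return 0.0
    if weights is None or np.allclose(weights, weights[0]):
        return float(values.mean())
    w = np.asarray(weights, float)
    return float(np.sqrt(np.sum(w * values ** 2) / np.sum(w)))


def _sweep_features(t, v, ipsc_onset, dt_filter_ms=30.0):
    """Median-filter (spike removal) then LTS-analyze one sweep."""
    dt = t[1] - t[0]
    n = max(3, int(round(dt_filter_ms / dt)) | 1)
    vf = median_filter(np.asarray(v, float), size=n, mode="reflect")
    res = analyze_sweep(t, vf, ipsc_onset)
    return vf, res


def total_error(sim_traces, target_traces, weights: FitWeights | None = None,
                ipsc_onset: float = 3000.0) -> dict:
    """Weighted multi-objective error between matched trace sets.

    Each trace is a ``(t, v)`` pair; sets must be aligned (same waveform
    order).  Feature errors are relative (fractions); E_sw is in mV.
    Components without any LTS-matching trace are dropped and the weights
    renormalized.
    """
    weights = weights or FitWeights()
    if len(sim_traces) != len(target_traces):
        raise ValueError("trace sets must align")
    n = len(sim_traces)
    sw = (np.asarray(weights.sweep_weights, float)
          if weights.sweep_weights is not None else None)
    e_m, e_sw = np.zeros(n), np.zeros(n)
    e_a, e_t, e_sl, match_w = [], [], [], []
    for i, ((ts, vs), (tt, vt)) in enumerate(zip(sim_traces, target_traces)):
        ts, vs = np.asarray(ts, float), np.asarray(vs, float)
        tt, vt = np.asarray(tt, float), np.asarray(vt, float)
        vfs, rs = _sweep_features(ts, vs, ipsc_onset)
        vft, rt = _sweep_features(tt, vt, ipsc_onset)
        if rt.has_lts and not rs.has_lts:
            e_m[i] = MISSED_LTS_PENALTY
        elif rs.has_lts and not rt.has_lts:
            e_m[i] = FALSE_LTS_PENALTY
        win_s = (ts >= ipsc_onset) & (ts <= ipsc_onset + FIT_WINDOW_MS)
        win_t = (tt >= ipsc_onset) & (tt <= ipsc_onset + FIT_WINDOW_MS)
        v_sim = np.interp(tt[win_t], ts[win_s], vfs[win_s])
        e_sw[i] = float(np.sqrt(np.mean((v_sim - vft[win_t]) ** 2)))
        if rs.has_lts and rt.has_lts:
            rng = max(np.ptp(vft[win_t]), 1e-9)
            e_a.append(abs(rs.peak_value - rt.peak_value) / rng)
            e_t.append(abs(rs.latency - rt.latency) / max(rt.latency, 1e-9))
            if np.isfinite(rs.max_slope) and np.isfinite(rt.max_slope):
                e_sl.append(abs(rs.max_slope - rt.max_slope)
                            / max(abs(rt.max_slope), 1e-9))
            match_w.append(sw[i] if sw is not None else 1.0)
    mw = np.asarray(match_w) if match_w else None
    comp = {
        "E_m": _trace_average(e_m, sw),
        "E_sw": _trace_average(e_sw, sw),
        "E_a": _trace_average(np.asarray(e_a), mw) if e_a else None,
        "E_t": _trace_average(np.asarray(e_t), mw) if e_t else None,
        "E_sl": _trace_average(np.asarray(e_sl), mw) if e_sl else None,
    }
    wmap = {"E_m": weights.w_m, "E_sw": weights.w_sw, "E_a": weights.w_a,
            "E_t": weights.w_t, "E_sl": weights.w_sl}
    num = sum(wmap[k] * v for k, v in comp.items() if v is not None)
    den = sum(wmap[k] for k, v in comp.items() if v is not None)
    comp["E_total"] = num / den if den > 0 else np.inf
    return comp


# ---------------------------------------------------------------------------
# bounded Nelder-Mead


def _to_unbounded(x, lo, hi):
    u = 2.0 * (np.asarray(x, float) - lo) / (hi - lo) - 1.0
    u = np.clip(u, -0.999999, 0.999999)
    return np.tan(np.pi * u / 2.0)


def _from_unbounded(z, lo, hi):
    u = 2.0 / np.pi * np.arctan(np.asarray(z, float))
    return lo + (u + 1.0) / 2.0 * (hi - lo)


def nelder_mead_bounded(objective, x0, bounds, cfg: SimplexConfig | None = None,
                        callback=None) -> dict:
    """Modified Nelder-Mead simplex inside finite bounds.

    Parameters are mapped linearly to [-1, 1] then through tan(pi u / 2) to
    the real line, guaranteeing every evaluation stays strictly inside the
    bounds.  Uses reflection 1, expansion 2, contraction 0.75, shrinkage 0.8
    and the stated iteration/evaluation/tolerance limits; non-finite
    objective values are treated as +inf.
    """
    cfg = cfg or SimplexConfig()
    lo = np.asarray([b[0] for b in bounds], float)
    hi = np.asarray([b[1] for b in bounds], float)
    if not np.all(np.isfinite(lo) & np.isfinite(hi) & (hi > lo)):
        raise ValueError("finite bounds required for every parameter")
    ndim = len(bounds)
    evals = {"n": 0}
    history = []

    def f(z):
        if evals["n"] >= cfg.max_evals:
            return np.inf
        x = _from_unbounded(z, lo, hi)
        val = objective(x)
        evals["n"] += 1
        if not np.isfinite(val):
            val = np.inf
        history.append((evals["n"], float(val)))
        return float(val)

    # initial simplex in the bounded [-1, 1] space: each vertex displaces one
    # parameter by init_spread of its total range (2 units), away from the
    # nearer bound
    u0 = 2.0 * (np.asarray(x0, float) - lo) / (hi - lo) - 1.0
    u0 = np.clip(u0, -0.99, 0.99)
    verts_u = [u0]
    d = cfg.init_spread * 2.0
    for j in range(ndim):
        u = u0.copy()
        u[j] = u[j] - d if u[j] > 0 else u[j] + d
        u[j] = np.clip(u[j], -0.999, 0.999)
        verts_u.append(u)
    simplex = [np.tan(np.pi * u / 2.0) for u in verts_u]
    fvals = np.array([f(z) for z in simplex])

    n_iter = 0
    while n_iter < cfg.max_iter and evals["n"] < cfg.max_evals:
        order = np.argsort(fvals)
        simplex = [simplex[i] for i in order]
        fvals = fvals[order]
        fb, fw = fvals[0], fvals[-1]
        # convergence: relative error spread and relative parameter spread
        if np.isfinite(fw):
            err_spread = 2.0 * abs(fw - fb) / (abs(fw) + abs(fb) + 1e-12)
            xb = _from_unbounded(simplex[0], lo, hi)
            xw = _from_unbounded(simplex[-1], lo, hi)
            par_spread = np.max(np.abs(xw - xb) / (np.abs(xb) + np.abs(xw) + 1e-12))
            if err_spread < cfg.rel_err_tol and par_spread < cfg.rel_param_tol:
                break
        centroid = np.mean(simplex[:-1], axis=0)
        xr = centroid + cfg.refl * (centroid - simplex[-1])
        fr = f(xr)
        if fr < fvals[0]:
            xe = centroid + cfg.expan * (xr - centroid)
            fe = f(xe)
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            xc = centroid + cfg.contr * (simplex[-1] - centroid)
            fc = f(xc)
            if fc < fvals[-1]:
                simplex[-1], fvals[-1] = xc, fc
            else:
                for i in range(1, len(simplex)):
                    simplex[i] = simplex[0] + cfg.shrink * (simplex[i] - simplex[0])
                    fvals[i] = f(simplex[i])
        n_iter += 1
        if callback is not None:
            callback(n_iter, _from_unbounded(simplex[0], lo, hi), fvals[0])

    order = np.argsort(fvals)
    zb = simplex[order[0]]
    return {"x_best": _from_unbounded(zb, lo, hi), "E_best": float(fvals[order[0]]),
            "n_iter": n_iter, "n_evals": evals["n"], "history": history}


# ---------------------------------------------------------------------------
# model-neuron fitting campaign


@dataclass(frozen=True)
class ParamSpec:
    """One fitted parameter: a density (log10 space) or geometry (linear)."""

    name: str                 # TCNeuronParams field or density column name
    compartments: tuple = ("soma", "dend1", "dend2")  # densities only
    low: float = np.nan
    high: float = np.nan
    log: bool = True

    def bounds_around(self, value: float):
        if np.isfinite(self.low) and np.isfinite(self.high):
            lo, hi = self.low, self.high
        elif self.log:
            lo, hi = value * 1e-2, value * 1e2   # +-2 orders around the seed
        else:
            lo, hi = value * 0.5, value * 2.0
        if self.log:
            return np.log10(lo), np.log10(hi)
        return lo, hi


DENSITY_COLUMNS = {"pbar_T": 0, "gbar_h": 1, "gbar_A": 2, "gbar_Kir": 3,
                   "gbar_NaP": 4}
GEOM_FIELDS = ("diam_soma", "diam_dend", "l_dend", "g_pas")
COMP_INDEX = {"soma": 0, "dend1": 1, "dend2": 2}


def _apply_params(base: TCNeuronParams, spec: list[ParamSpec],
                  x: np.ndarray) -> TCNeuronParams:
    dens = base.densities.copy()
    fields = {}
    i = 0
    for ps in spec:
        val = 10.0 ** x[i] if ps.log else x[i]
        if ps.name in DENSITY_COLUMNS:
            for comp in ps.compartments:
                dens[COMP_INDEX[comp], DENSITY_COLUMNS[ps.name]] = val
        elif ps.name in GEOM_FIELDS:
            fields[ps.name] = val
        else:
            raise KeyError(f"unknown parameter {ps.name!r}")
        i += 1
    return replace(base, densities=dens, **fields)


def _initial_values(base: TCNeuronParams, spec: list[ParamSpec]) -> np.ndarray:
    out = []
    for ps in spec:
        if ps.name in DENSITY_COLUMNS:
            v = base.densities[COMP_INDEX[ps.compartments[0]],
                               DENSITY_COLUMNS[ps.name]]
        else:
            v = getattr(base, ps.name)
        out.append(np.log10(v) if ps.log else v)
    return np.asarray(out)


def default_schedule(n_per_phase: int = 1) -> list[FitWeights]:
    """Coarse-to-fine weight schedule: LTS match first, then timing, then the
    full trace shape."""
    phases = [FitWeights(w_m=3, w_sw=0.5, w_a=0.5, w_t=0.5, w_sl=0.5),
              FitWeights(w_m=2, w_sw=1, w_a=1, w_t=3, w_sl=1),
              FitWeights(w_m=1, w_sw=2, w_a=1, w_t=1, w_sl=1)]
    return [w for w in phases for _ in range(n_per_phase)]


class IpscResponseModel:
    """TC-neuron model fitted to a set of IPSC-response target sweeps.

    Parameters
    ----------
    targets : list of dicts with keys ``kinetics`` (GababKinetics),
        ``t`` (ms), ``v`` (mV somatic voltage), recorded or synthesized.
    base_params : seed TCNeuronParams (passive estimates + literature
        density seeds).
    fit_spec : list of ParamSpec naming the free parameters.
    v_hold : holding potential of the protocol (mV).
    """

    def __init__(self, targets, base_params: TCNeuronParams,
                 fit_spec: list[ParamSpec], v_hold: float = -70.0,
                 t_total: float = 5000.0, dt: float = 0.1,
                 ipsc_onset: float = 3000.0, rec_dt: float = 1.0):
        if not targets:
            raise ValueError("no target sweeps")
        self.targets = targets
        self.base_params = base_params
        self.fit_spec = fit_spec
        self.v_hold = v_hold
        self.t_total = t_total
        self.dt = dt
        self.ipsc_onset = ipsc_onset
        self.rec_dt = rec_dt
        self._target_pairs = [(np.asarray(tg["t"], float),
                               np.asarray(tg["v"], float)) for tg in targets]

    def simulate(self, params: TCNeuronParams):
        """Simulated (t, v) pairs for every target waveform (no fast Na/K)."""
        model = TCModel(replace(params, gbar_na=0.0, gbar_k=0.0))
        out = []
        for tg in self.targets:
            tr = model.run_ipsc_protocol(tg["kinetics"], v_hold=self.v_hold,
                                         dt=self.dt, t_total=self.t_total,
                                         rec_dt=self.rec_dt,
                                         ipsc_onset=self.ipsc_onset)
            out.append((tr.t, tr.v_soma))
        return out

    def _objective(self, weights):
        def fun(x):
            try:
                params = _apply_params(self.base_params, self.fit_spec, x)
                sims = self.simulate(params)
            except (FloatingPointError, ValueError):
                return np.inf  # divergent candidates are penalized, not fatal
            return total_error(sims, self._target_pairs, weights,
                               self.ipsc_onset)["E_total"]
        return fun

    def fit(self, schedule: list[FitWeights] | None = None,
            cfg: SimplexConfig | None = None, seed: int = 0,
            max_evals_per_run: int = 120) -> "IpscFitResults":
        """Run the simplex under the weight schedule with warm restarts."""
        schedule = schedule or default_schedule()
        cfg = cfg or SimplexConfig()
        cfg = replace(cfg, max_evals=max_evals_per_run)
        x = _initial_values(self.base_params, self.fit_spec)
        bounds = [ps.bounds_around(10.0 ** x0 if ps.log else x0)
                  for ps, x0 in zip(self.fit_spec, x)]
        runs = []
        best_x, best_e = x, np.inf
        for phase, weights in enumerate(schedule):
            res = nelder_mead_bounded(self._objective(weights), best_x,
                                      bounds, cfg)
            runs.append({"phase": phase, "weights": weights,
                         "E_best": res["E_best"], "n_evals": res["n_evals"]})
            if res["E_best"] <= best_e:
                best_x, best_e = res["x_best"], res["E_best"]
        params = _apply_params(self.base_params, self.fit_spec, best_x)
        sims = self.simulate(params)
        comp = total_error(sims, self._target_pairs, FitWeights(),
                           self.ipsc_onset)
        return IpscFitResults(model=self, params=params, x_best=best_x,
                              errors=comp, runs=runs, seed=seed)


@dataclass
class IpscFitResults:
    model: IpscResponseModel
    params: TCNeuronParams
    x_best: np.ndarray
    errors: dict
    runs: list
    seed: int = 0

    @property
    def e_total(self) -> float:
        return float(self.errors["E_total"])

    def summary(self) -> str:
        lines = ["IPSC-response fit", "=" * 45]
        for ps, val in zip(self.model.fit_spec, self.x_best):
            v = 10.0 ** val if ps.log else val
            lines.append(f"{ps.name:12s} = {v:10.4g}"
                         + (f"  ({','.join(ps.compartments)})"
                            if ps.name in DENSITY_COLUMNS else ""))
        lines.append("-" * 45)
        for k in ("E_m", "E_sw", "E_a", "E_t", "E_sl", "E_total"):
            v = self.errors.get(k)
            lines.append(f"{k:8s} = {'--' if v is None else f'{v:.4f}'}")
        return "\n".join(lines)


def rank_and_select(total_errors, z: float = 2.0):
    """Rank a fitted cohort and flag the well-fitted subset.

    Neurons whose total error exceeds the cohort mean by more than ``z``
    standard deviations are excluded; the rest are well-fitted.  Returns
    (ranks, well_fitted_mask) with rank 1 = lowest error.
    """
    e = np.asarray(total_errors, float)
    ranks = np.empty(len(e), dtype=int)
    ranks[np.argsort(e)] = np.arange(1, len(e) + 1)
    mask = e <= e.mean() + z * e.std()
    return ranks, mask
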