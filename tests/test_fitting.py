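"""Multi-objective error, bounded Nelder-Mead, and model-neuron fitting."""

import dataclasses

import numpy as np
import pytest

from thalburst import (FitWeights, IpscResponseModel, ParamSpec, SimplexConfig,
                       TCModel, condition_params, nelder_mead_bounded,
                       rank_and_select, reference_neuron, total_error)
from thalburst.gabab import CONDITIONS


def bump_trace(has_lts, peak=-30.0, latency=800.0, t_end=5200.0):
    """Synthetic post-IPSC sweep with or without an LTS-like bump."""
    t = np.arange(0.0, t_end, 1.0)
    v = np.full_like(t, -70.0)
    v -= 12.0 * np.exp(-0.5 * ((t - 3200.0) / 120.0) ** 2)  # IPSC dip
    if has_lts:
        v += (peak + 70.0) * np.exp(-0.5 * ((t - 3000.0 - latency) / 40.0) ** 2)
    return t, v


class TestTotalError:
    def test_identical_traces_give_zero_shape_errors(self):
        tr = bump_trace(True)
        comp = total_error([tr], [tr])
        assert comp["E_sw"] == 0.0
        assert comp["E_a"] == 0.0 and comp["E_t"] == 0.0
        assert comp["E_m"] == 0.0

    def test_missed_lts_costs_18_false_lts_costs_6(self):
        with_l, without = bump_trace(True), bump_trace(False)
        missed = total_error([without], [with_l])
        false = total_error([with_l], [without])
        assert missed["E_m"] == 18.0
        assert false["E_m"] == 6.0

    def test_two_trace_toy_matches_manual_arithmetic(self):
        """Unit weights, one matching pair and one missed LTS; E_total
        reproduces the hand-computed weighted average."""
        a = bump_trace(True)
        b = bump_trace(False)
        comp = total_error([a, b], [a, a])
        # E_m = (0 + 18)/2 = 9; shape errors: first pair identical, second
        # contributes RMSE of the bump over the fit window
        assert comp["E_m"] == 9.0
        t, va = a
        _, vb = b
        from scipy.ndimage import median_filter

        w = (t >= 3000.0) & (t <= 4800.0)
        f = lambda v: median_filter(v, size=31, mode="reflect")
        rms = np.sqrt(np.mean((f(vb)[w] - f(va)[w]) ** 2))
        assert comp["E_sw"] == pytest.approx(rms / 2.0, rel=1e-6)
        manual = (1 * comp["E_m"] + 1 * comp["E_sw"] + comp["E_a"]
                  + comp["E_t"] + comp["E_sl"]) / 5.0
        assert comp["E_total"] == pytest.approx(manual)

    def test_permutation_invariance(self):
        a, b = bump_trace(True), bump_trace(True, peak=-35.0, latency=950.0)
        c1 = total_error([a, b], [b, a])
        c2 = total_error([b, a], [a, b])
        assert c1["E_total"] == pytest.approx(c2["E_total"])

    def test_weight_renormalization_without_matching_traces(self):
        a, b = bump_trace(True), bump_trace(False)
        comp = total_error([b], [a])  # no LTS-matching trace
        assert comp["E_a"] is None
        assert np.isfinite(comp["E_total"])

    def test_misaligned_sets_rejected(self):
        with pytest.raises(ValueError):
            total_error([bump_trace(True)], [])

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            FitWeights(w_m=0, w_sw=0, w_a=0, w_t=0, w_sl=0)


class TestNelderMead:
    TIGHT = SimplexConfig(rel_err_tol=1e-6, rel_param_tol=1e-6)

    def test_convex_quadratic_converges(self):
        f = lambda x: (x[0] - 1.0) ** 2 + 2.0 * (x[1] + 0.5) ** 2
        res = nelder_mead_bounded(f, [0.0, 0.0], [(-5, 5), (-5, 5)], self.TIGHT)
        assert np.allclose(res["x_best"], [1.0, -0.5], atol=1e-3)

    def test_never_leaves_bounds(self):
        seen = []

        def f(x):
            seen.append(x.copy())
            return (x[0] - 10.0) ** 2 + x[1] ** 2

        res = nelder_mead_bounded(f, [0.0, 0.0], [(-1, 2), (-1, 1)], self.TIGHT)
        seen = np.array(seen)
        assert np.all(seen[:, 0] >= -1) and np.all(seen[:, 0] <= 2)
        assert 1.9 < res["x_best"][0] <= 2.0  # pushed to the boundary

    def test_rosenbrock_beats_reference_at_equal_budget(self):
        from scipy.optimize import minimize

        ros = lambda x: (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2
        cfg = SimplexConfig(rel_err_tol=1e-12, rel_param_tol=1e-12,
                            max_evals=400)
        ours = nelder_mead_bounded(ros, [-1.2, 1.0], [(-5, 5), (-5, 5)], cfg)
        ref = minimize(ros, [-1.2, 1.0], method="Nelder-Mead",
                       options=dict(maxfev=400, xatol=1e-12, fatol=1e-12))
        assert ours["E_best"] <= ref.fun * 10 + 1e-9

    def test_nonfinite_objective_survives(self):
        f = lambda x: np.inf if x[0] < 0 else x[0] ** 2 + x[1] ** 2
        res = nelder_mead_bounded(f, [1.0, 1.0], [(-2, 2), (-2, 2)], self.TIGHT)
        assert res["E_best"] < 1e-4

    def test_infinite_bounds_rejected(self):
        with pytest.raises(ValueError):
            nelder_mead_bounded(lambda x: 0.0, [0.0], [(-np.inf, 1.0)])


class TestCohortSelection:
    def test_two_sd_exclusion_rule(self, rng):
        errors = np.concatenate([rng.normal(2.0, 0.3, 31), [8.0, 9.0]])
        ranks, mask = rank_and_select(errors)
        assert mask.sum() == 31
        assert not mask[-1] and not mask[-2]
        assert ranks[np.argmin(errors)] == 1

    def test_ranks_are_a_permutation(self, rng):
        e = rng.random(10)
        ranks, _ = rank_and_select(e)
        assert sorted(ranks) == list(range(1, 11))


@pytest.fixture(scope="module")
def recovery():
    """Fit dendritic T density and leak back from noiseless targets
    generated by the reference neuron (perturbed starting point)."""
    truth = reference_neuron()
    gen = TCModel(truth)
    targets = []
    for cond in CONDITIONS:
        k = condition_params(cond).with_scale(2.0)
        tr = gen.run_ipsc_protocol(k, t_total=5000.0, rec_dt=1.0)
        targets.append({"kinetics": k, "t": tr.t, "v": tr.v_soma})
    dens = truth.densities.copy()
    dens[1, 0] = dens[2, 0] = 1.5e-4
    seed_params = dataclasses.replace(truth, densities=dens,
                                      g_pas=truth.g_pas * 1.8)
    model = IpscResponseModel(
        targets, seed_params,
        [ParamSpec("pbar_T", ("dend1", "dend2"), low=5e-5, high=5e-3),
         ParamSpec("g_pas", low=3e-5, high=6e-4)],
        t_total=5000.0)
    res = model.fit(seed=0, max_evals_per_run=40)
    return truth, targets, res


class TestSelfRecovery:
    def test_lts_pattern_matches_on_every_waveform(self, recovery):
        truth, targets, res = recovery
        assert res.errors["E_m"] == 0.0

    def test_summary_lists_parameters_and_errors(self, recovery):
        *_, res = recovery
        s = res.summary()
        assert "pbar_T" in s and "E_total" in s

    def test_reproducible_given_seed(self, recovery):
        truth, targets, res = recovery
        model2 = IpscResponseModel(
            targets, res.model.base_params, res.model.fit_spec,
            t_total=5000.0)
        res2 = model2.fit(seed=0, max_evals_per_run=40)
        assert res2.e_total == pytest.approx(res.e_total)
        assert np.allclose(res2.x_best, res.x_best)
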