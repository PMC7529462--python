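"""Oscillation metrics: spike detection, bursts, period, OI, phase average."""

import numpy as np
import pytest

from thalburst.oscillations import (estimate_period, group_bursts,
                                    network_metrics, oscillatory_index,
                                    period_distance, phase_average,
                                    trial_oscillation)


class TestSignalToNoiseFormula:
    def test_identities(self):
        r = lambda beta_over_alpha: 1.0 + 0.1 * (beta_over_alpha - 1.0)
        assert r(1.0) == pytest.approx(1.0)
        assert r(5.0) == pytest.approx(1.4)


class TestGroupBursts:
    def test_empty(self):
        bursts, dur = group_bursts([], 1000.0)
        assert bursts == [] and dur == 0.0

    def test_continuous_train(self):
        spikes = np.arange(1000.0, 6000.0, 9.0)  # ~110 Hz for 5 s
        bursts, dur = group_bursts(spikes, 1000.0)
        assert len(bursts) == 1
        assert dur == pytest.approx(5000.0, abs=20.0)

    def test_manual_walkthrough(self):
        """Three candidate bursts, one 40 ms sub-threshold run, and one gap
        beyond 2 s: exactly two bursts survive and the duration stops at the
        second burst's end."""
        def burst(t0, length, step=8.0):
            return np.arange(t0, t0 + length, step)

        spikes = np.concatenate([
            burst(1100.0, 100.0),     # burst 1
            burst(1700.0, 40.0),      # too short (40 ms < 60 ms)
            burst(2400.0, 80.0),      # burst 2
            burst(5200.0, 300.0),     # follows a 2.7 s gap: chain broken
        ])
        bursts, dur = group_bursts(spikes, 1000.0)
        assert len(bursts) == 2
        assert dur == pytest.approx(2480.0 - 1000.0, abs=20.0)

    def test_first_burst_must_start_within_2s(self):
        spikes = np.arange(3500.0, 4000.0, 8.0)
        bursts, dur = group_bursts(spikes, 1000.0)
        assert bursts == [] and dur == 0.0

    def test_duration_invariant_to_spikes_after_chain_break(self):
        base = np.arange(1100.0, 3000.0, 8.0)
        extra = np.concatenate([base, np.arange(7000.0, 7500.0, 8.0)])
        _, d1 = group_bursts(base, 1000.0)
        _, d2 = group_bursts(extra, 1000.0)
        assert d1 == d2


def periodic_bursts(period=500.0, n=12, jitter=0.0, rng=None,
                    start=1100.0, spikes_per=12):
    out = []
    for k in range(n):
        t0 = start + k * period
        if jitter and rng is not None:
            t0 += rng.normal(0.0, jitter)
        out.extend(t0 + 7.0 * np.arange(spikes_per))
    return np.asarray(out)


class TestPeriod:
    def test_exactly_periodic(self):
        spikes = periodic_bursts(period=500.0)
        _, dur = group_bursts(spikes, 1000.0)
        per = estimate_period(spikes, 1000.0, dur)
        assert per == pytest.approx(500.0, abs=10.0)

    def test_matches_bruteforce_grid_minimization(self, rng):
        spikes = periodic_bursts(period=470.0, jitter=20.0, rng=rng)
        _, dur = group_bursts(spikes, 1000.0)
        per = estimate_period(spikes, 1000.0, dur)
        # independent dense-grid oracle over the same distance function
        from thalburst.oscillations import _acf_peaks, _filtered_acf

        lags, facf = _filtered_acf(spikes, 1000.0, dur, 10.0)
        pk = _acf_peaks(lags, facf)
        peaks = lags[pk]
        d0 = peaks[0]
        grid = np.arange(2 * d0 / 3, 1.5 * d0 + 0.01, 0.01)
        oracle = grid[np.argmin([period_distance(d, peaks) for d in grid])]
        assert per == pytest.approx(oracle, abs=1.0)

    def test_undefined_without_two_peaks(self):
        spikes = np.arange(1100.0, 1250.0, 8.0)  # one burst only
        _, dur = group_bursts(spikes, 1000.0)
        assert np.isnan(estimate_period(spikes, 1000.0, dur))


class TestOscillatoryIndex:
    def test_perfectly_rhythmic_near_one(self):
        spikes = periodic_bursts(period=500.0, n=16)
        _, dur = group_bursts(spikes, 1000.0)
        oi = oscillatory_index(spikes, 1000.0, dur)
        assert 0.5 < oi <= 1.0

    def test_decreases_with_jitter(self, rng):
        ois = []
        for jit in (0.0, 40.0, 120.0):
            r = np.random.default_rng(7)
            spikes = periodic_bursts(period=500.0, n=16, jitter=jit, rng=r)
            _, dur = group_bursts(spikes, 1000.0)
            ois.append(oscillatory_index(spikes, 1000.0, dur))
        assert ois[0] > ois[1] > ois[2]

    def test_zero_without_secondary_peak(self):
        spikes = np.arange(1100.0, 1400.0, 8.0)
        _, dur = group_bursts(spikes, 1000.0)
        assert oscillatory_index(spikes, 1000.0, dur) == 0.0


class TestPhaseAverage:
    def test_identical_values(self):
        val, fb = phase_average([3.0] * 10)
        assert val == 3.0 and not fb

    def test_outliers_excluded(self):
        vals = [1.0] * 8 + [5.0, 5.0]
        val, fb = phase_average(vals)
        assert val == pytest.approx(1.0) and not fb

    def test_permutation_invariant(self, rng):
        vals = list(rng.normal(10.0, 0.5, 10))
        v1, _ = phase_average(vals)
        v2, _ = phase_average(vals[::-1])
        assert v1 == pytest.approx(v2)

    def test_fallback_flag_on_wild_scatter(self, rng):
        vals = [1.0, 100.0, 2.0, 55.0, 7.0, 30.0, 0.1, 80.0, 3.0, 60.0]
        val, fb = phase_average(vals)
        assert fb
        assert val == pytest.approx(np.mean(vals[-5:]))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            phase_average([1.0, 2.0])


class TestNetworkMetrics:
    def test_silent_raster(self):
        trials = [trial_oscillation(np.array([]), 3040.0) for _ in range(4)]
        m = network_metrics(trials, [np.array([])] * 4, n_tc=20,
                            stim_start=3040.0)
        assert m.oscillation_probability == 0.0
        assert m.percent_active_tc == 0.0

    def test_three_bursts_count_as_oscillation(self):
        spikes = periodic_bursts(period=600.0, n=3, start=3140.0,
                                 spikes_per=80)
        tr = trial_oscillation(spikes, 3040.0)
        assert tr["oscillated"]
        m = network_metrics([tr], [np.array([3200.0])], n_tc=20,
                            stim_start=3040.0)
        assert m.oscillation_probability == 1.0

    def test_half_activation_latency_manual_fixture(self):
        # 5 TC cells activate at known latencies; the half-activation time is
        # the median first-spike latency of the finally active set
        first = np.array([3100.0, 3200.0, 3400.0, 3900.0, 4400.0])
        tr = trial_oscillation(periodic_bursts(period=500.0, n=4,
                                               start=3140.0, spikes_per=80),
                               3040.0)
        m = network_metrics([tr], [first], n_tc=10, stim_start=3040.0)
        assert m.percent_active_tc == pytest.approx(50.0)
        assert m.half_activation_latency == pytest.approx(3400.0 - 3040.0)
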