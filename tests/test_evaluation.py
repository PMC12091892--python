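"""Metrics, sliding-window profiles, cell characterization, unit selection."""

import numpy as np
import pytest

from suppfilt import core
from suppfilt.core import (EncodingModel, TentNonlinearity, KNOTS, N_KNOTS,
                           forward, sample_spikes)
from suppfilt.evaluation import (CellRecord, Psth, WindowProfile,
                                 asymmetry_index, classify_transiency,
                                 dedup_units, detect_on_off, filter_shift,
                                 info_per_spike, info_per_spike_feedback,
                                 low_frequency_performance,
                                 performance_range,
                                 poisson_explained_variance, psth_from_trials,
                                 r2, select_units, sliding_window_r2,
                                 split_half_reliability)
from suppfilt.stimulus import generate_white_noise
from conftest import random_model


class TestInfoPerSpike:
    def test_mean_rate_predictor_gives_zero(self, rng):
        counts = rng.poisson(0.5, 500)
        pred = np.full(500, counts.mean())
        assert info_per_spike(counts, pred) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        counts = np.array([2.0, 0.0])
        pred = np.array([2.0, 1e-12])
        # LL(pred) = 2 ln 2 - 2 - 1e-12; LL(mean=1) = -2; diff = 2 ln 2
        expected = (2 * np.log(2.0) - 1e-12) / (2 * np.log(2.0))
        assert info_per_spike(counts, pred) == pytest.approx(expected)

    def test_negative_values_not_clipped(self, rng):
        counts = rng.poisson(1.0, 200)
        bad_pred = np.where(counts > 0, 1e-6, 5.0)  # anti-predictive
        assert info_per_spike(counts, bad_pred) < 0

    def test_zero_spikes_error(self):
        with pytest.raises(ValueError):
            info_per_spike(np.zeros(10), np.ones(10))


class TestInfoPerSpikeFeedback:
    def test_zero_feedback_equals_ln_info(self, rng):
        model = random_model("feedback", rng)
        model.fb_taps = np.zeros_like(model.fb_taps)
        x = rng.standard_normal(1000)
        counts = sample_spikes(forward(model, x, np.zeros(1000)), seed=1)
        ln_rate = core.eval_rectifier(model.rectifier, model.exc_signal(x))
        expected = info_per_spike(counts, ln_rate)
        got = info_per_spike_feedback(model, x, counts, n_eval=3, seed=2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_reproducible_and_averaging_shrinks_spread(self, rng):
        model = random_model("feedback", rng)
        x = rng.standard_normal(1000)
        _, cts = core.free_running_forward(model, x, seed=3)
        counts = cts[0].astype(np.int64)
        a = info_per_spike_feedback(model, x, counts, n_eval=5, seed=7)
        b = info_per_spike_feedback(model, x, counts, n_eval=5, seed=7)
        assert a == b
        singles = [info_per_spike_feedback(model, x, counts, n_eval=1, seed=s)
                   for s in range(20)]
        averaged = [info_per_spike_feedback(model, x, counts, n_eval=25,
                                            seed=100 + s) for s in range(6)]
        assert np.std(averaged) < np.std(singles) / 2.0


class TestPoissonExplainedVariance:
    def test_trivial_endpoints(self, rng):
        r = rng.poisson(2.0, 100).astype(float) + 0.1
        psth = Psth(r, 10, 60.0)
        assert poisson_explained_variance(psth, r) == pytest.approx(1.0)
        mean_pred = np.full(100, r.mean())
        assert poisson_explained_variance(psth, mean_pred) \
            == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_deviances(self):
        r = np.array([1.0, 3.0])
        pred = np.array([1.5, 2.2])
        dev1 = 2 * ((1 * np.log(1 / 1.5) - (1 - 1.5))
                    + (3 * np.log(3 / 2.2) - (3 - 2.2)))
        dev0 = 2 * ((1 * np.log(1 / 2) - (1 - 2))
                    + (3 * np.log(3 / 2) - (3 - 2)))
        assert poisson_explained_variance(r, pred) \
            == pytest.approx(1 - dev1 / dev0)

    def test_zero_rate_bins_allowed(self):
        r = np.array([0.0, 2.0, 0.0, 4.0])
        val = poisson_explained_variance(r, np.array([0.1, 2, 0.1, 4.0]))
        assert np.isfinite(val)

    def test_nonpositive_prediction_floored_with_warning(self):
        with pytest.warns(UserWarning):
            poisson_explained_variance(np.array([1.0, 2.0]),
                                       np.array([0.0, 2.0]))


class TestR2:
    def test_trivials(self, rng):
        r = rng.normal(2, 1, 50)
        assert r2(r, r) == pytest.approx(1.0)
        assert r2(r, np.full(50, r.mean())) == pytest.approx(0.0, abs=1e-12)
        assert r2(np.array([0.0, 2.0]), np.array([1.0, 1.0])) \
            == pytest.approx(0.0)

    def test_anticorrelated_negative(self):
        r = np.array([0.0, 1.0, 2.0, 3.0])
        assert r2(r, r[::-1].copy()) < 0

    def test_zero_variance_undefined(self):
        assert np.isnan(r2(np.ones(5), np.ones(5)))


class TestSlidingWindow:
    def test_window_count_and_axis(self):
        n = 480
        rates = np.abs(np.sin(np.arange(n) / 7.0)) + 0.05
        axis = np.linspace(0, 15, n)
        prof = sliding_window_r2(rates, rates * 1.0, axis, 60.0)
        assert prof.r2.size == 472  # 480 - 9 + 1
        assert prof.window_start_axis[0] == 0.0
        assert np.all(prof.r2[np.isfinite(prof.r2)]
                      == pytest.approx(1.0))

    def test_performance_range(self):
        axis = np.linspace(0, 100, 101)
        vals = np.where((axis >= 20) & (axis <= 80), 0.5, -0.1)
        lo, hi, width = performance_range(WindowProfile(axis, vals))
        assert (lo, hi, width) == (20.0, 80.0, 60.0)
        assert performance_range(WindowProfile(axis, -np.ones(101)))[2] == 0.0
        full = performance_range(WindowProfile(axis, np.ones(101)))
        assert full == (0.0, 100.0, 100.0)

    def test_low_frequency_performance(self):
        axis = np.arange(20.0)
        vals = np.concatenate([np.linspace(1.0, 0.1, 10), np.zeros(10)])
        prof = WindowProfile(axis, vals)
        assert low_frequency_performance(prof) == pytest.approx(0.55)
        with pytest.warns(UserWarning):
            short = WindowProfile(axis[:5], vals[:5])
            low_frequency_performance(short)


class TestFilterShift:
    def test_identical_and_delayed(self):
        from suppfilt.synthetic import biphasic_taps

        k = biphasic_taps(15, "fast", -1)
        assert filter_shift(k, k) == 0
        delayed = np.zeros_like(k)
        delayed[2:] = k[:-2]
        assert filter_shift(k, delayed) == 2

    def test_matches_numpy_correlate(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        got = filter_shift(a, b)
        c = np.correlate(b, a, mode="full")  # lag = index - (n-1)
        assert got == int(np.argmax(c)) - 11


class TestAsymmetryIndex:
    def test_symmetric_bump_is_zero(self):
        w = np.exp(-KNOTS ** 2)
        assert asymmetry_index(TentNonlinearity(w, "bump")) \
            == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_is_one(self):
        w = np.full(N_KNOTS, 1e-16)
        w[:7] = 0.5
        w[7] = 1.0
        nl = TentNonlinearity(core.project_bump_weights(w), "bump")
        assert asymmetry_index(nl) == pytest.approx(1.0, abs=1e-10)

    def test_hand_built_value(self):
        w = np.full(N_KNOTS, 1e-16)
        w[5], w[6] = 0.4, 0.8
        w[8], w[9] = 0.6, 0.2
        w[7] = 1.0
        nl = TentNonlinearity(core.project_bump_weights(w), "bump")
        assert asymmetry_index(nl) == pytest.approx(abs(1.2 - 0.8) / 2.0)


class TestTransiency:
    def _psth(self, peak, sustained):
        fr = 60.0
        rates = np.zeros(300)
        segs = [("background", 0, 120), ("on_step", 120, 180),
                ("off_step", 180, 240), ("background", 240, 300)]
        rates[120:132] = peak          # first 200 ms of the ON step
        rates[180 - 42:180] = 0.0
        rates[132:180] = sustained
        return Psth(rates, 15, fr), segs

    def test_transient_and_sustained(self):
        psth, segs = self._psth(10.0, 1.0)
        assert classify_transiency(psth, segs) == "transient"
        psth, segs = self._psth(10.0, 3.0)
        assert classify_transiency(psth, segs) == "sustained"

    def test_boundary_is_strict(self):
        psth, segs = self._psth(10.0, 2.0)  # ratio exactly 0.2
        assert classify_transiency(psth, segs) == "sustained"

    def test_preferred_step_by_larger_peak(self):
        fr = 60.0
        rates = np.zeros(240)
        segs = [("on_step", 0, 60), ("off_step", 60, 120)]
        rates[0:12] = 2.0    # weak ON peak, sustained
        rates[12:60] = 1.9
        rates[60:72] = 20.0  # strong OFF peak, transient
        assert classify_transiency(Psth(rates, 15, fr), segs) == "transient"


class TestDetectOnOff:
    def _nl_from_slopes(self, sL, sR):
        w = np.empty(N_KNOTS)
        w[:7] = sL * KNOTS[:7] + 3.0
        w[7] = 3.0
        w[8:] = sR * KNOTS[8:] + 3.0
        return TentNonlinearity(w - w.min() + 0.1, "monotone") \
            if np.all(np.diff(w) >= 0) else None

    def test_u_shape_detected(self):
        # symmetric U: sL=-1, sR=1 -> index -0.5 < -0.2
        w = np.abs(KNOTS) + 0.1
        nl = TentNonlinearity.__new__(TentNonlinearity)
        nl.weights, nl.shape_class = w, "monotone"
        assert detect_on_off(nl) is True

    def test_monotone_not_detected(self):
        w = KNOTS + 3.1  # sL = sR = 1 -> index +0.5
        nl = TentNonlinearity(w, "monotone")
        assert detect_on_off(nl) is False

    def test_weak_left_slope_not_detected(self):
        # sL=-0.1, sR=0.9 -> -0.1 > -0.2
        w = np.empty(N_KNOTS)
        w[:7] = -0.1 * KNOTS[:7]
        w[7] = 0.05
        w[8:] = 0.9 * KNOTS[8:]
        nl = TentNonlinearity.__new__(TentNonlinearity)
        nl.weights, nl.shape_class = w, "monotone"
        assert detect_on_off(nl) is False


class TestSelection:
    def _stationary_cell(self, seed=71):
        rng = np.random.default_rng(seed)
        fr = 60.0
        rate = 0.2  # 12 sp/s
        counts = rng.poisson(rate, 18000)
        psth_rate = 0.1 + 4.0 * np.abs(np.sin(np.arange(300) / 5.0))
        trials = rng.poisson(psth_rate, size=(16, 300))
        nl = TentNonlinearity(np.sort(rng.uniform(0, 2, N_KNOTS)), "monotone")
        return CellRecord(counts=counts, frame_rate_hz=fr, species="marmoset",
                          trial_counts=trials, ln_nonlinearity=nl,
                          train_info={"LN": 0.5}, test_info={"LN": 0.45})

    def test_stationary_reliable_cell_passes(self):
        df = select_units([self._stationary_cell()])
        row = df.iloc[0]
        assert row[["rate", "reliability", "stationarity",
                    "not_on_off", "generalization"]].all()

    def test_rate_drift_fails_stationarity(self):
        rec = self._stationary_cell()
        rng = np.random.default_rng(72)
        ramp = np.linspace(0.1, 0.4, 18000)  # rate doubles and more
        rec.counts = rng.poisson(ramp)
        df = select_units([rec])
        assert not df.iloc[0]["stationarity"]
        assert df.iloc[0]["rate"]  # still fires enough on average

    def test_overfit_cell_fails_generalization(self):
        rec = self._stationary_cell()
        rec.train_info = {"LN": 0.5, "divisive": 0.6}
        rec.test_info = {"LN": 0.45, "divisive": 0.2}
        assert not select_units([rec]).iloc[0]["generalization"]

    def test_odd_trial_count_allowed(self):
        rng = np.random.default_rng(73)
        trials = rng.poisson(1.0, size=(7, 200))
        val = split_half_reliability(trials, seed=1)
        assert np.isfinite(val)


class TestDedup:
    def test_identical_pair_reduced(self, rng):
        a = rng.poisson(1.0, 5000).astype(float)
        kept = dedup_units(np.vstack([a, a]))
        assert kept == [0]

    def test_independent_cells_kept(self, rng):
        R = rng.poisson(1.0, size=(5, 10000)).astype(float)
        assert dedup_units(R) == [0, 1, 2, 3, 4]

    def test_correlated_triplet_reduced_to_one(self, rng):
        base = rng.normal(1.0, 0.5, 5000)
        trio = [np.maximum(base + rng.normal(0, 0.1, 5000), 0)
                for _ in range(3)]
        others = [rng.poisson(1.0, 5000).astype(float) for _ in range(2)]
        kept = dedup_units(np.vstack(trio + others))
        assert kept == [0, 3, 4]


class TestPsth:
    def test_from_trials(self):
        trials = np.array([[0, 2], [2, 0]])
        psth = psth_from_trials(trials, 60.0)
        np.testing.assert_array_equal(psth.rates, [1.0, 1.0])
        assert psth.n_trials == 2

    def test_validation(self):
        with pytest.raises(ValueError):
            Psth(np.array([-1.0]), 1, 60.0)
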