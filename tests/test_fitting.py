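"""Block-coordinate constrained ML: likelihood, contexts, gradients,
block updates, initialization, full fits."""

import numpy as np
import pytest

from suppfilt import core
from suppfilt.core import (EncodingModel, TemporalFilter, TentNonlinearity,
                           N_KNOTS, WEIGHT_FLOOR, forward, sample_spikes)
from suppfilt.fitting import (SuppressionModel, block_objective,
                              blocks_for_kind, constraint_audit, fit_block,
                              fit_model, initialize_run, make_block_context,
                              negative_log_likelihood, nll_gradient,
                              valid_train_mask)
from suppfilt.stimulus import build_schedule, generate_white_noise
from suppfilt.sta import compute_stc_features
from conftest import random_model


class TestNegativeLogLikelihood:
    def test_zero_counts(self):
        rate = np.array([0.5, 1.5, 2.0])
        assert negative_log_likelihood(rate, np.zeros(3)) \
            == pytest.approx(rate.sum())

    def test_toy_value(self):
        val = negative_log_likelihood(np.array([1.0, 2.0]),
                                      np.array([1, 2]))
        assert val == pytest.approx(3.0 - np.log(2.0))

    def test_minimized_at_mean_rate(self, rng):
        counts = rng.poisson(1.3, 200)
        grid = np.linspace(0.5, 3.0, 101)
        vals = [negative_log_likelihood(np.full(200, g), counts)
                for g in grid]
        assert grid[np.argmin(vals)] == pytest.approx(counts.mean(), abs=0.02)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            negative_log_likelihood(np.ones(3), np.ones(4))


class TestBlockContext:
    def setup_method(self):
        self.rng = np.random.default_rng(7)
        self.x = self.rng.standard_normal(200)
        self.counts = self.rng.poisson(0.3, 200)

    def test_subtractive_sup_row(self):
        m = random_model("subtractive", self.rng)
        ctx = make_block_context(m, "sup_filter", self.x, self.counts)
        np.testing.assert_array_equal(ctx.X, self.x)
        np.testing.assert_allclose(ctx.P, m.exc_signal(self.x))
        assert ctx.sign_branch == -1 and ctx.M == 1.0 and ctx.A == 0.0

    def test_feedback_exc_row(self):
        m = random_model("feedback", self.rng)
        ctx = make_block_context(m, "exc_filter", self.x, self.counts)
        assert ctx.M == 1.0 and ctx.P == 0.0
        np.testing.assert_allclose(
            ctx.A, core.apply_feedback_filter(m.fb_taps, self.counts))

    def test_ln_exc_row(self):
        m = random_model("LN", self.rng)
        ctx = make_block_context(m, "exc_weights", self.x, self.counts)
        assert ctx.P == 0.0 and ctx.M == 1.0 and ctx.A == 0.0
        assert ctx.sign_branch == 1

    def test_divisive_rows_swap_multiplier(self):
        m = random_model("divisive", self.rng)
        ctx_e = make_block_context(m, "exc_filter", self.x, self.counts)
        ctx_s = make_block_context(m, "sup_weights", self.x, self.counts)
        np.testing.assert_allclose(ctx_e.M, m.sup_signal(self.x))
        np.testing.assert_allclose(ctx_s.M, m.exc_signal(self.x))

    def test_invalid_pair(self):
        m = random_model("LN", self.rng)
        with pytest.raises(ValueError):
            make_block_context(m, "sup_filter", self.x, self.counts)


class TestGradients:
    """Analytic block gradients against central finite differences."""

    @pytest.mark.parametrize("kind", ["LN", "subtractive", "divisive",
                                      "feedback"])
    def test_matches_finite_differences(self, kind):
        rng = np.random.default_rng(101)
        model = random_model(kind, rng, n_taps=8)
        x = rng.standard_normal(400)
        hist = rng.poisson(0.3, 400) if kind == "feedback" else None
        counts = sample_spikes(forward(model, x, hist), seed=5)
        mask = valid_train_mask(400, model.n_taps, None)
        for block in blocks_for_kind(kind):
            prob = block_objective(model, block, x, counts, mask)
            g = prob.jac(prob.x0)
            g_fd = np.empty_like(g)
            h = 1e-6
            for i in range(prob.x0.size):
                xp, xm = prob.x0.copy(), prob.x0.copy()
                xp[i] += h
                xm[i] -= h
                g_fd[i] = (prob.fun(xp) - prob.fun(xm)) / (2 * h)
            err = np.linalg.norm(g - g_fd) / max(np.linalg.norm(g_fd), 1e-10)
            assert err <= 1e-5, f"{kind}/{block}: rel err {err:.2e}"

    def test_rectifier_offset_gradient_closed_form(self, rng):
        model = random_model("LN", rng)
        x = rng.standard_normal(300)
        counts = sample_spikes(forward(model, x), seed=6)
        mask = valid_train_mask(300, model.n_taps, None)
        g = nll_gradient(model, "rectifier", x, counts, mask)
        rate = forward(model, x)[mask]
        expected_dc = np.sum(1.0 - counts[mask] / np.maximum(rate, 1e-12))
        assert g[2] == pytest.approx(expected_dc, rel=1e-10)


class TestFitBlock:
    def _data(self, kind, seed=11, n=3000):
        rng = np.random.default_rng(seed)
        truth = random_model(kind, rng, n_taps=10)
        x = generate_white_noise(n, 60.0, seed=seed).values
        hist = None
        if kind == "feedback":
            _, cts = core.free_running_forward(truth, x, seed=seed + 1)
            counts = cts[0].astype(np.int64)
        else:
            counts = sample_spikes(forward(truth, x), seed=seed + 1)
        return truth, x, counts

    @pytest.mark.parametrize("kind,block", [
        ("LN", "exc_filter"), ("LN", "exc_weights"), ("LN", "rectifier"),
        ("subtractive", "sup_filter"), ("subtractive", "sup_weights"),
        ("divisive", "sup_filter"), ("divisive", "sup_weights"),
        ("feedback", "fb_filter"),
    ])
    def test_descent_and_constraints(self, kind, block):
        truth, x, counts = self._data(kind)
        rng = np.random.default_rng(55)
        model = random_model(kind, rng, n_taps=10)
        mask = valid_train_mask(x.size, 10, None)
        hist = counts if kind == "feedback" else None
        before = negative_log_likelihood(forward(model, x, hist), counts,
                                         mask)
        updated = fit_block(model, block, x, counts, mask)
        hist_u = counts if kind == "feedback" else None
        after = negative_log_likelihood(forward(updated, x, hist_u), counts,
                                        mask)
        assert after <= before + 1e-6
        audit = constraint_audit(updated)
        for key, val in audit.items():
            if key.endswith(("norm_err", "tail_mean")):
                assert val <= 1e-6, f"{key}={val}"
            elif key.endswith("viol"):
                assert val <= 1e-12, f"{key}={val}"
        if "sup_bump_center" in audit:
            assert audit["sup_bump_center"] == 1.0


class TestInitializeRun:
    def _features(self, n_taps=15):
        rng = np.random.default_rng(61)
        model = random_model("LN", rng, n_taps=n_taps)
        x = generate_white_noise(20_000, 60.0, seed=61).values
        counts = sample_spikes(forward(model, x), seed=62)
        return compute_stc_features(x, counts, n_taps)

    def test_run1_subtractive_uses_sta_and_stc(self):
        feats = self._features()
        m = initialize_run(1, "subtractive", 15, feats, seed=0)
        from suppfilt.core import project_filter

        np.testing.assert_allclose(m.exc_filter.taps,
                                   project_filter(feats.sta))
        np.testing.assert_allclose(m.sup_filter.taps,
                                   project_filter(feats.stc_first))
        assert m.exc_nl.shape_class == "monotone"

    def test_run5_is_noise(self):
        feats = self._features()
        m = initialize_run(5, "divisive", 15, feats, seed=0)
        assert np.linalg.norm(m.exc_filter.taps) == pytest.approx(1.0)
        assert abs(m.exc_filter.taps @ feats.sta) < 0.9

    def test_bump_initialization_projected(self):
        m = initialize_run(2, "divisive", 15, self._features(), seed=3)
        w = m.sup_nl.weights
        assert w[N_KNOTS // 2] == 1.0
        assert np.all((w >= WEIGHT_FLOOR) & (w <= 1.0))

    def test_rectifier_initial_values(self):
        m = initialize_run(1, "LN", 15, self._features(), seed=0)
        np.testing.assert_allclose(m.rectifier.as_array(),
                                   [0.1, 0.0, 0.0, 10.0])

    def test_feedback_filter_initially_zero(self):
        m = initialize_run(2, "feedback", 15, self._features(), seed=0)
        assert np.all(m.fb_taps == 0.0)

    def test_run_index_validated(self):
        with pytest.raises(ValueError):
            initialize_run(6, "LN", 10, None, seed=0)


class TestFitModel:
    def test_ln_self_consistency(self):
        from suppfilt.synthetic import make_cell, simulate_recording

        cell = make_cell("LN_ON", seed=9)
        rec = simulate_recording(cell, seed=9, n_train_block=1500,
                                 n_frozen=300, n_blocks=4)
        sm = SuppressionModel.from_recording(rec, kind="LN")
        res = sm.fit(n_runs=2, seed=9)
        truth_rate = forward(cell, rec.stim.values)
        from suppfilt.evaluation import info_per_spike

        mask = sm.eval_mask("test")
        truth_info = info_per_spike(rec.counts[mask], truth_rate[mask])
        assert abs(res.info_per_spike("test") - truth_info) <= 0.1

    def test_bookkeeping_and_summary(self):
        from suppfilt.synthetic import make_cell, simulate_recording

        cell = make_cell("LN_ON", seed=10)
        rec = simulate_recording(cell, seed=10, n_train_block=750,
                                 n_frozen=150, n_blocks=3)
        res = SuppressionModel.from_recording(rec, kind="LN") \
            .fit(n_runs=3, seed=10)
        assert res.converged_by in ("iteration_cap", "relative_change")
        assert res.train_nll == pytest.approx(min(res.run_nlls))
        assert 1 <= res.run_index <= 3
        # objective trace non-increasing
        assert np.all(np.diff(res.objective_trace) <= 1e-6)
        text = res.summary()
        assert "LN" in text and "Training -LL" in text

    def test_empty_training_interval_rejected(self):
        stim = generate_white_noise(100, 60.0, seed=0)
        from suppfilt.stimulus import TrainTestSchedule

        sched = TrainTestSchedule([(0, 10)], [(10, 100)])
        with pytest.raises(ValueError):
            SuppressionModel(np.zeros(100, dtype=int), stim, kind="LN",
                             schedule=sched, n_taps=15)

    def test_functional_wrapper(self):
        stim = generate_white_noise(2000, 60.0, seed=12)
        rngl = np.random.default_rng(12)
        counts = rngl.poisson(0.2, 2000)
        res = fit_model("LN", stim, counts, n_taps=8, n_runs=1, seed=1,
                        max_outer=3)
        assert res.kind == "LN"
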