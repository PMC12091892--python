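"""Constrained block-coordinate maximum-likelihood fitting.

Every model kind is trained inside the unified master structure

    r(t) = f( [ s_b * sum_i w_i g_i( (k * X)(t) )  +  s_P * P(t) ] * M(t) + A(t) )

where exactly one component (a filter ``k``, a weight vector ``w``, or the
rectifier ``f``) is free at a time and the frozen remainder of the model is
captured by the per-frame signals P (additive before the multiplication),
M (multiplicative) and A (additive after). The branch sign ``s_b`` is -1 for
the suppressive branch of the subtractive model and +1 otherwise.

Blocks are visited in a fixed order (excitatory filter and weights,
suppressive filter and weights or feedback filter, output rectifier), each
updated by a few steps of a smooth constrained optimizer honoring the shape
constraints (unit-norm / zero-tail filters; nondecreasing or bump-shaped
weights), with an accept-only-if-improved guard that keeps the objective
trace non-increasing. Training restarts from five initializations seeded by
spike-triggered statistics and the best run (lowest training negative
log-likelihood) is returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from . import core
from .core import (EncodingModel, SoftplusRectifier, TemporalFilter,
                   TentNonlinearity, RATE_FLOOR, WEIGHT_FLOOR, KNOTS, N_KNOTS,
                   CENTER_KNOT, eval_rectifier, rectifier_slope,
                   eval_nonlinearity, nonlinearity_slope, tent_basis_matrix,
                   apply_feedback_filter)
from .sta import StaFeatures, compute_stc_features, stimulus_windows
from .stimulus import StimulusTrace, TrainTestSchedule

__all__ = [
    "negative_log_likelihood",
    "make_block_context",
    "nll_gradient",
    "block_objective",
    "fit_block",
    "initialize_run",
    "fit_model",
    "SuppressionModel",
    "SuppressionResults",
    "FitResult",
    "blocks_for_kind",
    "valid_train_mask",
]

logger = logging.getLogger(__name__)

REL_TOL = 1e-4          # "change smaller than 0.01%" outer stopping rule
MAX_OUTER = 100
MAX_BLOCK_STEPS = 10
DEFAULT_N_RUNS = 5


def negative_log_likelihood(rate: np.ndarray, counts: np.ndarray,
                            mask: np.ndarray | None = None) -> float:
    """Poisson negative log-likelihood -sum_t [n_t ln r_t - r_t - ln n_t!]
    over the (optionally masked) bins; rates floored at 1e-12."""
    rate = np.asarray(rate, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if rate.shape != counts.shape:
        raise ValueError("rate and counts must have equal length")
    if mask is not None:
        rate = rate[mask]
        counts = counts[mask]
    r = np.maximum(rate, RATE_FLOOR)
    return float(np.sum(r - counts * np.log(r) + gammaln(counts + 1.0)))


def valid_train_mask(n_frames: int, n_taps: int,
                     schedule: TrainTestSchedule | None) -> np.ndarray:
    """Training bins excluding the convolution warm-up (first n_taps-1 bins
    of the trace), so every model kind is scored on identical bins."""
    if schedule is None:
        m = np.ones(n_frames, dtype=bool)
    else:
        m = schedule.train_mask(n_frames)
    m = m.copy()
    m[: n_taps - 1] = False
    return m


def blocks_for_kind(kind: str) -> list[str]:
    if kind == "LN":
        return ["exc_filter", "exc_weights", "rectifier"]
    if kind in ("subtractive", "divisive"):
        return ["exc_filter", "exc_weights", "sup_filter", "sup_weights",
                "rectifier"]
    if kind == "feedback":
        return ["exc_filter", "exc_weights", "fb_filter", "rectifier"]
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class TrainingBlockContext:
    """Frozen contributions of the untrained model parts for one block."""

    X: np.ndarray            # source signal feeding the trained filter
    P: np.ndarray | float    # additive term inside the brackets
    M: np.ndarray | float    # multiplicative term
    A: np.ndarray | float    # additive term outside the multiplication
    sign_branch: int         # s_b of the trained branch
    sign_P: int              # sign applied to P


def make_block_context(model: EncodingModel, block_id: str,
                       stim_values: np.ndarray,
                       counts: np.ndarray) -> TrainingBlockContext:
    """Freeze all branches except the trained one, per the unified-structure
    variable assignment for the (kind, block) pair. The feedback block is
    teacher-forced: its source signal is the observed spike counts."""
    kind = model.kind
    branch = "exc" if block_id.startswith("exc") else "sup"
    if block_id == "fb_filter":
        branch = "fb"
    ok = {
        "LN": ("exc",),
        "subtractive": ("exc", "sup"),
        "divisive": ("exc", "sup"),
        "feedback": ("exc", "fb"),
    }[kind]
    if block_id != "rectifier" and branch not in ok:
        raise ValueError(f"block {block_id!r} does not exist for kind {kind!r}")
    x = np.asarray(stim_values, dtype=float)
    if branch == "exc" or block_id == "rectifier":
        if kind == "LN":
            return TrainingBlockContext(x, 0.0, 1.0, 0.0, +1, +1)
        if kind == "subtractive":
            return TrainingBlockContext(x, model.sup_signal(x), 1.0, 0.0, +1, -1)
        if kind == "divisive":
            return TrainingBlockContext(x, 0.0, model.sup_signal(x), 0.0, +1, +1)
        fb_out = apply_feedback_filter(model.fb_taps, counts)
        return TrainingBlockContext(x, 0.0, 1.0, fb_out, +1, +1)
    if branch == "sup":
        if kind == "subtractive":
            return TrainingBlockContext(x, model.exc_signal(x), 1.0, 0.0, -1, +1)
        return TrainingBlockContext(x, 0.0, model.exc_signal(x), 0.0, +1, +1)
    # feedback filter: X = observed spikes, A = excitatory branch output
    return TrainingBlockContext(np.asarray(counts, dtype=float), 0.0, 1.0,
                                model.exc_signal(x), +1, +1)


# ---------------------------------------------------------------------------
# Block objective/gradient machinery
# ---------------------------------------------------------------------------

def _feedback_design(counts: np.ndarray, n_taps: int) -> np.ndarray:
    """Design matrix for the spike-history filter: row t holds the counts at
    bins t-1 ... t-n_taps (one-bin delay; strictly causal)."""
    shifted = np.concatenate([[0.0], np.asarray(counts, dtype=float)[:-1]])
    return stimulus_windows(shifted, n_taps)


@dataclass
class _BlockProblem:
    """Objective/gradient closure pair for one block's free parameters."""

    x0: np.ndarray
    fun: callable
    jac: callable
    apply: callable          # apply(model, x) -> None (in-place update)
    kind: str = "generic"    # 'filter' | 'fb_filter' | 'monotone' | 'bump' | 'rectifier'


def block_objective(model: EncodingModel, block_id: str,
                    stim_values: np.ndarray, counts: np.ndarray,
                    mask: np.ndarray) -> _BlockProblem:
    """Build the masked NLL and analytic gradient as functions of the block's
    free parameters, with everything else frozen."""
    counts_f = np.asarray(counts, dtype=float)
    nmask = counts_f[mask]
    lgam = float(np.sum(gammaln(nmask + 1.0)))
    rect = model.rectifier

    def nll_and_dz(z):
        """NLL over masked bins and dNLL/dz (full-length, 0 off-mask)."""
        r = eval_rectifier(rect, z)
        rf = np.maximum(r, RATE_FLOOR)
        val = float(np.sum(rf[mask] - nmask * np.log(rf[mask]))) + lgam
        coef = np.zeros_like(z)
        coef[mask] = (1.0 - nmask / rf[mask]) * rectifier_slope(rect, z[mask])
        return val, coef

    ctx = make_block_context(model, block_id, stim_values, counts_f)

    if block_id == "rectifier":
        hist = counts_f if model.kind == "feedback" else None
        z = model.drive(np.asarray(stim_values, dtype=float), hist)
        zm = z[mask]
        nm = nmask

        def fun(p):
            a, b, c, m = p
            u = a * zm + b
            sp = np.maximum(u, 0.0) + np.log1p(np.exp(-np.abs(u)))
            r = np.maximum(m * sp + c, RATE_FLOOR)
            return float(np.sum(r - nm * np.log(r))) + lgam

        def jac(p):
            from scipy.special import expit

            a, b, c, m = p
            u = a * zm + b
            sp = np.maximum(u, 0.0) + np.log1p(np.exp(-np.abs(u)))
            sig = expit(u)
            r = np.maximum(m * sp + c, RATE_FLOOR)
            coef = 1.0 - nm / r
            return np.array([
                np.sum(coef * m * sig * zm),
                np.sum(coef * m * sig),
                np.sum(coef),
                np.sum(coef * sp),
            ])

        def apply(mod, p):
            mod.rectifier = SoftplusRectifier(*[float(v) for v in p])

        return _BlockProblem(rect.as_array(), fun, jac, apply, "rectifier")

    in_filter = block_id.endswith("filter")
    if block_id == "fb_filter":
        D = _feedback_design(counts_f, model.fb_taps.size)
        A = ctx.A

        def fun(k):
            z = D @ k + A
            return nll_and_dz(z)[0]

        def jac(k):
            z = D @ k + A
            _, coef = nll_and_dz(z)
            return D.T @ coef

        def apply(mod, k):
            mod.fb_taps = np.asarray(k, dtype=float).copy()

        return _BlockProblem(model.fb_taps.copy(), fun, jac, apply, "fb_filter")

    branch_filter = model.exc_filter if block_id.startswith("exc") else model.sup_filter
    branch_nl = model.exc_nl if block_id.startswith("exc") else model.sup_nl
    sb, sP, P, M, A = ctx.sign_branch, ctx.sign_P, ctx.P, ctx.M, ctx.A
    D = stimulus_windows(ctx.X, branch_filter.n_taps)

    if in_filter:
        def fun(k):
            y = D @ k
            N = eval_nonlinearity(branch_nl, y)
            z = (sb * N + sP * P) * M + A
            return nll_and_dz(z)[0]

        def jac(k):
            y = D @ k
            N = eval_nonlinearity(branch_nl, y)
            z = (sb * N + sP * P) * M + A
            _, coef = nll_and_dz(z)
            w = coef * sb * nonlinearity_slope(branch_nl, y)
            if not np.isscalar(M):
                w = w * M
            elif M != 1.0:
                w = w * M
            return D.T @ w

        def apply(mod, k):
            f = mod.exc_filter if block_id.startswith("exc") else mod.sup_filter
            f.taps = np.asarray(k, dtype=float).copy()

        return _BlockProblem(branch_filter.taps.copy(), fun, jac, apply, "filter")

    # weights block: filter output fixed, tent-basis matrix precomputed
    y = D @ branch_filter.taps
    G = tent_basis_matrix(y)

    shape = branch_nl.shape_class
    if shape == "bump":
        free_idx = np.array([i for i in range(N_KNOTS) if i != CENTER_KNOT])

        def full_w(v):
            w = np.empty(N_KNOTS)
            w[free_idx] = v
            w[CENTER_KNOT] = 1.0
            return w
    else:
        free_idx = np.arange(N_KNOTS)
        full_w = lambda v: np.asarray(v, dtype=float)

    def fun(v):
        w = full_w(v)
        z = (sb * (G @ w) + sP * P) * M + A
        return nll_and_dz(z)[0]

    def jac(v):
        w = full_w(v)
        z = (sb * (G @ w) + sP * P) * M + A
        _, coef = nll_and_dz(z)
        g = coef * sb
        if not np.isscalar(M) or M != 1.0:
            g = g * M
        return (G.T @ g)[free_idx]

    def apply(mod, v):
        nl = mod.exc_nl if block_id.startswith("exc") else mod.sup_nl
        nl.weights = full_w(np.asarray(v, dtype=float))

    return _BlockProblem(branch_nl.weights[free_idx].copy(), fun, jac, apply,
                         shape)


def nll_gradient(model: EncodingModel, block_id: str,
                 stim_values: np.ndarray, counts: np.ndarray,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Analytic gradient of the masked training NLL over the block's free
    parameters, evaluated at the model's current values."""
    if mask is None:
        mask = valid_train_mask(np.asarray(stim_values).size, model.n_taps, None)
    prob = block_objective(model, block_id, stim_values, counts, mask)
    return prob.jac(prob.x0)


# ---------------------------------------------------------------------------
# Constrained block update
# ---------------------------------------------------------------------------

def _optimize_block(prob: _BlockProblem, norm_constrained: bool,
                    max_steps: int) -> np.ndarray:
    """Run a few constrained optimizer steps; return the candidate point
    (pre-projection). Failures leave the block unchanged."""
    opts = {"maxiter": max_steps}
    try:
        if prob.kind in ("filter", "fb_filter"):
            T = prob.x0.size
            cons = []
            if T >= core.TAIL_TAPS:
                tail_jac = np.zeros(T)
                tail_jac[-core.TAIL_TAPS:] = 1.0 / core.TAIL_TAPS
                cons.append({"type": "eq",
                             "fun": lambda k: k[-core.TAIL_TAPS:].mean(),
                             "jac": lambda k: tail_jac})
            if prob.kind == "filter" and norm_constrained:
                cons.append({"type": "eq", "fun": lambda k: k @ k - 1.0,
                             "jac": lambda k: 2.0 * k})
            res = minimize(prob.fun, prob.x0, jac=prob.jac, method="SLSQP",
                           constraints=cons, options=opts)
        elif prob.kind == "monotone":
            Dm = np.diff(np.eye(N_KNOTS), axis=0)
            cons = [{"type": "ineq", "fun": lambda w: Dm @ w,
                     "jac": lambda w: Dm}]
            res = minimize(prob.fun, prob.x0, jac=prob.jac, method="SLSQP",
                           bounds=[(WEIGHT_FLOOR, None)] * N_KNOTS,
                           constraints=cons, options=opts)
        elif prob.kind == "bump":
            free_idx = np.array([i for i in range(N_KNOTS) if i != CENTER_KNOT])
            Ins = np.zeros((N_KNOTS, N_KNOTS - 1))
            Ins[free_idx, np.arange(N_KNOTS - 1)] = 1.0
            ec = np.zeros(N_KNOTS)
            ec[CENTER_KNOT] = 1.0
            rowsC = []
            for i in range(CENTER_KNOT):
                r = np.zeros(N_KNOTS)
                r[i + 1], r[i] = 1.0, -1.0
                rowsC.append(r)
            for i in range(CENTER_KNOT, N_KNOTS - 1):
                r = np.zeros(N_KNOTS)
                r[i], r[i + 1] = 1.0, -1.0
                rowsC.append(r)
            C = np.array(rowsC)
            CI = C @ Ins
            Ce = C @ ec
            cons = [{"type": "ineq", "fun": lambda v: CI @ v + Ce,
                     "jac": lambda v: CI}]
            res = minimize(prob.fun, prob.x0, jac=prob.jac, method="SLSQP",
                           bounds=[(WEIGHT_FLOOR, 1.0)] * (N_KNOTS - 1),
                           constraints=cons, options=opts)
        else:  # rectifier
            res = minimize(prob.fun, prob.x0, jac=prob.jac, method="L-BFGS-B",
                           bounds=[(1e-6, None), (None, None), (None, None),
                                   (1e-6, None)], options=opts)
        return np.asarray(res.x, dtype=float)
    except Exception as err:  # pragma: no cover - defensive
        logger.warning("block optimizer failed (%s); block left unchanged", err)
        return prob.x0.copy()


def _project_block(model: EncodingModel, block_id: str) -> None:
    """Exact projection of the just-updated block onto its constraint set."""
    if block_id in ("exc_filter", "sup_filter"):
        f = model.exc_filter if block_id == "exc_filter" else model.sup_filter
        f.taps = core.project_filter(f.taps, f.norm_constrained)
    elif block_id == "fb_filter":
        model.fb_taps = core.project_filter(model.fb_taps, norm=False)
    elif block_id in ("exc_weights", "sup_weights"):
        nl = model.exc_nl if block_id == "exc_weights" else model.sup_nl
        if nl.shape_class == "monotone":
            nl.weights = core.project_monotone_weights(nl.weights)
        elif nl.shape_class == "bump":
            nl.weights = core.project_bump_weights(nl.weights)


def _train_nll(model: EncodingModel, stim_values: np.ndarray,
               counts: np.ndarray, mask: np.ndarray) -> float:
    hist = counts if model.kind == "feedback" else None
    rate = core.forward(model, stim_values, hist)
    return negative_log_likelihood(rate, counts, mask)


def fit_block(model: EncodingModel, block_id: str, stim_values: np.ndarray,
              counts: np.ndarray, mask: np.ndarray,
              max_steps: int = MAX_BLOCK_STEPS) -> EncodingModel:
    """One constrained update of a single block; the objective never
    increases (candidate updates that fail to improve are reverted)."""
    before = _train_nll(model, stim_values, counts, mask)
    prob = block_objective(model, block_id, stim_values, counts, mask)
    norm_c = True
    if block_id in ("exc_filter", "sup_filter"):
        f = model.exc_filter if block_id == "exc_filter" else model.sup_filter
        norm_c = f.norm_constrained
    x = _optimize_block(prob, norm_c, max_steps)
    candidate = model.copy()
    prob.apply(candidate, x)
    _project_block(candidate, block_id)
    after = _train_nll(candidate, stim_values, counts, mask)
    if after <= before + 1e-9:
        return candidate
    return model


# ---------------------------------------------------------------------------
# Initialization (five restarts seeded by spike-triggered statistics)
# ---------------------------------------------------------------------------

def _w_mono(rng: np.random.Generator) -> np.ndarray:
    """Soft-rectifier template 0.1*ln(1+e^(10u)) sampled at the knots,
    plus N(0, 0.1) jitter; projected onto the monotone class."""
    u = 10.0 * KNOTS
    w = 0.1 * (np.maximum(u, 0.0) + np.log1p(np.exp(-np.abs(u))))
    w = w + rng.normal(0.0, 0.1, size=N_KNOTS)
    return core.project_monotone_weights(w)


def _w_bi(rng: np.random.Generator, shape_class: str) -> np.ndarray:
    """Bell template: unit-height Gaussian spanning ~2 SDs over [-3, 3],
    plus jitter; projected onto the requested class."""
    w = np.exp(-KNOTS ** 2 / (2 * 1.5 ** 2))
    w = w + rng.normal(0.0, 0.1, size=N_KNOTS)
    if shape_class == "bump":
        return core.project_bump_weights(w)
    return core.project_monotone_weights(w)


# Table-driven restart grid. Entries per run: (exc_filter, exc_fn, sup_filter,
# sup_fn) with per-kind choices where they differ (sub / div / fb / LN).
_EXC_FILTER_GRID = ["sta", "sta", "stc1", "stcN", "noise"]
_EXC_FN_GRID = {
    # runs where the excitatory template is the bell shape for div/LN
    "subtractive": ["mono", "mono", "mono", "mono", "mono"],
    "divisive": ["mono", "bi", "mono", "bi", "mono"],
    "feedback": ["mono", "mono", "mono", "mono", "mono"],
    "LN": ["mono", "bi", "mono", "bi", "mono"],
}
_SUP_FILTER_GRID = {
    "subtractive": ["stc1", "stcN", "stcN", "stc1", "noise"],
    "divisive": ["stc1", "stcN", "stcN", "stc1", "noise"],
    "feedback": ["zero", "zero", "zero", "zero", "noise"],
}


def _pick_filter(name: str, features: StaFeatures | None, n_taps: int,
                 rng: np.random.Generator) -> np.ndarray:
    if name == "noise" or features is None:
        return rng.standard_normal(n_taps)
    return {"sta": features.sta, "stc1": features.stc_first,
            "stcN": features.stc_last}[name].copy()


def initialize_run(run_index: int, kind: str, n_taps: int,
                   features: StaFeatures | None, seed: int,
                   frame_rate_hz: float = 60.0) -> EncodingModel:
    """Model initialization for restart ``run_index`` (1-based, 1..5).

    Filters come from the STA / first and last STC eigenvectors / standard
    normal noise; weights from a soft-rectifier or bell template with
    additive jitter; the rectifier starts at 10*ln(1+e^(0.1x)). All initial
    values are projected onto their constraint sets.
    """
    if not 1 <= run_index <= 5:
        raise ValueError("run_index must be in 1..5")
    if kind not in core.MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    rng = np.random.default_rng(seed + run_index)
    i = run_index - 1
    exc_taps = core.project_filter(
        _pick_filter(_EXC_FILTER_GRID[i], features, n_taps, rng))
    exc_w = _w_mono(rng) if _EXC_FN_GRID[kind][i] == "mono" \
        else _w_bi(rng, "monotone")
    exc = TemporalFilter(exc_taps)
    exc_nl = TentNonlinearity(exc_w, "monotone")
    rect = SoftplusRectifier(a=0.1, b=0.0, c=0.0, m=10.0)
    if kind == "LN":
        return EncodingModel("LN", exc, exc_nl, rect,
                             frame_rate_hz=frame_rate_hz)
    if kind == "feedback":
        name = _SUP_FILTER_GRID["feedback"][i]
        fb = np.zeros(n_taps) if name == "zero" else \
            core.project_filter(rng.standard_normal(n_taps), norm=False)
        return EncodingModel("feedback", exc, exc_nl, rect, fb_taps=fb,
                             frame_rate_hz=frame_rate_hz)
    sup_taps = core.project_filter(
        _pick_filter(_SUP_FILTER_GRID[kind][i], features, n_taps, rng))
    sup = TemporalFilter(sup_taps)
    if kind == "subtractive":
        sup_nl = TentNonlinearity(_w_mono(rng), "monotone")
        return EncodingModel("subtractive", exc, exc_nl, rect, sup, sup_nl,
                             frame_rate_hz=frame_rate_hz)
    sup_nl = TentNonlinearity(_w_bi(rng, "bump"), "bump")
    return EncodingModel("divisive", exc, exc_nl, rect, sup, sup_nl,
                         frame_rate_hz=frame_rate_hz)


def constraint_audit(model: EncodingModel) -> dict:
    """Violation magnitudes of every shape constraint the model carries."""
    rep = {
        "exc_norm_err": abs(np.linalg.norm(model.exc_filter.taps) - 1.0),
        "exc_tail_mean": abs(model.exc_filter.taps[-core.TAIL_TAPS:].mean()),
        "exc_monotone_viol": float(
            np.maximum(-np.diff(model.exc_nl.weights), 0.0).max()),
        "exc_weight_min": float(model.exc_nl.weights.min()),
    }
    if model.sup_filter is not None:
        rep["sup_norm_err"] = abs(np.linalg.norm(model.sup_filter.taps) - 1.0)
        rep["sup_tail_mean"] = abs(
            model.sup_filter.taps[-core.TAIL_TAPS:].mean())
        w = model.sup_nl.weights
        rep["sup_weight_min"] = float(w.min())
        if model.sup_nl.shape_class == "monotone":
            rep["sup_monotone_viol"] = float(
                np.maximum(-np.diff(w), 0.0).max())
        else:
            left, right = w[: CENTER_KNOT + 1], w[CENTER_KNOT:]
            rep["sup_bump_viol"] = float(max(
                np.maximum(-np.diff(left), 0.0).max(),
                np.maximum(np.diff(right), 0.0).max()))
            rep["sup_bump_center"] = float(w[CENTER_KNOT])
            rep["sup_weight_max"] = float(w.max())
    if model.fb_taps is not None:
        rep["fb_tail_mean"] = abs(model.fb_taps[-core.TAIL_TAPS:].mean())
    return rep


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

@dataclass
class SuppressionResults:
    """Fit results: the estimated model, optimization diagnostics, and
    evaluation helpers. Returned by :meth:`SuppressionModel.fit`."""

    model: "SuppressionModel"
    params: EncodingModel
    objective_trace: np.ndarray
    run_index: int
    converged_by: str          # 'iteration_cap' | 'relative_change'
    train_nll: float
    run_nlls: list = field(default_factory=list)

    @property
    def kind(self) -> str:
        return self.params.kind

    def predict(self, stim_values: np.ndarray | None = None,
                spike_history: np.ndarray | None = None) -> np.ndarray:
        """Expected spike count per bin (teacher-forced for feedback when a
        spike history is given, else requires one for the feedback kind)."""
        if stim_values is None:
            stim_values = self.model.stim_values
            if spike_history is None and self.params.kind == "feedback":
                spike_history = self.model.counts
        return core.forward(self.params, np.asarray(stim_values, float),
                            spike_history)

    def info_per_spike(self, subset: str = "test", n_eval: int = 100,
                       seed: int = 0) -> float:
        """Held-out (or training) information per spike in bits/spike; the
        feedback kind is averaged over ``n_eval`` free-running evaluations."""
        from . import evaluation

        mask = self.model.eval_mask(subset)
        counts = self.model.counts
        stim = self.model.stim_values
        if self.params.kind == "feedback":
            return evaluation.info_per_spike_feedback(
                self.params, stim, counts, mask=mask, n_eval=n_eval, seed=seed)
        rate = self.predict()
        return evaluation.info_per_spike(counts[mask], rate[mask])

    def constraint_report(self) -> dict:
        """Audit of the shape constraints on the fitted parameters."""
        return constraint_audit(self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Suppression encoding model fit",
            "=" * 46,
            f"{'Model kind:':<28}{p.kind}",
            f"{'Frame rate (Hz):':<28}{p.frame_rate_hz:g}",
            f"{'Filter taps:':<28}{p.n_taps}",
            f"{'Training bins:':<28}{int(self.model.train_mask.sum())}",
            f"{'Training -LL:':<28}{self.train_nll:.3f}",
            f"{'Outer iterations:':<28}{len(self.objective_trace)}",
            f"{'Stopped by:':<28}{self.converged_by}",
            f"{'Best restart (1-5):':<28}{self.run_index}",
            f"{'Rectifier (a, b, c, m):':<28}"
            + "(" + ", ".join(f"{v:.4g}" for v in p.rectifier.as_array()) + ")",
        ]
        if self.model.schedule is not None:
            lines.append(f"{'Held-out bins:':<28}"
                         f"{int(self.model.eval_mask('test').sum())}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_components(self, ax=None):
        """Plot fitted filters and nonlinearities (matplotlib axes array)."""
        import matplotlib.pyplot as plt

        p = self.params
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(8, 3))
        t = -np.arange(p.n_taps) / p.frame_rate_hz * 1000.0
        ax[0].plot(t, p.exc_filter.taps, label="excitatory")
        if p.sup_filter is not None:
            ax[0].plot(t, p.sup_filter.taps, "--", label="suppressive")
        if p.fb_taps is not None:
            ax[0].plot(-np.arange(p.fb_taps.size) / p.frame_rate_hz * 1000.0,
                       p.fb_taps, ":", label="feedback")
        ax[0].set_xlabel("time before bin (ms)")
        ax[0].legend(fontsize=8)
        ax[1].plot(KNOTS, p.exc_nl.weights, label="excitatory NL")
        if p.sup_nl is not None:
            ax[1].plot(KNOTS, p.sup_nl.weights, "--", label="suppressive NL")
        ax[1].set_xlabel("filter output")
        ax[1].legend(fontsize=8)
        return ax


FitResult = SuppressionResults  # alias: the fit-result contract


class SuppressionModel:
    """Encoding model of binned spike counts driven by a 1-D stimulus.

    Parameters
    ----------
    counts : array of int
        Spike counts per stimulus frame.
    stim : StimulusTrace or array
        Stimulus trace in model input units.
    kind : {'LN', 'subtractive', 'divisive', 'feedback'}
    schedule : TrainTestSchedule, optional
        Train/test split; all bins are training data when omitted.
    n_taps : int
        Temporal filter length in frames (species presets 30/25/15).
    """

    def __init__(self, counts, stim, kind: str = "divisive",
                 schedule: TrainTestSchedule | None = None,
                 n_taps: int = 15, frame_rate_hz: float | None = None):
        if kind not in core.MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        if isinstance(stim, StimulusTrace):
            self.stim_values = stim.values
            self.frame_rate_hz = stim.frame_rate_hz
        else:
            self.stim_values = np.asarray(stim, dtype=float)
            self.frame_rate_hz = 60.0
        if frame_rate_hz is not None:
            self.frame_rate_hz = frame_rate_hz
        self.counts = np.asarray(counts)
        if self.counts.shape != self.stim_values.shape:
            raise ValueError("counts and stimulus must have equal length")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype,
                                                        np.integer):
            if np.any(self.counts < 0) or np.any(self.counts % 1 != 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        self.kind = kind
        self.schedule = schedule
        self.n_taps = int(n_taps)
        self.train_mask = valid_train_mask(self.counts.size, self.n_taps,
                                           schedule)
        if not self.train_mask.any():
            raise ValueError("training interval set is empty")

    @classmethod
    def from_recording(cls, recording, kind: str = "divisive",
                       n_taps: int | None = None) -> "SuppressionModel":
        """Build from a synthetic Recording (stimulus, counts, schedule)."""
        return cls(recording.counts, recording.stim, kind=kind,
                   schedule=recording.schedule,
                   n_taps=n_taps or recording.n_taps)

    def eval_mask(self, subset: str = "test") -> np.ndarray:
        if subset == "train":
            return self.train_mask
        if self.schedule is None:
            raise ValueError("no schedule: held-out subset undefined")
        m = self.schedule.test_mask(self.counts.size)
        m[: self.n_taps - 1] = False
        return m

    def spike_features(self) -> StaFeatures:
        """STA/STC features of the training data (cached)."""
        if not hasattr(self, "_features"):
            c = np.where(self.train_mask, self.counts, 0)
            self._features = compute_stc_features(self.stim_values, c,
                                                  self.n_taps)
        return self._features

    def fit(self, n_runs: int = DEFAULT_N_RUNS, seed: int = 0,
            max_outer: int = MAX_OUTER, rel_tol: float = REL_TOL,
            max_block_steps: int = MAX_BLOCK_STEPS) -> SuppressionResults:
        """Constrained block-coordinate ML over ``n_runs`` restarts; returns
        the restart with the lowest training negative log-likelihood."""
        try:
            features = self.spike_features()
        except Exception as err:
            warnings.warn(f"spike-triggered initialization unavailable "
                          f"({err}); using noise initializations")
            features = None
        blocks = blocks_for_kind(self.kind)
        best = None
        run_nlls = []
        failures = []
        for run in range(1, n_runs + 1):
            try:
                model = initialize_run(run, self.kind, self.n_taps, features,
                                       seed, self.frame_rate_hz)
                trace = [_train_nll(model, self.stim_values, self.counts,
                                    self.train_mask)]
                converged_by = "iteration_cap"
                for _ in range(max_outer):
                    for block in blocks:
                        model = fit_block(model, block, self.stim_values,
                                          self.counts, self.train_mask,
                                          max_block_steps)
                    nll = _train_nll(model, self.stim_values, self.counts,
                                     self.train_mask)
                    prev = trace[-1]
                    trace.append(nll)
                    if abs(prev - nll) < rel_tol * abs(prev):
                        converged_by = "relative_change"
                        break
                run_nlls.append(trace[-1])
                if best is None or trace[-1] < best[1][-1]:
                    best = (model, trace, run, converged_by)
            except Exception as err:
                logger.warning("restart %d failed: %s", run, err)
                failures.append((run, err))
                run_nlls.append(np.inf)
        if best is None:
            raise RuntimeError(f"all restarts failed: {failures}")
        model, trace, run, converged_by = best
        return SuppressionResults(
            model=self, params=model, objective_trace=np.asarray(trace[1:]),
            run_index=run, converged_by=converged_by,
            train_nll=float(trace[-1]), run_nlls=run_nlls)


def fit_model(kind: str, stim, counts, schedule=None, n_taps: int = 15,
              n_runs: int = DEFAULT_N_RUNS, seed: int = 0,
              **fit_kwargs) -> SuppressionResults:
    """Functional wrapper: build a SuppressionModel and fit it."""
    return SuppressionModel(counts, stim, kind=kind, schedule=schedule,
                            n_taps=n_taps).fit(n_runs=n_runs, seed=seed,
                                               **fit_kwargs)
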