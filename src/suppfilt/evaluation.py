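"""Model evaluation and cell characterization.

Performance metrics: information per spike (log-likelihood gain over a
constant-rate predictor, per spike, in bits), Poisson explained variance
(deviance-based, for trial-averaged frozen-noise firing rates), ordinary R^2,
and sliding-window generalization profiles along the chirp sweeps.
Descriptive statistics: excitation/suppression filter shift, nonlinearity
asymmetry, transiency, ON-OFF detection, unit-selection criteria and
duplicate-unit removal by correlation cliques.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import core
from .core import EncodingModel, TentNonlinearity, KNOTS, CENTER_KNOT, RATE_FLOOR

__all__ = [
    "Psth",
    "WindowProfile",
    "psth_from_trials",
    "info_per_spike",
    "info_per_spike_feedback",
    "poisson_explained_variance",
    "r2",
    "sliding_window_r2",
    "performance_range",
    "low_frequency_performance",
    "filter_shift",
    "asymmetry_index",
    "classify_transiency",
    "detect_on_off",
    "CellRecord",
    "select_units",
    "split_half_reliability",
    "dedup_units",
]

LN2 = np.log(2.0)


@dataclass
class Psth:
    """Trial-averaged spike count per bin."""

    rates: np.ndarray
    n_trials: int
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0) or not np.all(np.isfinite(self.rates)):
            raise ValueError("PSTH rates must be finite and non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def psth_from_trials(trial_counts: np.ndarray, frame_rate_hz: float) -> Psth:
    """PSTH from a (n_trials, n_bins) matrix of spike counts."""
    trial_counts = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    return Psth(trial_counts.mean(axis=0), trial_counts.shape[0],
                frame_rate_hz)


@dataclass
class WindowProfile:
    """Sliding-window performance profile along a sweep stimulus; the axis
    holds the contrast (%) or instantaneous frequency (Hz) at each window's
    start frame."""

    window_start_axis: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.window_start_axis = np.asarray(self.window_start_axis, float)
        self.r2 = np.asarray(self.r2, dtype=float)
        if np.any(np.diff(self.window_start_axis) <= 0):
            raise ValueError("window axis must be strictly increasing")


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def _poisson_ll(counts: np.ndarray, rate: np.ndarray) -> float:
    """Poisson log-likelihood up to the ln(n!) term, which cancels in every
    reported difference-based metric."""
    r = np.maximum(rate, RATE_FLOOR)
    return float(np.sum(counts * np.log(r) - r))


def info_per_spike(counts: np.ndarray, rate_pred: np.ndarray) -> float:
    """Information per spike in bits: the log-likelihood gain of the
    prediction over the constant mean-rate predictor, divided by the total
    spike count times ln 2. Negative values are possible and not clipped."""
    counts = np.asarray(counts, dtype=float)
    rate_pred = np.asarray(rate_pred, dtype=float)
    if counts.shape != rate_pred.shape:
        raise ValueError("counts and prediction must have equal length")
    total = counts.sum()
    if total < 1:
        raise ValueError("information per spike undefined without spikes")
    mean_rate = np.full_like(counts, counts.mean())
    return (_poisson_ll(counts, rate_pred)
            - _poisson_ll(counts, mean_rate)) / (total * LN2)


def info_per_spike_feedback(model: EncodingModel, stim_values: np.ndarray,
                            counts: np.ndarray,
                            mask: np.ndarray | None = None,
                            n_eval: int = 100, seed: int = 0) -> float:
    """Feedback-model performance: information per spike averaged over
    ``n_eval`` free-running forward passes (the model's own sampled spikes
    feed the history filter), each with a distinct derived seed."""
    if model.kind != "feedback":
        raise ValueError("only the feedback kind requires stochastic evaluation")
    stim_values = np.asarray(stim_values, dtype=float)
    counts = np.asarray(counts)
    if mask is None:
        mask = np.ones(counts.size, dtype=bool)
    rates, _ = core.free_running_forward(model, stim_values, seed=seed,
                                         n_chains=n_eval)
    vals = [info_per_spike(counts[mask], rates[j][mask])
            for j in range(n_eval)]
    return float(np.mean(vals))


def poisson_explained_variance(psth: Psth | np.ndarray,
                               pred: np.ndarray) -> float:
    """1 - dev(r, r_hat) / dev(r, r_bar) with the Poisson deviance
    dev(r, q) = 2 * sum[r ln(r/q) - (r - q)], convention 0*ln 0 = 0."""
    r = psth.rates if isinstance(psth, Psth) else np.asarray(psth, float)
    q = np.asarray(pred, dtype=float)
    if r.shape != q.shape:
        raise ValueError("PSTH and prediction must have equal length")
    if np.any(q <= 0):
        warnings.warn("non-positive predictions floored at 1e-12 in the "
                      "Poisson deviance", stacklevel=2)
        q = np.maximum(q, RATE_FLOOR)

    def dev(a, b):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(a > 0, a * np.log(a / b), 0.0)
        return 2.0 * float(np.sum(t - (a - b)))

    return 1.0 - dev(r, q) / dev(r, np.full_like(r, r.mean()))


def r2(psth: Psth | np.ndarray, pred: np.ndarray) -> float:
    """Fraction of variance explained, 1 - SS_res/SS_tot; NaN for a
    zero-variance window (undefined), negative values not clipped."""
    r = psth.rates if isinstance(psth, Psth) else np.asarray(psth, float)
    q = np.asarray(pred, dtype=float)
    if r.shape != q.shape:
        raise ValueError("PSTH and prediction must have equal length")
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - float(np.sum((r - q) ** 2)) / ss_tot


def sliding_window_r2(psth: Psth | np.ndarray, pred: np.ndarray,
                      axis_values: np.ndarray, frame_rate_hz: float,
                      window_ms: float = 150.0,
                      step_frames: int = 1) -> WindowProfile:
    """R^2 within a sliding window along a sweep segment.

    The window length is round(window_ms/1000 * frame_rate) frames (9 at
    60 Hz); each window is tagged with the axis value (contrast % or
    frequency Hz) at its start frame.
    """
    r = psth.rates if isinstance(psth, Psth) else np.asarray(psth, float)
    q = np.asarray(pred, dtype=float)
    axis_values = np.asarray(axis_values, dtype=float)
    win = int(round(window_ms / 1000.0 * frame_rate_hz))
    if r.size < win:
        raise ValueError("segment shorter than the analysis window")
    starts = np.arange(0, r.size - win + 1, step_frames)
    vals = np.array([r2(r[s:s + win], q[s:s + win]) for s in starts])
    return WindowProfile(axis_values[starts], vals)


def performance_range(profile: WindowProfile):
    """(axis_min, axis_max, width) over windows with R^2 > 0.

    The bounds are the min/max axis values among qualifying windows; the
    width is the measure of the qualifying set, (count - 1) * axis step,
    which coincides with max - min when the qualifying windows are contiguous
    but is robust to isolated lucky windows in noisy profiles. No window
    qualifying returns null bounds and width 0.
    """
    with np.errstate(invalid="ignore"):
        ok = profile.r2 > 0
    if not ok.any():
        return None, None, 0.0
    ax = profile.window_start_axis[ok]
    step = float(np.mean(np.diff(profile.window_start_axis)))
    width = max(0.0, (int(ok.sum()) - 1) * step)
    return float(ax.min()), float(ax.max()), width


def low_frequency_performance(profile: WindowProfile) -> float:
    """Mean R^2 of the first 10 windows (the first 300 ms of the frequency
    sweep at 60 Hz); undefined windows are excluded."""
    head = profile.r2[:10]
    if head.size < 10:
        warnings.warn("fewer than 10 windows available", stacklevel=2)
    return float(np.nanmean(head))


# ---------------------------------------------------------------------------
# Descriptive statistics of fitted components
# ---------------------------------------------------------------------------

def filter_shift(exc: np.ndarray, sup: np.ndarray) -> int:
    """Lag (frames) at which the cross-correlogram of the two tap vectors is
    maximal; positive values mean suppression lags excitation."""
    exc = np.asarray(exc, dtype=float)
    sup = np.asarray(sup, dtype=float)
    T = exc.size
    lags = np.arange(-(T - 1), T)
    best_lag, best_val = 0, -np.inf
    for lag in lags:
        s = 0.0
        for tau in range(T):
            j = tau + lag
            if 0 <= j < sup.size:
                s += exc[tau] * sup[j]
        if s > best_val:
            best_val, best_lag = s, int(lag)
    return best_lag


def asymmetry_index(nl: TentNonlinearity) -> float:
    """|sum of values over negative knots - sum over positive knots| divided
    by the total (center knot excluded); 0 = symmetric, 1 = one-sided."""
    if nl.shape_class == "identity":
        raise ValueError("asymmetry index undefined for the identity class")
    w = nl.weights
    neg = float(w[:CENTER_KNOT].sum())
    pos = float(w[CENTER_KNOT + 1:].sum())
    tot = neg + pos
    if tot == 0:
        return 0.0
    return abs(neg - pos) / tot


def classify_transiency(step_psth: Psth, step_segments,
                        peak_window_ms: float = 200.0,
                        sustained_window_ms: float = 700.0,
                        threshold: float = 0.2) -> str:
    """'transient' if the ratio of sustained rate (mean over the last 700 ms
    of the preferred-contrast step) to the early peak (max within the first
    200 ms) is strictly below 0.2, else 'sustained'. The preferred step (ON
    or OFF) is the one with the larger early peak."""
    fr = step_psth.frame_rate_hz
    n_peak = int(round(peak_window_ms / 1000.0 * fr))
    n_sus = int(round(sustained_window_ms / 1000.0 * fr))
    best = None
    for label, s, e in step_segments:
        if label not in ("on_step", "off_step"):
            continue
        seg = step_psth.rates[s:e]
        peak = seg[:n_peak].max()
        if best is None or peak > best[0]:
            best = (peak, seg)
    if best is None:
        raise ValueError("no ON/OFF step segments supplied")
    peak, seg = best
    if peak <= 0:
        return "sustained"
    ratio = seg[-n_sus:].mean() / peak
    return "transient" if ratio < threshold else "sustained"


def detect_on_off(nl: TentNonlinearity, threshold: float = -0.2) -> bool:
    """ON-OFF detection from a U-shaped LN nonlinearity: least-squares line
    slopes sL (knots < 0) and sR (knots > 0); ON-OFF iff
    sL / (|sL| + |sR|) < -0.2."""
    if nl.shape_class == "identity":
        return False
    w = nl.weights
    kl, wl = KNOTS[:CENTER_KNOT], w[:CENTER_KNOT]
    kr, wr = KNOTS[CENTER_KNOT + 1:], w[CENTER_KNOT + 1:]
    sL = np.polyfit(kl, wl, 1)[0]
    sR = np.polyfit(kr, wr, 1)[0]
    denom = abs(sL) + abs(sR)
    if denom == 0:
        return False
    return bool(sL / denom < threshold)


# ---------------------------------------------------------------------------
# Unit selection and duplicate removal
# ---------------------------------------------------------------------------

RATE_THRESHOLD_HZ = {"axolotl": 2.0, "mouse": 5.0, "marmoset": 5.0}


def split_half_reliability(trial_counts: np.ndarray, n_divisions: int = 20,
                           seed: int = 0) -> float:
    """Trial-splitting reliability: trials are split into two equal halves
    (without replacement; an odd trial out is allowed), the variance of one
    half's PSTH explained by the other (R^2) is averaged over ``n_divisions``
    random divisions."""
    trial_counts = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    n_trials = trial_counts.shape[0]
    if n_trials < 2:
        raise ValueError("need at least 2 trials for split-half reliability")
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    vals = []
    for _ in range(n_divisions):
        perm = rng.permutation(n_trials)
        a = trial_counts[perm[:half]].mean(axis=0)
        b = trial_counts[perm[half:2 * half]].mean(axis=0)
        vals.append(r2(a, b))
    return float(np.nanmean(vals))


@dataclass
class CellRecord:
    """Per-cell inputs to the unit-selection criteria."""

    counts: np.ndarray                  # white-noise spike counts per frame
    frame_rate_hz: float
    species: str = "marmoset"
    trial_counts: np.ndarray | None = None   # frozen-noise repeats x bins
    ln_nonlinearity: TentNonlinearity | None = None
    train_info: dict | None = None      # kind -> bits/spike on training data
    test_info: dict | None = None       # kind -> bits/spike on held-out data


def select_units(records: list[CellRecord], reliability_seed: int = 0):
    """Five independently reported selection flags per cell:

    1. mean firing rate above the species threshold (2 Hz axolotl,
       5 Hz mouse/marmoset);
    2. split-half frozen-noise reliability > 0.5 (20 random divisions);
    3. |early - late mean rate| < 0.5 * overall rate (first/last 30% of the
       white-noise recording);
    4. not an ON-OFF cell (U-shaped LN nonlinearity test);
    5. held-out performance at least 60% of training performance for all
       fitted model kinds.

    Returns a pandas DataFrame of booleans (NaN-free: criteria lacking the
    needed inputs are reported as False).
    """
    import pandas as pd

    rows = []
    for rec in records:
        c = np.asarray(rec.counts, dtype=float)
        rate_hz = c.mean() * rec.frame_rate_hz
        thr = RATE_THRESHOLD_HZ.get(rec.species, 5.0)
        f1 = bool(rate_hz > thr)
        if rec.trial_counts is not None and len(rec.trial_counts) >= 2:
            f2 = bool(split_half_reliability(rec.trial_counts,
                                             seed=reliability_seed) > 0.5)
        else:
            f2 = False
        n = c.size
        k = int(round(0.3 * n))
        early, late = c[:k].mean(), c[-k:].mean()
        f3 = bool(abs(early - late) < 0.5 * c.mean()) if c.mean() > 0 else False
        f4 = (not detect_on_off(rec.ln_nonlinearity)) \
            if rec.ln_nonlinearity is not None else False
        if rec.train_info and rec.test_info:
            f5 = all(rec.test_info[k_] >= 0.6 * rec.train_info[k_]
                     for k_ in rec.train_info)
        else:
            f5 = False
        rows.append({"rate": f1, "reliability": f2, "stationarity": f3,
                     "not_on_off": f4, "generalization": f5})
    return pd.DataFrame(rows)


def dedup_units(binned_rates: np.ndarray,
                corr_threshold: float = 0.3) -> list[int]:
    """Duplicate-unit removal: build a graph with an edge wherever the
    zero-lag Pearson correlation of frame-binned rates exceeds the
    threshold, find maximal cliques, and keep one member (the lowest index)
    per clique, resolving overlapping cliques greedily largest-first."""
    import networkx as nx

    R = np.atleast_2d(np.asarray(binned_rates, dtype=float))
    n = R.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(R)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(C[i, j]) and C[i, j] > corr_threshold:
                g.add_edge(i, j)
    removed: set[int] = set()
    cliques = sorted(nx.find_cliques(g), key=len, reverse=True)
    for clique in cliques:
        alive = sorted(set(clique) - removed)
        if len(alive) >= 2:
            removed.update(alive[1:])
    return [i for i in range(n) if i not in removed]
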