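"""Ground-truth cell factory and recording simulator.

Synthetic cells are constraint-satisfying encoding models with biphasic
temporal filters (difference of two gamma kernels, fast or slow, ON or OFF),
suppressive branches that are delayed copies of the excitatory filter or
independent biphasic filters, and a rectifier offset calibrated so the cell
fires at a target mean rate on white noise. Recordings mirror the
experimental design: non-repeating white-noise training blocks interleaved
with a frozen test segment, plus optional repeated chirp trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from . import core
from .core import (EncodingModel, SoftplusRectifier, TemporalFilter,
                   TentNonlinearity, KNOTS)
from .stimulus import (StimulusTrace, TrainTestSchedule, build_schedule,
                       generate_chirp, generate_white_noise)

__all__ = [
    "GroundTruthPreset",
    "PRESETS",
    "biphasic_taps",
    "make_cell",
    "Recording",
    "simulate_recording",
    "recovery_report",
]

# Default recording scale: 12 blocks of 1500 fresh + 300 frozen frames at
# 60 Hz = 18,000 train + 3,600 test bins (5 + 1 min), mean rate ~10 sp/s.
DEFAULT_TRAIN_BLOCK = 1500
DEFAULT_FROZEN = 300
DEFAULT_N_BLOCKS = 12
DEFAULT_CHIRP_TRIALS = 15


@dataclass(frozen=True)
class GroundTruthPreset:
    """Parameter family for a synthetic ganglion cell."""

    name: str
    kind: str                       # LN | subtractive | divisive | feedback
    polarity: int = 1               # +1 ON, -1 OFF
    speed: str = "fast"             # 'fast' | 'slow' excitatory kinetics
    sup_speed: str | None = None    # None: sup = delayed copy of exc;
    #                                 else an independent biphasic filter
    sup_delay: int = 0              # delay (frames) applied to the sup filter
    sup_bump_sigma: float = 0.8     # width of the divisive bump nonlinearity
    sup_gain: float = 1.5           # scale of the subtractive suppressive NL
    fb_amplitude: float = -0.8      # peak of the spike-history filter
    fb_tau: float = 1.5             # decay (frames) of the history filter
    target_rate_hz: float = 10.0
    n_taps: int = 15
    frame_rate_hz: float = 60.0


PRESETS = {
    "LN_ON": GroundTruthPreset("LN_ON", "LN", polarity=+1),
    # suppression with slower kinetics than excitation: the regime in which
    # subtractive release-from-suppression is not LN-representable
    "fast_OFF_subtractive": GroundTruthPreset(
        "fast_OFF_subtractive", "subtractive", polarity=-1,
        sup_speed="slow"),
    # suppressive filter = excitatory filter delayed by 2 frames, the
    # delayed-gain-control motif of divisive suppression
    "fast_OFF_divisive": GroundTruthPreset(
        "fast_OFF_divisive", "divisive", polarity=-1, sup_delay=2),
    # moderate spike-history adaptation (~13 ms decay at 60 Hz)
    "fast_OFF_feedback": GroundTruthPreset(
        "fast_OFF_feedback", "feedback", polarity=-1),
}


def biphasic_taps(n_taps: int, speed: str = "fast",
                  polarity: int = 1) -> np.ndarray:
    """Biphasic temporal filter as a difference of two gamma kernels,
    tail-projected and unit-normalized; tau=0 is the most recent frame."""
    tau = np.arange(n_taps) + 0.5
    if speed == "fast":
        peak, trough = 2.2, 5.0
    elif speed == "slow":
        peak, trough = 4.5, 9.0
    else:
        raise ValueError(f"unknown speed {speed!r}")
    g1 = gamma_dist.pdf(tau, a=4.0, scale=peak / 3.0)
    g2 = gamma_dist.pdf(tau, a=5.0, scale=trough / 4.0)
    k = g1 / g1.max() - 0.65 * g2 / g2.max()
    return core.project_filter(polarity * k)


def _delayed(taps: np.ndarray, d: int) -> np.ndarray:
    out = np.zeros_like(taps)
    if d >= 0:
        out[d:] = taps[: taps.size - d]
    else:
        out[:d] = taps[-d:]
    return core.project_filter(out)


def _monotone_weights(gain: float = 1.0, slope: float = 2.0) -> np.ndarray:
    """Smooth rectifier-shaped monotone weights on the knot grid."""
    u = slope * KNOTS
    w = gain * (np.maximum(u, 0.0) + np.log1p(np.exp(-np.abs(u)))) / slope
    return core.project_monotone_weights(w)


def _bump_weights(sigma: float) -> np.ndarray:
    return core.project_bump_weights(np.exp(-KNOTS ** 2 / (2 * sigma ** 2)))


CAL_FRAMES = 20000
CAL_TOL = 0.03  # relative mean-rate tolerance of the offset calibration


def _calibrate_offset(cell: EncodingModel, target_count: float,
                      seed: int) -> EncodingModel:
    """Choose the rectifier offset b so the mean rate on white noise hits the
    target expected count per bin. Deterministic for a fixed seed."""
    x = generate_white_noise(CAL_FRAMES, cell.frame_rate_hz, seed).values
    rect = cell.rectifier

    if cell.kind != "feedback":
        z = cell.drive(x)

        def gap(b):
            r = SoftplusRectifier(rect.a, b, rect.c, rect.m)
            return core.eval_rectifier(r, z).mean() - target_count

        b = brentq(gap, -60.0, 60.0, xtol=1e-6)
        out = cell.copy()
        out.rectifier = SoftplusRectifier(rect.a, float(b), rect.c, rect.m)
        return out

    # feedback: the realized rate depends on the sampled spikes; secant
    # iterations on the free-running mean rate
    def mean_rate(b):
        c = cell.copy()
        c.rectifier = SoftplusRectifier(rect.a, b, rect.c, rect.m)
        rates, _ = core.free_running_forward(c, x, seed=seed + 1, n_chains=1)
        return rates.mean()

    z0 = cell.exc_signal(x)

    def gap0(b):
        r = SoftplusRectifier(rect.a, b, rect.c, rect.m)
        return core.eval_rectifier(r, z0).mean() - target_count

    b0 = brentq(gap0, -60.0, 60.0, xtol=1e-4)
    b1 = b0 + 1.0
    f0 = mean_rate(b0) - target_count
    for _ in range(6):
        if abs(f0) <= CAL_TOL * target_count:
            b1 = b0
            break
        f1 = mean_rate(b1) - target_count
        if f1 == f0:
            break
        b0, b1, f0 = b1, b1 - f1 * (b1 - b0) / (f1 - f0), f1
    b = b1
    if abs(mean_rate(b) - target_count) > 0.1 * target_count:
        raise RuntimeError("rate calibration failed for the feedback cell")
    out = cell.copy()
    out.rectifier = SoftplusRectifier(rect.a, float(b), rect.c, rect.m)
    return out


def make_cell(preset: GroundTruthPreset | str, seed: int = 0) -> EncodingModel:
    """Constraint-satisfying ground-truth model for a preset, with the
    rectifier offset calibrated to the preset's target mean rate."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    exc_taps = biphasic_taps(preset.n_taps, preset.speed, preset.polarity)
    exc = TemporalFilter(exc_taps)
    exc_nl = TentNonlinearity(_monotone_weights(gain=1.4), "monotone")
    rect = SoftplusRectifier(a=1.0, b=0.0, c=0.0, m=1.0)
    kw = dict(rectifier=rect, frame_rate_hz=preset.frame_rate_hz)
    if preset.sup_speed is None:
        sup_taps = _delayed(exc_taps, preset.sup_delay)
    else:
        sup_taps = _delayed(biphasic_taps(preset.n_taps, preset.sup_speed,
                                          preset.polarity), preset.sup_delay)
    if preset.kind == "LN":
        cell = EncodingModel("LN", exc, exc_nl, **kw)
    elif preset.kind == "subtractive":
        sup = TemporalFilter(sup_taps)
        sup_nl = TentNonlinearity(_monotone_weights(gain=preset.sup_gain),
                                  "monotone")
        cell = EncodingModel("subtractive", exc, exc_nl, sup_filter=sup,
                             sup_nl=sup_nl, **kw)
    elif preset.kind == "divisive":
        sup = TemporalFilter(sup_taps)
        sup_nl = TentNonlinearity(_bump_weights(preset.sup_bump_sigma), "bump")
        cell = EncodingModel("divisive", exc, exc_nl, sup_filter=sup,
                             sup_nl=sup_nl, **kw)
    elif preset.kind == "feedback":
        fb = preset.fb_amplitude * np.exp(-np.arange(preset.n_taps)
                                          / preset.fb_tau)
        fb = core.project_filter(fb, norm=False)
        cell = EncodingModel("feedback", exc, exc_nl, fb_taps=fb, **kw)
    else:
        raise ValueError(f"unknown kind {preset.kind!r}")
    target_count = preset.target_rate_hz / preset.frame_rate_hz
    return _calibrate_offset(cell, target_count, seed)


@dataclass
class Recording:
    """Simulated white-noise recording (plus optional chirp trials)."""

    stim: StimulusTrace
    counts: np.ndarray
    schedule: TrainTestSchedule
    cell: EncodingModel
    n_taps: int
    chirp_stim: StimulusTrace | None = None
    chirp_trial_counts: np.ndarray | None = None   # (n_trials, n_bins)

    def test_trial_counts(self) -> np.ndarray:
        """Spike counts of the frozen-noise repeats, stacked (repeats, bins)."""
        if self.schedule.test_mode != "frozen_repeat":
            raise ValueError("frozen repeats only exist in frozen_repeat mode")
        return np.stack([self.counts[s:e]
                         for s, e in self.schedule.test_intervals])


def simulate_recording(cell: EncodingModel, seed: int = 0,
                       n_train_block: int = DEFAULT_TRAIN_BLOCK,
                       n_frozen: int = DEFAULT_FROZEN,
                       n_blocks: int = DEFAULT_N_BLOCKS,
                       mode: str = "frozen_repeat",
                       chirp_trials: int = 0,
                       contrast_to_model_units: float | None = None) -> Recording:
    """Simulate a white-noise recording from a ground-truth cell.

    Frozen test segments share their stimulus across repeats but carry
    independent Poisson spikes. The feedback kind runs free (sequential
    sampling); other kinds have deterministic rates and bin-wise draws.
    """
    stim, sched = build_schedule(n_train_block, n_frozen, n_blocks, mode,
                                 cell.frame_rate_hz, seed=seed)
    if cell.kind == "feedback":
        _, counts = core.free_running_forward(cell, stim.values,
                                              seed=seed + 1)
        counts = counts[0].astype(np.int64)
    else:
        rate = core.forward(cell, stim.values)
        counts = core.sample_spikes(rate, seed + 1)
    chirp_stim = None
    chirp_counts = None
    if chirp_trials > 0:
        from .stimulus import DEFAULT_CONTRAST_TO_MODEL_UNITS

        c2mu = contrast_to_model_units or DEFAULT_CONTRAST_TO_MODEL_UNITS
        chirp_stim = generate_chirp(cell.frame_rate_hz, c2mu)
        if cell.kind == "feedback":
            _, cc = core.free_running_forward(cell, chirp_stim.values,
                                              seed=seed + 2,
                                              n_chains=chirp_trials)
            chirp_counts = cc.astype(np.int64)
        else:
            r = core.forward(cell, chirp_stim.values)
            rng = np.random.default_rng(seed + 2)
            chirp_counts = rng.poisson(
                np.broadcast_to(r, (chirp_trials, r.size))).astype(np.int64)
    return Recording(stim, counts, sched, cell, cell.n_taps,
                     chirp_stim, chirp_counts)


def _aligned_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity after sign alignment (sign flips of a filter are
    absorbed by its downstream nonlinearity)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return abs(float(a @ b)) / denom


def recovery_report(truth: EncodingModel, fitted: EncodingModel,
                    stim_values: np.ndarray, counts: np.ndarray,
                    test_mask: np.ndarray, seed: int = 0) -> dict:
    """Compare a fitted model against its generating ground truth: filter
    cosine similarities (sign-aligned), held-out information per spike of
    truth and fit, and a constraint audit of the fitted parameters."""
    from . import evaluation
    from .fitting import constraint_audit

    rep = {"exc_cosine": _aligned_cosine(truth.exc_filter.taps,
                                         fitted.exc_filter.taps)}
    if truth.sup_filter is not None and fitted.sup_filter is not None:
        rep["sup_cosine"] = _aligned_cosine(truth.sup_filter.taps,
                                            fitted.sup_filter.taps)
    if truth.fb_taps is not None and fitted.fb_taps is not None:
        rep["fb_cosine"] = _aligned_cosine(truth.fb_taps, fitted.fb_taps)

    def info(model):
        if model.kind == "feedback":
            return evaluation.info_per_spike_feedback(
                model, stim_values, counts, mask=test_mask, seed=seed)
        rate = core.forward(model, stim_values)
        return evaluation.info_per_spike(counts[test_mask], rate[test_mask])

    rep["info_truth"] = info(truth)
    rep["info_fitted"] = info(fitted)
    rep["info_gap"] = rep["info_truth"] - rep["info_fitted"]
    rep["constraints"] = constraint_audit(fitted)
    return rep
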