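"""Full-field stimulus ensembles used to drive and probe the encoding models.

Stimuli are one-dimensional traces in model input units (0 = mean luminance;
white-noise training stimuli are zero-mean, unit-SD). Three ensembles are
provided: Gaussian white-noise flicker, white noise with interleaved frozen
(repeated) test segments or pseudo-trial splits, and a chirp containing
contrast steps, a 0-to-15 Hz frequency sweep and a 0-to-100% contrast sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusTrace",
    "TrainTestSchedule",
    "generate_white_noise",
    "build_schedule",
    "generate_chirp",
    "chirp_axis",
    "DEFAULT_CONTRAST_TO_MODEL_UNITS",
]

# White-noise training stimuli have SD = 30% contrast, so 100% contrast
# corresponds to 1/0.3 model units.
DEFAULT_CONTRAST_TO_MODEL_UNITS = 1.0 / 0.3


@dataclass
class StimulusTrace:
    """Frame-rate stimulus trace with labeled half-open segments."""

    values: np.ndarray
    frame_rate_hz: float
    segments: list = field(default_factory=list)  # (label, start, end)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stimulus values must be finite")
        n = self.values.size
        for label, s, e in self.segments:
            if not (0 <= s < e <= n):
                raise ValueError(f"segment {label!r} [{s}, {e}) outside trace")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    def segment(self, label: str) -> tuple[int, int]:
        """First segment with the given label as (start, end)."""
        for lab, s, e in self.segments:
            if lab == label:
                return s, e
        raise KeyError(label)

    def segment_values(self, label: str) -> np.ndarray:
        s, e = self.segment(label)
        return self.values[s:e]


@dataclass
class TrainTestSchedule:
    """Partition of a trace into training and held-out test intervals."""

    train_intervals: list
    test_intervals: list
    test_mode: str = "frozen_repeat"  # or "pseudo_trial"
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.test_mode not in ("frozen_repeat", "pseudo_trial"):
            raise ValueError(f"unknown test mode {self.test_mode!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.test_mode == "frozen_repeat":
            lengths = {e - s for s, e in self.test_intervals}
            if len(lengths) > 1:
                raise ValueError("frozen-repeat test intervals must share a length")

    def train_mask(self, n_frames: int) -> np.ndarray:
        m = np.zeros(n_frames, dtype=bool)
        for s, e in self.train_intervals:
            m[s:e] = True
        return m

    def test_mask(self, n_frames: int) -> np.ndarray:
        m = np.zeros(n_frames, dtype=bool)
        for s, e in self.test_intervals:
            m[s:e] = True
        return m


def generate_white_noise(n_frames: int, frame_rate_hz: float,
                         seed: int) -> StimulusTrace:
    """Gaussian white noise: one i.i.d. standard-normal value per frame."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal(n_frames)
    return StimulusTrace(values, frame_rate_hz,
                         [("white_noise", 0, n_frames)])


def build_schedule(n_train_block: int, n_frozen: int, n_blocks: int,
                   mode: str = "frozen_repeat", frame_rate_hz: float = 60.0,
                   seed: int = 0) -> tuple[StimulusTrace, TrainTestSchedule]:
    """White-noise recording layout with held-out test data.

    frozen_repeat: each of ``n_blocks`` blocks is ``n_train_block`` frames of
    fresh noise followed by the *same* ``n_frozen``-frame frozen segment.
    pseudo_trial: trials of ``n_train_block + n_frozen`` frames of fresh
    noise; the final ``n_frozen`` frames of each trial are held out.
    """
    if n_train_block < 1 or n_frozen < 1 or n_blocks < 1:
        raise ValueError("block sizes and counts must be >= 1")
    if mode not in ("frozen_repeat", "pseudo_trial"):
        raise ValueError(f"unknown schedule mode {mode!r}")
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    if n_frozen >= n_train_block:
        warnings.warn("test segment is at least as long as each training block",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    block = n_train_block + n_frozen
    values = np.empty(n_blocks * block)
    segments = []
    train_iv, test_iv = [], []
    frozen = rng.standard_normal(n_frozen) if mode == "frozen_repeat" else None
    for i in range(n_blocks):
        s = i * block
        values[s:s + n_train_block] = rng.standard_normal(n_train_block)
        if mode == "frozen_repeat":
            values[s + n_train_block:s + block] = frozen
        else:
            values[s + n_train_block:s + block] = rng.standard_normal(n_frozen)
        segments.append((f"train_{i}", s, s + n_train_block))
        segments.append((f"test_{i}", s + n_train_block, s + block))
        train_iv.append((s, s + n_train_block))
        test_iv.append((s + n_train_block, s + block))
    trace = StimulusTrace(values, frame_rate_hz, segments)
    sched = TrainTestSchedule(train_iv, test_iv, test_mode=mode,
                              n_repeats=n_blocks if mode == "frozen_repeat" else 1)
    return trace, sched


# Chirp segment layout in seconds: (label, duration_s). At 60 Hz this gives
# the frame counts 120/60/60/60/480/60/480/60 (1380 frames, 23 s).
_CHIRP_LAYOUT = [
    ("background", 2.0),
    ("on_step", 1.0),
    ("off_step", 1.0),
    ("background", 1.0),
    ("freq_sweep", 8.0),
    ("background", 1.0),
    ("contrast_sweep", 8.0),
    ("background", 1.0),
]
CHIRP_F_MAX_HZ = 15.0
CHIRP_CONTRAST_FREQ_HZ = 4.0


def generate_chirp(frame_rate_hz: float = 60.0,
                   contrast_to_model_units: float = DEFAULT_CONTRAST_TO_MODEL_UNITS,
                   ) -> StimulusTrace:
    """Chirp stimulus: ON/OFF contrast steps, a frequency sweep (unit
    amplitude, instantaneous frequency linear from 0 to 15 Hz) and a contrast
    sweep (4 Hz sinusoid, envelope linear from 0 to 100%).

    Contrast (fraction of the mean light level, in [-1, 1]) is scaled to
    model input units by ``contrast_to_model_units``.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    fr = frame_rate_hz
    pieces = []
    segments = []
    pos = 0
    for label, dur in _CHIRP_LAYOUT:
        n = int(round(dur * fr))
        if label == "background":
            contrast = np.zeros(n)
        elif label == "on_step":
            contrast = np.full(n, 1.0)
        elif label == "off_step":
            contrast = np.full(n, -1.0)
        elif label == "freq_sweep":
            # linear chirp: f(t) = f_max * t / T, phase = 2*pi*(f_max/(2T))*t^2
            T = (n - 1) / fr  # time of the final frame; f there = f_max
            t = np.arange(n) / fr
            phase = 2 * np.pi * (CHIRP_F_MAX_HZ / (2 * T)) * t ** 2 if T > 0 \
                else np.zeros(n)
            contrast = np.sin(phase)
        elif label == "contrast_sweep":
            t = np.arange(n) / fr
            env = np.arange(n) / max(n - 1, 1)
            contrast = env * np.sin(2 * np.pi * CHIRP_CONTRAST_FREQ_HZ * t)
        pieces.append(contrast)
        segments.append((label, pos, pos + n))
        pos += n
    contrast_trace = np.concatenate(pieces)
    values = contrast_trace * contrast_to_model_units
    return StimulusTrace(values, fr, segments)


def chirp_axis(trace: StimulusTrace, label: str) -> np.ndarray:
    """Per-frame analysis axis for a sweep segment of the chirp: the
    instantaneous frequency in Hz for 'freq_sweep', the envelope contrast in
    percent for 'contrast_sweep'. Both ramp linearly from 0 at the first
    frame to the sweep maximum at the last frame."""
    s, e = trace.segment(label)
    n = e - s
    ramp = np.arange(n) / max(n - 1, 1)
    if label == "freq_sweep":
        return CHIRP_F_MAX_HZ * ramp
    if label == "contrast_sweep":
        return 100.0 * ramp
    raise ValueError(f"segment {label!r} has no sweep axis")
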