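"""Unified encoding-model structure for retinal ganglion cell spike trains.

All four model kinds (LN, subtractive suppression, divisive suppression,
spike-feedback suppression) are special cases of one master cascade: each
stimulus branch is a temporal filter followed by a piecewise-linear
nonlinearity parametrized on a fixed tent-basis knot grid, branches are
combined additively (subtractive) or multiplicatively (divisive), a
spike-history filter may feed back additively, and a softplus rectifier maps
the combined signal to a non-negative Poisson rate per time bin.

Time is discretized at the stimulus frame rate; rates are expected spike
counts *per bin* (multiply by the frame rate for sp/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KNOTS",
    "N_KNOTS",
    "CENTER_KNOT",
    "WEIGHT_FLOOR",
    "RATE_FLOOR",
    "TemporalFilter",
    "TentNonlinearity",
    "SoftplusRectifier",
    "EncodingModel",
    "apply_filter",
    "apply_feedback_filter",
    "eval_nonlinearity",
    "nonlinearity_slope",
    "tent_basis_matrix",
    "eval_rectifier",
    "rectifier_slope",
    "forward",
    "free_running_forward",
    "sample_spikes",
    "project_filter",
    "project_monotone_weights",
    "project_bump_weights",
]

# Knot grid shared by every upstream nonlinearity: 15 uniform knots on
# [-3, 3] (spacing 3/7); knot index 7 sits exactly at 0, which lets the
# unit-maximum constraint of the bump nonlinearity act on a single weight.
N_KNOTS = 15
KNOTS = np.linspace(-3.0, 3.0, N_KNOTS)
CENTER_KNOT = N_KNOTS // 2
WEIGHT_FLOOR = 1e-16
RATE_FLOOR = 1e-12
# ceiling on free-running rates: an unconstrained (sign-free) fitted
# spike-history filter can self-excite, and without a ceiling the
# rate -> count -> rate loop overflows
RATE_CEILING = 1e4
TAIL_TAPS = 5  # filter taps entering the zero-tail constraint


def project_filter(taps: np.ndarray, norm: bool = True) -> np.ndarray:
    """Project taps onto the constraint set: mean of last five taps = 0,
    and (optionally) unit Euclidean norm.

    Rescaling preserves the zero tail, so tail-projection followed by
    normalization lands exactly on the intersection.
    """
    k = np.asarray(taps, dtype=float).copy()
    if k.size >= TAIL_TAPS:
        k[-TAIL_TAPS:] -= k[-TAIL_TAPS:].mean()
    if norm:
        nrm = np.linalg.norm(k)
        if nrm < 1e-12:  # degenerate: fall back to a unit impulse
            k = np.zeros_like(k)
            k[0] = 1.0
        else:
            k = k / nrm
    return k


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto nondecreasing sequences."""
    from sklearn.isotonic import isotonic_regression

    return isotonic_regression(np.asarray(y, dtype=float), increasing=True)


def project_monotone_weights(w: np.ndarray) -> np.ndarray:
    """Nearest nondecreasing weight vector with lower bound WEIGHT_FLOOR."""
    return np.maximum(_pava_increasing(w), WEIGHT_FLOOR)


def project_bump_weights(w: np.ndarray) -> np.ndarray:
    """Project onto the bump class: nondecreasing up to the center knot,
    nonincreasing after, center weight exactly 1, range [WEIGHT_FLOOR, 1]."""
    w = np.asarray(w, dtype=float).copy()
    left = _pava_increasing(w[: CENTER_KNOT + 1])
    right = _pava_increasing(w[CENTER_KNOT:][::-1])[::-1]
    out = np.concatenate([left, right[1:]])
    out = np.clip(out, WEIGHT_FLOOR, 1.0)
    out[CENTER_KNOT] = 1.0
    return out


@dataclass
class TemporalFilter:
    """Temporal stimulus filter sampled at the frame rate.

    ``taps[0]`` weights the most recent frame. When ``norm_constrained`` the
    Euclidean norm is 1; the mean of the last five taps is 0 in either case.
    """

    taps: np.ndarray
    norm_constrained: bool = True

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if self.taps.ndim != 1 or self.taps.size < 1:
            raise ValueError("filter taps must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("filter taps must be finite")

    @property
    def n_taps(self) -> int:
        return int(self.taps.size)

    def projected(self) -> "TemporalFilter":
        return TemporalFilter(project_filter(self.taps, self.norm_constrained),
                              self.norm_constrained)


@dataclass
class TentNonlinearity:
    """Piecewise-linear nonlinearity on the shared knot grid.

    shape_class: 'monotone' (nondecreasing, floor 1e-16), 'bump'
    (unimodal with unit maximum at 0), or 'identity' (weights unused).
    """

    weights: np.ndarray | None = None
    shape_class: str = "monotone"

    def __post_init__(self) -> None:
        if self.shape_class not in ("monotone", "bump", "identity"):
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        if self.shape_class == "identity":
            self.weights = None
        else:
            if self.weights is None:
                raise ValueError("weights required for non-identity class")
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (N_KNOTS,):
                raise ValueError(f"expected {N_KNOTS} weights")

    def projected(self) -> "TentNonlinearity":
        if self.shape_class == "monotone":
            return TentNonlinearity(project_monotone_weights(self.weights),
                                    "monotone")
        if self.shape_class == "bump":
            return TentNonlinearity(project_bump_weights(self.weights), "bump")
        return self


@dataclass
class SoftplusRectifier:
    """Output rectifier f(x) = m * ln(1 + exp(a*x + b)) + c."""

    a: float = 0.1
    b: float = 0.0
    c: float = 0.0
    m: float = 10.0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.a <= 0:
            raise ValueError("softplus orientation requires a > 0 and m > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.m], dtype=float)


def apply_filter(taps: np.ndarray | TemporalFilter, x: np.ndarray) -> np.ndarray:
    """Causal convolution y(t) = sum_tau k_tau * x(t - tau), zero-padded.

    Output has the same length as ``x``.
    """
    if isinstance(taps, TemporalFilter):
        taps = taps.taps
    taps = np.asarray(taps, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("input signal must be non-empty")
    return np.convolve(x, taps)[: x.size]


def apply_feedback_filter(taps: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Spike-history convolution with a one-bin delay.

    ``taps[0]`` weights the count in the *previous* bin, so the result at bin
    t depends only on counts at bins < t (strict causality; this is what makes
    sequential free-running generation well defined).
    """
    taps = np.asarray(taps, dtype=float)
    counts = np.asarray(counts, dtype=float)
    shifted = np.concatenate([[0.0], counts[:-1]])
    return np.convolve(shifted, taps)[: counts.size]


def eval_nonlinearity(nl: TentNonlinearity, u: np.ndarray) -> np.ndarray:
    """Evaluate the tent-basis expansion; inputs outside [-3, 3] are clamped
    to the boundary value. The identity class returns its input unchanged."""
    u = np.asarray(u, dtype=float)
    if nl.shape_class == "identity":
        return u.copy()
    return np.interp(np.clip(u, KNOTS[0], KNOTS[-1]), KNOTS, nl.weights)


def nonlinearity_slope(nl: TentNonlinearity, u: np.ndarray) -> np.ndarray:
    """Derivative of the tent expansion w.r.t. its input (0 where clamped)."""
    u = np.asarray(u, dtype=float)
    if nl.shape_class == "identity":
        return np.ones_like(u)
    h = KNOTS[1] - KNOTS[0]
    slopes = np.diff(nl.weights) / h
    inside = (u > KNOTS[0]) & (u < KNOTS[-1])
    seg = np.clip(np.searchsorted(KNOTS, u, side="right") - 1, 0, N_KNOTS - 2)
    out = np.where(inside, slopes[seg], 0.0)
    return out


def tent_basis_matrix(u: np.ndarray) -> np.ndarray:
    """Dense basis matrix G with G[t, i] = g_i(clamp(u_t)); each row has at
    most two nonzero entries and rows sum to 1."""
    u = np.clip(np.asarray(u, dtype=float), KNOTS[0], KNOTS[-1])
    h = KNOTS[1] - KNOTS[0]
    pos = (u - KNOTS[0]) / h
    j = np.clip(np.floor(pos).astype(int), 0, N_KNOTS - 2)
    frac = pos - j
    G = np.zeros((u.size, N_KNOTS))
    rows = np.arange(u.size)
    G[rows, j] = 1.0 - frac
    G[rows, j + 1] = frac
    return G


def eval_rectifier(r: SoftplusRectifier, x: np.ndarray) -> np.ndarray:
    """Numerically stable softplus: m*ln(1+e^(a*x+b)) + c."""
    z = r.a * np.asarray(x, dtype=float) + r.b
    # ln(1+e^z) = max(z, 0) + log1p(e^(-|z|)) avoids overflow at large |z|
    sp = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    return r.m * sp + r.c


def rectifier_slope(r: SoftplusRectifier, x: np.ndarray) -> np.ndarray:
    """df/dx = m * a * sigmoid(a*x + b)."""
    from scipy.special import expit

    z = r.a * np.asarray(x, dtype=float) + r.b
    return r.m * r.a * expit(z)


MODEL_KINDS = ("LN", "subtractive", "divisive", "feedback")


@dataclass
class EncodingModel:
    """One of the four encoding models expressed in the unified structure.

    Branch presence matches ``kind``: LN carries only the excitatory branch;
    subtractive and divisive carry a suppressive branch (monotone and bump
    nonlinearity, respectively); feedback carries a spike-history filter with
    no nonlinearity and no norm constraint.
    """

    kind: str
    exc_filter: TemporalFilter = None
    exc_nl: TentNonlinearity = None
    rectifier: SoftplusRectifier = field(default_factory=SoftplusRectifier)
    sup_filter: TemporalFilter | None = None
    sup_nl: TentNonlinearity | None = None
    fb_taps: np.ndarray | None = None
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.exc_filter is None or self.exc_nl is None:
            raise ValueError("excitatory branch is required for every kind")
        if self.kind == "subtractive":
            if self.sup_filter is None or self.sup_nl is None:
                raise ValueError("subtractive kind requires a suppressive branch")
            if self.sup_nl.shape_class != "monotone":
                raise ValueError("subtractive suppression must be monotone")
        elif self.kind == "divisive":
            if self.sup_filter is None or self.sup_nl is None:
                raise ValueError("divisive kind requires a suppressive branch")
            if self.sup_nl.shape_class != "bump":
                raise ValueError("divisive suppression must be bump-shaped")
        elif self.kind == "feedback":
            if self.fb_taps is None:
                raise ValueError("feedback kind requires a spike-history filter")
            self.fb_taps = np.asarray(self.fb_taps, dtype=float)
        if self.exc_nl.shape_class != "monotone":
            raise ValueError("excitatory nonlinearity must be monotone")

    @property
    def n_taps(self) -> int:
        return self.exc_filter.n_taps

    def copy(self) -> "EncodingModel":
        return EncodingModel(
            kind=self.kind,
            exc_filter=TemporalFilter(self.exc_filter.taps.copy(),
                                      self.exc_filter.norm_constrained),
            exc_nl=TentNonlinearity(
                None if self.exc_nl.weights is None else self.exc_nl.weights.copy(),
                self.exc_nl.shape_class),
            rectifier=replace(self.rectifier),
            sup_filter=None if self.sup_filter is None else TemporalFilter(
                self.sup_filter.taps.copy(), self.sup_filter.norm_constrained),
            sup_nl=None if self.sup_nl is None else TentNonlinearity(
                self.sup_nl.weights.copy(), self.sup_nl.shape_class),
            fb_taps=None if self.fb_taps is None else self.fb_taps.copy(),
            frame_rate_hz=self.frame_rate_hz,
        )

    # -- branch signals ----------------------------------------------------
    def exc_signal(self, x: np.ndarray) -> np.ndarray:
        """Excitatory branch output E(t) (after the nonlinearity)."""
        return eval_nonlinearity(self.exc_nl, apply_filter(self.exc_filter, x))

    def sup_signal(self, x: np.ndarray) -> np.ndarray:
        """Suppressive branch output S(t) (after the nonlinearity)."""
        return eval_nonlinearity(self.sup_nl, apply_filter(self.sup_filter, x))

    def drive(self, x: np.ndarray,
              spike_history: np.ndarray | None = None) -> np.ndarray:
        """Pre-rectifier signal z(t) for the model's kind."""
        E = self.exc_signal(x)
        if self.kind == "LN":
            return E
        if self.kind == "subtractive":
            return E - self.sup_signal(x)
        if self.kind == "divisive":
            return E * self.sup_signal(x)
        if spike_history is None:
            raise ValueError(
                "feedback kind requires spike_history (teacher forcing) or "
                "free_running_forward for sequential generation")
        return E + apply_feedback_filter(self.fb_taps, spike_history)


def forward(model: EncodingModel, x: np.ndarray,
            spike_history: np.ndarray | None = None) -> np.ndarray:
    """Expected spike count per bin for a stimulus trace (teacher-forced for
    the feedback kind when ``spike_history`` is given)."""
    x = np.asarray(x, dtype=float)
    return eval_rectifier(model.rectifier, model.drive(x, spike_history))


def free_running_forward(model: EncodingModel, x: np.ndarray, seed: int,
                         n_chains: int = 1):
    """Sequential stochastic generation for the feedback model.

    Each bin's Poisson count is sampled before the next bin's rate is
    computed; ``n_chains`` independent realizations run in parallel.
    Returns (rates, counts), each of shape (n_chains, n_bins).

    For non-feedback kinds the rate is deterministic; counts are sampled
    bin-independently for API symmetry.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    if model.kind != "feedback":
        # a fitted rectifier offset c < 0 can push the nominal rate below
        # zero; expected counts are clipped into [0, ceiling] for sampling
        r = np.clip(forward(model, x), 0.0, RATE_CEILING)
        rates = np.broadcast_to(r, (n_chains, x.size)).copy()
        counts = rng.poisson(rates).astype(float)
        return rates, counts
    E = model.exc_signal(x)
    fb = model.fb_taps
    T = fb.size
    n = x.size
    rates = np.empty((n_chains, n))
    counts = np.empty((n_chains, n))
    hist = np.zeros((n_chains, T))  # hist[:, j] = count at bin t-1-j
    rect = model.rectifier
    for t in range(n):
        z = E[t] + hist @ fb
        r = eval_rectifier(rect, z)
        r = np.where(np.isfinite(r), np.clip(r, 0.0, RATE_CEILING),
                     RATE_CEILING)
        rates[:, t] = r
        c = rng.poisson(r)
        counts[:, t] = c
        hist[:, 1:] = hist[:, :-1]
        hist[:, 0] = c
    return rates, counts


def sample_spikes(rate: np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draws per bin with the given expected counts."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("Poisson rates must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(rate).astype(np.int64)
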