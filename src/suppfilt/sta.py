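"""Spike-triggered statistics: STA, spike-triggered covariance features,
a histogram-nonlinearity LN baseline, and PCA-based temporal-filter
classification into slow/fast ON/OFF classes.

These serve two roles: initialization of the constrained maximum-likelihood
fits (STA, STC eigenvectors) and classical baselines / descriptive analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StaFeatures",
    "stimulus_windows",
    "compute_sta",
    "compute_stc_features",
    "HistogramLN",
    "histogram_ln",
    "pca_classify_filters",
]


class NoSpikesError(ValueError):
    """Raised when a spike-triggered statistic is requested with no spikes."""


@dataclass
class StaFeatures:
    """Unit-norm spike-triggered feature vectors in filter tap order
    (index 0 = spike bin, increasing = further into the past)."""

    sta: np.ndarray
    stc_first: np.ndarray
    stc_last: np.ndarray
    n_spikes_used: int


def stimulus_windows(stim_values: np.ndarray, n_taps: int) -> np.ndarray:
    """Matrix W with W[t, tau] = stim[t - tau]; rows are the reversed
    stimulus windows feeding the causal convolution. First n_taps-1 rows are
    zero-padded (warm-up)."""
    x = np.asarray(stim_values, dtype=float)
    n = x.size
    padded = np.concatenate([np.zeros(n_taps - 1), x])
    # sliding windows, reversed into tau-order
    from numpy.lib.stride_tricks import sliding_window_view

    W = sliding_window_view(padded, n_taps)[:n]
    return W[:, ::-1]


def _valid(counts: np.ndarray, n_taps: int) -> np.ndarray:
    m = np.ones(counts.size, dtype=bool)
    m[: n_taps - 1] = False
    return m


def compute_sta(stim_values: np.ndarray, counts: np.ndarray,
                n_taps: int, normalize: bool = True) -> np.ndarray:
    """Count-weighted average of the stimulus windows preceding (and
    including) each spike bin, unit-normalized; tau=0 is the spike bin."""
    counts = np.asarray(counts, dtype=float)
    valid = _valid(counts, n_taps)
    w = counts * valid
    total = w.sum()
    if total < 1:
        raise NoSpikesError("STA undefined without spikes")
    W = stimulus_windows(stim_values, n_taps)
    sta = (w @ W) / total
    if normalize:
        nrm = np.linalg.norm(sta)
        if nrm > 0:
            sta = sta / nrm
    return sta


def compute_stc_features(stim_values: np.ndarray, counts: np.ndarray,
                         n_taps: int) -> StaFeatures:
    """Eigenvectors of the count-weighted second moment of spike-triggered
    stimulus windows after projecting out the STA direction.

    Returns the first (largest-eigenvalue) and last eigenvectors, unit-norm
    and orthogonal to the STA by construction.
    """
    counts = np.asarray(counts, dtype=float)
    valid = _valid(counts, n_taps)
    w = counts * valid
    total = w.sum()
    if total < 1:
        raise NoSpikesError("STC undefined without spikes")
    if total < n_taps:
        warnings.warn("fewer spikes than filter taps: spike-triggered "
                      "covariance is rank deficient", stacklevel=2)
    sta = compute_sta(stim_values, counts, n_taps)
    W = stimulus_windows(stim_values, n_taps)
    proj = W - np.outer(W @ sta, sta)
    C = (proj.T * w) @ proj / total
    evals, evecs = np.linalg.eigh(C)  # ascending
    first = evecs[:, -1]
    # last = smallest *nonzero* direction: the STA direction itself has
    # eigenvalue 0 by construction, so skip the eigenvector closest to it
    order = np.argsort(evals)
    last = None
    for idx in order:
        if abs(evecs[:, idx] @ sta) < 0.9:
            last = evecs[:, idx]
            break
    if last is None:
        last = evecs[:, order[0]]
    return StaFeatures(sta=sta, stc_first=first, stc_last=last,
                       n_spikes_used=int(round(total)))


class HistogramLN:
    """Classical LN baseline: a fixed temporal filter plus a nonparametric
    nonlinearity obtained as the histogram of filter outputs versus mean
    spike counts; prediction interpolates linearly between bin centers."""

    def __init__(self, filt: np.ndarray, centers: np.ndarray,
                 values: np.ndarray, n_taps: int):
        self.filter = np.asarray(filt, dtype=float)
        self.centers = np.asarray(centers, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.n_taps = n_taps

    def predict(self, stim_values: np.ndarray) -> np.ndarray:
        from .core import apply_filter

        y = apply_filter(self.filter, stim_values)
        return np.interp(y, self.centers, self.values)


def histogram_ln(stim_values: np.ndarray, counts: np.ndarray,
                 filt: np.ndarray, n_bins: int = 40) -> HistogramLN:
    """Fit the histogram-nonlinearity LN baseline.

    Bins the filtered-stimulus values uniformly over their range; each bin's
    nonlinearity value is the mean spike count of the time bins falling
    there. Empty bins inherit the nearest nonempty bin's value.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 histogram bins")
    from .core import apply_filter

    filt = np.asarray(filt, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n_taps = filt.size
    valid = _valid(counts, n_taps)
    y = apply_filter(filt, stim_values)[valid]
    c = counts[valid]
    edges = np.linspace(y.min(), y.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(y, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=c, minlength=n_bins)
    occ = np.bincount(idx, minlength=n_bins)
    values = np.full(n_bins, np.nan)
    nonempty = occ > 0
    values[nonempty] = sums[nonempty] / occ[nonempty]
    if not nonempty.all():
        # nearest-nonempty fill keeps the lookup defined at extreme inputs
        filled = np.flatnonzero(nonempty)
        for i in np.flatnonzero(~nonempty):
            values[i] = values[filled[np.argmin(np.abs(filled - i))]]
    return HistogramLN(filt, centers, values, n_taps)


_CLASS_RULES = {
    "slow_ON": (1, 1),
    "fast_ON": (1, -1),
    "slow_OFF": (-1, -1),
    "fast_OFF": (-1, 1),
}


def pca_classify_filters(filters: np.ndarray, threshold: float = 0.02):
    """Classify temporal filters into slow/fast ON/OFF classes by their
    scores on the first two principal components of the filter set.

    Component signs are data-dependent; each component is flipped so that
    its largest-magnitude loading is positive, making the classification
    deterministic. The ON/OFF interpretation of the score signs should be
    checked against the class-mean filters.
    """
    filters = np.asarray(filters, dtype=float)
    if filters.ndim != 2 or filters.shape[0] < 2:
        raise ValueError("need at least 2 filters to classify")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=2)
    scores = pca.fit_transform(filters)  # centering only, no scaling
    comps = pca.components_.copy()
    for j in range(2):
        if comps[j, np.argmax(np.abs(comps[j]))] < 0:
            comps[j] = -comps[j]
            scores[:, j] = -scores[:, j]
    labels = []
    for s1, s2 in scores:
        lab = "unclassified"
        for name, (g1, g2) in _CLASS_RULES.items():
            if g1 * s1 > threshold and g2 * s2 > threshold:
                lab = name
                break
        labels.append(lab)
    return labels, scores, comps
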