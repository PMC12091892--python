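"""Shared fixtures: random constraint-satisfying models and the fitted
recovery suite used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from suppfilt.core import (EncodingModel, SoftplusRectifier, TemporalFilter,
                           TentNonlinearity, N_KNOTS, WEIGHT_FLOOR,
                           project_bump_weights, project_filter,
                           project_monotone_weights)


def random_monotone_weights(rng: np.random.Generator) -> np.ndarray:
    w = np.cumsum(np.abs(rng.normal(0.0, 0.3, N_KNOTS)))
    return project_monotone_weights(w)


def random_bump_weights(rng: np.random.Generator) -> np.ndarray:
    return project_bump_weights(np.exp(-((np.linspace(-3, 3, N_KNOTS)
                                          - rng.normal(0, 0.3)) ** 2)
                                       / (2 * rng.uniform(0.5, 2.0) ** 2)))


def random_model(kind: str, rng: np.random.Generator,
                 n_taps: int = 12) -> EncodingModel:
    """Random model satisfying every constraint of its kind."""
    exc = TemporalFilter(project_filter(rng.standard_normal(n_taps)))
    exc_nl = TentNonlinearity(random_monotone_weights(rng), "monotone")
    rect = SoftplusRectifier(a=rng.uniform(0.2, 1.5), b=rng.normal(0, 0.5),
                             c=rng.uniform(0, 0.1), m=rng.uniform(0.5, 3.0))
    if kind == "LN":
        return EncodingModel("LN", exc, exc_nl, rect)
    if kind == "subtractive":
        sup = TemporalFilter(project_filter(rng.standard_normal(n_taps)))
        return EncodingModel("subtractive", exc, exc_nl, rect, sup,
                             TentNonlinearity(random_monotone_weights(rng),
                                              "monotone"))
    if kind == "divisive":
        sup = TemporalFilter(project_filter(rng.standard_normal(n_taps)))
        return EncodingModel("divisive", exc, exc_nl, rect, sup,
                             TentNonlinearity(random_bump_weights(rng),
                                              "bump"))
    fb = project_filter(-np.abs(rng.normal(0.5, 0.3))
                        * np.exp(-np.arange(n_taps) / rng.uniform(1, 3)),
                        norm=False)
    return EncodingModel("feedback", exc, exc_nl, rect, fb_taps=fb)


@pytest.fixture
def rng():
    return np.random.default_rng(20240831)


# ---------------------------------------------------------------------------
# Heavy shared fixture: ground-truth recovery fits across presets and seeds.
# Built once per session; consumed by several acceptance tests.
# ---------------------------------------------------------------------------

RECOVERY_SEEDS = (1, 2, 3, 4, 5)
PRESET_KINDS = {
    "LN_ON": "LN",
    "fast_OFF_subtractive": "subtractive",
    "fast_OFF_divisive": "divisive",
    "fast_OFF_feedback": "feedback",
}


@pytest.fixture(scope="session")
def recovery_suite():
    """For each ground-truth preset and master seed: the simulated recording
    and the matched-kind and LN fits (5 restarts each)."""
    from suppfilt.fitting import SuppressionModel
    from suppfilt.synthetic import make_cell, simulate_recording

    suite = {}
    for preset, kind in PRESET_KINDS.items():
        per_seed = []
        for seed in RECOVERY_SEEDS:
            cell = make_cell(preset, seed=seed)
            rec = simulate_recording(cell, seed=seed)
            sm = SuppressionModel.from_recording(rec, kind=kind)
            matched = sm.fit(n_runs=5, seed=seed)
            if kind == "LN":
                ln = matched
            else:
                ln = SuppressionModel.from_recording(rec, kind="LN") \
                    .fit(n_runs=5, seed=seed)
            per_seed.append({"seed": seed, "cell": cell, "rec": rec,
                             "sm": sm, "matched": matched, "ln": ln})
        suite[preset] = per_seed
    return suite
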