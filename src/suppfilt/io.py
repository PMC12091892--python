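"""File formats, configs and the simulate-fit-evaluate pipeline.

Stimuli and spike counts are headered TSV; models, schedules and configs are
JSON-compatible structured text with a schema version. Floats are stored at
full precision (Python repr), so write/read round trips are bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (EncodingModel, SoftplusRectifier, TemporalFilter,
                   TentNonlinearity)
from .stimulus import StimulusTrace, TrainTestSchedule

__all__ = [
    "SCHEMA_VERSION",
    "ParseError",
    "write_stimulus", "read_stimulus",
    "write_spikes", "read_binned_spikes",
    "write_model", "read_model",
    "write_schedule", "read_schedule",
    "RunConfig", "load_config",
    "run_pipeline",
]

SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Malformed input file (message names the offending line/field)."""


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------

def write_stimulus(trace: StimulusTrace, tsv_path, sidecar_path=None,
                   seed: int | None = None) -> None:
    n = trace.n_frames
    labels = np.array([""] * n, dtype=object)
    for lab, s, e in trace.segments:
        labels[s:e] = lab
    df = pd.DataFrame({"frame_index": np.arange(n), "value": trace.values,
                       "segment_label": labels})
    # %.17g guarantees a bit-exact float round trip
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    if sidecar_path is not None:
        side = {"schema_version": SCHEMA_VERSION,
                "frame_rate_hz": trace.frame_rate_hz,
                "segments": [[lab, int(s), int(e)]
                             for lab, s, e in trace.segments]}
        if seed is not None:
            side["seed"] = int(seed)
        Path(sidecar_path).write_text(json.dumps(side, indent=1))


def read_stimulus(tsv_path, sidecar_path=None) -> StimulusTrace:
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    for col in ("frame_index", "value"):
        if col not in df.columns:
            raise ParseError(f"{tsv_path}: missing column {col!r}")
    if not np.all(np.isfinite(df["value"].to_numpy(float))):
        bad = int(np.flatnonzero(~np.isfinite(df["value"].to_numpy(float)))[0])
        raise ParseError(f"{tsv_path}: non-finite value at line {bad + 2}")
    frame_rate = 60.0
    segments = []
    if sidecar_path is not None:
        side = json.loads(Path(sidecar_path).read_text())
        if side.get("schema_version") != SCHEMA_VERSION:
            raise ParseError(f"{sidecar_path}: schema version mismatch")
        frame_rate = float(side["frame_rate_hz"])
        segments = [(lab, int(s), int(e)) for lab, s, e in side["segments"]]
    elif "segment_label" in df.columns:
        labels = df["segment_label"].fillna("").to_numpy(object)
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                if str(labels[start]):
                    segments.append((str(labels[start]), start, i))
                start = i
    return StimulusTrace(df["value"].to_numpy(float), frame_rate, segments)


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def write_spikes(counts: np.ndarray, path, trial_counts=None) -> None:
    """Single-trace counts as (frame_index, count); optional multi-trial
    blocks as (trial, frame_index, count)."""
    if trial_counts is not None:
        tc = np.asarray(trial_counts)
        rows = [(t, i, int(tc[t, i])) for t in range(tc.shape[0])
                for i in range(tc.shape[1])]
        pd.DataFrame(rows, columns=["trial", "frame_index", "count"]) \
            .to_csv(path, sep="\t", index=False)
        return
    counts = np.asarray(counts)
    pd.DataFrame({"frame_index": np.arange(counts.size),
                  "count": counts.astype(int)}) \
        .to_csv(path, sep="\t", index=False)


def read_binned_spikes(path) -> np.ndarray:
    """Counts per frame-aligned bin; 2-D (trials, bins) when the file has a
    trial column."""
    df = pd.read_csv(path, sep="\t")
    if "count" not in df.columns:
        raise ParseError(f"{path}: missing column 'count'")
    counts = df["count"].to_numpy()
    if np.any(counts != counts.astype(np.int64)) or np.any(counts < 0):
        bad = int(np.flatnonzero((counts < 0)
                                 | (counts != counts.astype(np.int64)))[0])
        raise ParseError(f"{path}: invalid count at line {bad + 2} "
                         "(must be a non-negative integer)")
    counts = counts.astype(np.int64)
    if "trial" in df.columns:
        trials = df["trial"].to_numpy(int)
        n_trials = trials.max() + 1
        return counts.reshape(n_trials, -1)
    return counts


# ---------------------------------------------------------------------------
# Schedules and models
# ---------------------------------------------------------------------------

def write_schedule(schedule: TrainTestSchedule, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION,
           "test_mode": schedule.test_mode,
           "n_repeats": schedule.n_repeats,
           "train_intervals": [[int(s), int(e)]
                               for s, e in schedule.train_intervals],
           "test_intervals": [[int(s), int(e)]
                              for s, e in schedule.test_intervals]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_schedule(path) -> TrainTestSchedule:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(f"{path}: schema version mismatch")
    return TrainTestSchedule(
        [tuple(iv) for iv in doc["train_intervals"]],
        [tuple(iv) for iv in doc["test_intervals"]],
        test_mode=doc["test_mode"], n_repeats=doc["n_repeats"])


def write_model(model: EncodingModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": model.kind,
        "frame_rate_hz": model.frame_rate_hz,
        "exc_filter": {"taps": model.exc_filter.taps.tolist(),
                       "norm_constrained": model.exc_filter.norm_constrained},
        "exc_nl": {"weights": model.exc_nl.weights.tolist(),
                   "shape_class": model.exc_nl.shape_class},
        "rectifier": {k: float(v) for k, v in
                      zip("abcm", model.rectifier.as_array())},
    }
    if model.sup_filter is not None:
        doc["sup_filter"] = {"taps": model.sup_filter.taps.tolist(),
                             "norm_constrained":
                                 model.sup_filter.norm_constrained}
        doc["sup_nl"] = {"weights": model.sup_nl.weights.tolist(),
                         "shape_class": model.sup_nl.shape_class}
    if model.fb_taps is not None:
        doc["fb_taps"] = model.fb_taps.tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> EncodingModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ParseError(f"{path}: schema version mismatch "
                         f"(expected {SCHEMA_VERSION})")
    try:
        kw = dict(
            kind=doc["kind"],
            exc_filter=TemporalFilter(np.array(doc["exc_filter"]["taps"]),
                                      doc["exc_filter"]["norm_constrained"]),
            exc_nl=TentNonlinearity(np.array(doc["exc_nl"]["weights"]),
                                    doc["exc_nl"]["shape_class"]),
            rectifier=SoftplusRectifier(**doc["rectifier"]),
            frame_rate_hz=float(doc["frame_rate_hz"]),
        )
        if "sup_filter" in doc:
            kw["sup_filter"] = TemporalFilter(
                np.array(doc["sup_filter"]["taps"]),
                doc["sup_filter"]["norm_constrained"])
            kw["sup_nl"] = TentNonlinearity(
                np.array(doc["sup_nl"]["weights"]),
                doc["sup_nl"]["shape_class"])
        if "fb_taps" in doc:
            kw["fb_taps"] = np.array(doc["fb_taps"])
    except KeyError as err:
        raise ParseError(f"{path}: missing field {err}") from err
    return EncodingModel(**kw)


# ---------------------------------------------------------------------------
# Config and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Training-run settings; defaults match the standard procedure
    (five restarts, 100 outer iterations, 0.01% stopping rule)."""

    kinds: list = field(default_factory=lambda: ["LN", "subtractive",
                                                 "divisive", "feedback"])
    preset: str = "fast_OFF_divisive"
    n_taps: int = 15
    frame_rate_hz: float = 60.0
    n_runs: int = 5
    max_outer: int = 100
    rel_tol: float = 1e-4
    seed: int = 0
    out_dir: str = "."


def load_config(path) -> RunConfig:
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(p.read_text())
    else:
        doc = json.loads(p.read_text())
    return RunConfig(**doc)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """simulate -> fit every configured kind -> evaluate; writes fitted
    models and a per-kind summary TSV into the output directory."""
    from . import core, evaluation
    from .fitting import SuppressionModel
    from .synthetic import make_cell, simulate_recording

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cell = make_cell(config.preset, seed=config.seed)
    rec = simulate_recording(cell, seed=config.seed)
    write_stimulus(rec.stim, out / "stimulus.tsv", out / "stimulus.json",
                   seed=config.seed)
    write_spikes(rec.counts, out / "spikes.tsv")
    write_schedule(rec.schedule, out / "schedule.json")
    rows = []
    frozen = rec.schedule.test_mode == "frozen_repeat"
    for kind in config.kinds:
        sm = SuppressionModel(rec.counts, rec.stim, kind=kind,
                              schedule=rec.schedule, n_taps=config.n_taps)
        res = sm.fit(n_runs=config.n_runs, seed=config.seed,
                     max_outer=config.max_outer, rel_tol=config.rel_tol)
        write_model(res.params, out / f"model_{kind}.json")
        row = {"kind": kind,
               "train_nll": res.train_nll,
               "train_info_per_spike": res.info_per_spike("train",
                                                          seed=config.seed),
               "test_info_per_spike": res.info_per_spike("test",
                                                         seed=config.seed)}
        if frozen:
            trials = rec.test_trial_counts()
            psth = evaluation.psth_from_trials(trials,
                                               rec.stim.frame_rate_hz)
            s0, e0 = rec.schedule.test_intervals[0]
            pred = res.predict()[s0:e0] if kind != "feedback" else None
            if pred is None:
                rates, _ = core.free_running_forward(
                    res.params, rec.stim.values, seed=config.seed,
                    n_chains=20)
                pred = rates.mean(axis=0)[s0:e0]
            row["poisson_explained_variance"] = \
                evaluation.poisson_explained_variance(psth, pred)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "summary.tsv", sep="\t", index=False)
    return df
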