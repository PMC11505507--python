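"""Sample-level metrics, event-level episode detection, and the ablation harness.

Two complementary views of detector quality:

* sample-level confusion metrics (accuracy, precision, sensitivity,
  specificity, F1) — dominated by the class imbalance when FoG is a few
  percent of samples, so accuracy alone can look excellent while the detector
  is useless;
* event-level metrics — did each labeled freezing *episode* get at least one
  detection, how many false-positive detection runs occurred outside any
  episode, and how long after episode onset the first detection came
  (detection delay, in samples and in milliseconds at 25 ms/sample).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CHANNEL_GROUPS, Episode, GaitRecording
from .windowing import batch_windows

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "EventReport",
    "confusion_counts",
    "metrics",
    "episodes_from_labels",
    "event_report",
    "ablation_harness",
    "ablation_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    #: names of metrics whose denominator was zero (reported as 0.0)
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


@dataclass
class EventReport:
    n_episodes: int
    n_detected: int
    fp_events: int
    delays_samples: list[float] = field(default_factory=list)
    sampling_rate_hz: float = 40.0

    @property
    def mean_delay_samples(self) -> float:
        return float(np.mean(self.delays_samples)) if self.delays_samples else float("nan")

    @property
    def mean_delay_ms(self) -> float:
        return self.mean_delay_samples * 1000.0 / self.sampling_rate_hz

    def as_dict(self) -> dict:
        return {
            "n_episodes": self.n_episodes,
            "n_detected": self.n_detected,
            "fp_events": self.fp_events,
            "mean_delay_samples": self.mean_delay_samples,
            "mean_delay_ms": self.mean_delay_ms,
        }


def confusion_counts(predicted, target) -> ConfusionCounts:
    """Cellwise TP/TN/FP/FN counts over aligned binary series."""
    predicted = np.asarray(predicted).astype(np.uint8).ravel()
    target = np.asarray(target).astype(np.uint8).ravel()
    if predicted.shape != target.shape:
        raise ValueError("predicted and target must have equal length")
    tp = int(np.sum((predicted == 1) & (target == 1)))
    tn = int(np.sum((predicted == 0) & (target == 0)))
    fp = int(np.sum((predicted == 1) & (target == 0)))
    fn = int(np.sum((predicted == 0) & (target == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Standard confusion metrics; zero-denominator ratios are reported as 0
    and flagged in ``undefined`` so heavily imbalanced runs still yield a full
    row instead of NaNs."""
    if c.total == 0:
        raise ValueError("no samples to evaluate")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (c.tp + c.tn) / c.total
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        undefined.append("f1")
        f1 = 0.0
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        undefined=tuple(undefined),
    )


def episodes_from_labels(labels, kind: str = "fog") -> list[Episode]:
    """Maximal runs of 1s as ordered, disjoint half-open [start, end) episodes."""
    labels = np.asarray(labels).astype(np.int8).ravel()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if labels.size == 0:
        return []
    padded = np.concatenate([[0], labels, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [Episode(int(s), int(e), kind) for s, e in zip(starts, ends)]


def event_report(detected, labels, fs: float = 40.0) -> EventReport:
    """Episode-level summary of a detection series against labels.

    An episode counts as detected iff at least one detected sample falls
    inside it; its delay is the offset of the first such sample from episode
    onset.  A false-positive event is a maximal run of detected samples that
    overlaps no labeled episode.
    """
    detected = np.asarray(detected).astype(np.uint8).ravel()
    labels = np.asarray(labels).astype(np.uint8).ravel()
    if detected.shape != labels.shape:
        raise ValueError("detected and labels must have equal length")
    episodes = episodes_from_labels(labels)
    delays: list[float] = []
    n_detected = 0
    for ep in episodes:
        hits = np.flatnonzero(detected[ep.start : ep.end])
        if hits.size:
            n_detected += 1
            delays.append(float(hits[0]))
    fp_events = 0
    for run in episodes_from_labels(detected, kind="detected"):
        if not labels[run.start : run.end].any():
            fp_events += 1
    return EventReport(
        n_episodes=len(episodes),
        n_detected=n_detected,
        fp_events=fp_events,
        delays_samples=delays,
        sampling_rate_hz=fs,
    )


# ------------------------------------------------------------------ ablation


def _group_channels(sensor_groups) -> list[int]:
    groups = list(sensor_groups)
    if not groups:
        raise ValueError("sensor_groups must be a non-empty subset of "
                         f"{tuple(CHANNEL_GROUPS)}")
    bad = [g for g in groups if g not in CHANNEL_GROUPS]
    if bad:
        raise ValueError(f"unknown sensor group(s) {bad}; valid: {tuple(CHANNEL_GROUPS)}")
    idx: list[int] = []
    for g in CHANNEL_GROUPS:  # keep canonical channel order
        if g in groups:
            idx.extend(CHANNEL_GROUPS[g])
    return idx


def ablation_harness(
    recording: GaitRecording,
    sensor_groups,
    ps: int = 39,
    train_fraction: float = 0.6,
    **fit_params,
) -> MetricSet:
    """Train and score a model on a restricted sensor-channel subset.

    Channels of excluded groups are dropped *before* windowing, so the window
    length shrinks to ``len(kept_channels) * (ps + 1)``.  Returns test-split
    sample-level metrics under the chronological 60/40 split.
    """
    from .model import FogClassifier, chronological_split

    idx = _group_channels(sensor_groups)
    signals = recording.signals[:, idx]
    X, y = batch_windows(signals, ps, labels=recording.labels)
    tr, te = chronological_split(X.shape[0], train_fraction)
    clf = FogClassifier(ps=ps, **fit_params)
    clf.fit(X[tr], y[tr])
    return metrics(confusion_counts(clf.predict(X[te]), y[te]))


def ablation_table(
    recording: GaitRecording,
    groups=("CF", "ACC", "GYRO", "MA"),
    ps: int = 39,
    **fit_params,
) -> pd.DataFrame:
    """Evaluate every non-empty combination of sensor groups (ablation study)."""
    rows = []
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            m = ablation_harness(recording, combo, ps=ps, **fit_params)
            rows.append({"combination": ", ".join(combo), **m.as_dict()})
    return pd.DataFrame(rows)
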