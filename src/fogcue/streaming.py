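"""Online detection loop: rolling buffer, threshold, cue state machine.

Emulates the deployed 40 Hz loop.  Each incoming sample updates the rolling
buffer; once the buffer is warm the model scores the current window; the score
is compared against a per-patient threshold (strictly: a score equal to the
threshold does not trigger); and a countdown variable drives the vibratory
cue.  On detection the countdown is set to 3 and the one-second decrement
timer restarts, so an isolated detection keeps the cue on for exactly
3 s — 120 samples at 40 Hz — after the last detected sample.  The cue is
active whenever the countdown is positive.

Real-time pacing is simulated (sample index x 25 ms); there is no wall-clock
scheduling or radio transmission here, only the decision logic and a log of
the cue on/off commands that would be sent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GaitRecording
from .windowing import RollingBuffer, batch_windows

__all__ = [
    "DetectorConfig",
    "DetectionTrace",
    "threshold_fn",
    "FogConditionTracker",
    "update_fog_condition",
    "run_stream",
    "StreamingDetector",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Online-loop settings.

    ``threshold`` defaults to 0.9; deployments on patients with weaker model
    confidence used 0.2-0.4.  ``cue_duration_s`` is both the cue persistence
    after the last detection and the initial countdown value (one unit per
    second).  ``stim_intensity_level`` (1-10) is carried as metadata for the
    cue command log; it does not affect detection.
    """

    threshold: float = 0.9
    cue_duration_s: float = 3.0
    sampling_rate_hz: float = 40.0
    stim_intensity_level: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be strictly between 0 and 1")
        if self.cue_duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("cue_duration_s and sampling_rate_hz must be positive")
        if not 1 <= self.stim_intensity_level <= 10:
            raise ValueError("stim_intensity_level must be in 1..10")

    @property
    def fog_condition_max(self) -> int:
        return int(round(self.cue_duration_s))


@dataclass
class DetectionTrace:
    """Per-sample record of the online loop plus the cue command log."""

    scores: np.ndarray  # (T,) float32 model output (0 during warm-up)
    detected: np.ndarray  # (T,) uint8 thresholded detection
    fog_condition: np.ndarray  # (T,) int8 countdown state
    cue_active: np.ndarray  # (T,) uint8, 1 iff fog_condition > 0
    sampling_rate_hz: float
    events: list[dict] = field(default_factory=list)  # cue on/off commands

    def __post_init__(self) -> None:
        t = len(self.scores)
        if not (len(self.detected) == len(self.fog_condition) == len(self.cue_active) == t):
            raise ValueError("trace arrays must be aligned")
        if not ((self.cue_active == 1) == (self.fog_condition > 0)).all():
            raise ValueError("cue_active must be 1 exactly when fog_condition > 0")
        if self.detected.any():
            at_detection = self.fog_condition[self.detected == 1]
            if not (at_detection == self.fog_condition.max()).all():
                raise ValueError("a detected sample must carry the maximal countdown state")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(len(self.scores)),
                "score": self.scores,
                "detected": self.detected,
                "fog_condition": self.fog_condition,
                "cue_active": self.cue_active,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    def write_events(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev) + "\n")


def threshold_fn(score: float, threshold: float) -> int:
    """1 iff the model output strictly exceeds the threshold."""
    return int(score > threshold)


class FogConditionTracker:
    """Countdown state machine driving the cue.

    Detection sets the state to its maximum (3 by default) and restarts the
    one-second decrement timer; each full second without a detection lowers
    the state by one, to a floor of 0.
    """

    def __init__(self, fs: float = 40.0, max_condition: int = 3):
        self.fs_samples = int(round(fs))
        self.max_condition = max_condition
        self.state = 0
        self._since_detection = 0

    def update(self, detected: int) -> int:
        if detected:
            self.state = self.max_condition
            self._since_detection = 0
        else:
            self._since_detection += 1
            if self._since_detection % self.fs_samples == 0 and self.state > 0:
                self.state -= 1
        return self.state


def update_fog_condition(
    state: int, detected: int, samples_since_detection: int, fs: float = 40.0
) -> int:
    """Pure single-step form of the countdown (see FogConditionTracker)."""
    if detected:
        return 3 if state <= 3 else state
    if samples_since_detection > 0 and samples_since_detection % int(round(fs)) == 0:
        return max(state - 1, 0)
    return state


def run_stream(
    recording: GaitRecording,
    model,
    config: DetectorConfig = DetectorConfig(),
) -> DetectionTrace:
    """Run the online loop over a recording and return the full trace.

    Samples are pushed one by one through the rolling buffer (warm-up samples
    score 0 and cannot trigger); emitted windows are scored with the same
    fixed-chunk forward routine as offline batch prediction, so the streamed
    score sequence is bit-identical to ``model.predict_score`` on
    ``batch_windows(recording, ps)``.  The state machine then runs strictly
    per sample.
    """
    ps = model.ps
    n_channels = getattr(model, "n_channels_", recording.n_channels)
    if recording.n_channels != n_channels:
        raise ValueError(
            f"recording has {recording.n_channels} channels, model expects {n_channels}"
        )
    t_total = recording.n_samples
    windows = []
    buf = RollingBuffer(ps, n_channels)
    for t in range(t_total):
        w = buf.push(recording.signals[t])
        if w is not None:
            windows.append(w)
    scores = np.zeros(t_total, dtype=np.float32)
    if windows:
        scores[ps:] = model.predict_score(np.stack(windows))

    detected = np.zeros(t_total, dtype=np.uint8)
    fog_condition = np.zeros(t_total, dtype=np.int8)
    tracker = FogConditionTracker(config.sampling_rate_hz, config.fog_condition_max)
    events: list[dict] = []
    prev_active = 0
    for t in range(t_total):
        d = threshold_fn(scores[t], config.threshold) if t >= ps else 0
        detected[t] = d
        fog_condition[t] = tracker.update(d)
        active = int(fog_condition[t] > 0)
        if active != prev_active:
            events.append(
                {
                    "t": t,
                    "time_s": t / config.sampling_rate_hz,
                    "command": "cue_on" if active else "cue_off",
                    "intensity": config.stim_intensity_level,
                }
            )
            prev_active = active
    cue_active = (fog_condition > 0).astype(np.uint8)
    return DetectionTrace(
        scores=scores,
        detected=detected,
        fog_condition=fog_condition,
        cue_active=cue_active,
        sampling_rate_hz=config.sampling_rate_hz,
        events=events,
    )


class StreamingDetector:
    """Stateful per-sample detector for incremental use.

    ``step(sample)`` mirrors one 25 ms tick: buffer update, model score,
    threshold, countdown.  :func:`run_stream` is the batch-equivalent driver
    used for evaluation (identical arithmetic, amortized model calls).
    """

    def __init__(self, model, config: DetectorConfig = DetectorConfig()):
        self.model = model
        self.config = config
        self.buffer = RollingBuffer(model.ps, getattr(model, "n_channels_", 20))
        self.tracker = FogConditionTracker(
            config.sampling_rate_hz, config.fog_condition_max
        )

    def step(self, sample: np.ndarray) -> dict:
        window = self.buffer.push(sample)
        if window is not None:
            score = float(np.asarray(self.model.predict_score(window)).reshape(-1)[0])
        else:
            score = 0.0
        detected = threshold_fn(score, self.config.threshold) if window is not None else 0
        condition = self.tracker.update(detected)
        return {
            "score": score,
            "detected": detected,
            "fog_condition": condition,
            "cue_active": int(condition > 0),
        }
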