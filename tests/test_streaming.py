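import numpy as np
import pytest

from fogcue import DetectorConfig, FogClassifier, batch_windows, run_stream
from fogcue.streaming import FogConditionTracker, StreamingDetector, threshold_fn

from conftest import ScorePassthroughModel, recording_with_scores


class TestThresholdFn:
    def test_strictly_exceeding_triggers(self):
        assert threshold_fn(0.95, 0.9) == 1
        assert threshold_fn(0.25, 0.2) == 1

    def test_boundary_equality_does_not_trigger(self):
        assert threshold_fn(0.9, 0.9) == 0
        assert threshold_fn(0.0, 0.5) == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=500)
        for lo, hi in [(0.2, 0.5), (0.5, 0.9), (0.1, 0.95)]:
            det_hi = scores > hi
            det_lo = scores > lo
            assert not np.any(det_hi & ~det_lo)  # lowering never loses detections


class TestFogConditionStateMachine:
    def hand_simulate(self, detections, fs=40, maximum=3):
        """Independent oracle: explicit countdown bookkeeping."""
        state, since, out = 0, 0, []
        for d in detections:
            if d:
                state, since = maximum, 0
            else:
                since += 1
                if since % fs == 0:
                    state = max(0, state - 1)
            out.append(state)
        return out

    def test_isolated_detection_cues_exactly_120_samples(self):
        detections = [0] * 10 + [1] + [0] * 200
        tracker = FogConditionTracker(fs=40)
        states = [tracker.update(d) for d in detections]
        active = [s > 0 for s in states]
        # cue on from the detection sample through 119 samples later
        assert active[10:130] == [True] * 120
        assert not any(active[:10]) and not any(active[130:])
        assert states == self.hand_simulate(detections)

    def test_redetection_restarts_countdown(self):
        detections = [0] * 5 + [1] + [0] * 49 + [1] + [0] * 300
        tracker = FogConditionTracker(fs=40)
        states = [tracker.update(d) for d in detections]
        active = [s > 0 for s in states]
        last_detection = 5 + 1 + 49
        assert all(active[5 : last_detection + 120])
        assert not any(active[last_detection + 120 :])
        assert states == self.hand_simulate(detections)

    def test_never_detected_stays_zero(self):
        tracker = FogConditionTracker()
        assert all(tracker.update(0) == 0 for _ in range(500))


class TestRunStream:
    def test_stub_detector_cues_every_labeled_episode(self, stub_model):
        labels = np.zeros(800, dtype=np.uint8)
        labels[100:140] = 1
        labels[400:460] = 1
        rec = recording_with_scores(labels.astype(np.float32), labels)
        trace = run_stream(rec, stub_model, DetectorConfig(threshold=0.9))
        assert np.array_equal(trace.detected, labels)
        # last detection at t=139 keeps the cue on through t=139+119=258
        assert trace.cue_active[100:259].all()
        assert trace.cue_active[259] == 0
        assert ((trace.cue_active == 1) == (trace.fog_condition > 0)).all()
        assert (trace.fog_condition[trace.detected == 1] == 3).all()
        commands = [e["command"] for e in trace.events]
        assert commands == ["cue_on", "cue_off", "cue_on", "cue_off"]

    def test_silent_model_produces_no_cues(self, stub_model):
        rec = recording_with_scores(np.zeros(300, dtype=np.float32))
        trace = run_stream(rec, stub_model, DetectorConfig(threshold=0.5))
        assert trace.detected.sum() == 0
        assert (trace.fog_condition == 0).all()
        assert trace.events == []

    def test_warmup_scores_zero_and_cannot_trigger(self):
        stub = ScorePassthroughModel(ps=10)
        rec = recording_with_scores(np.ones(50, dtype=np.float32))
        trace = run_stream(rec, stub, DetectorConfig(threshold=0.5))
        assert (trace.scores[:10] == 0).all()
        assert (trace.detected[:10] == 0).all()
        assert (trace.detected[10:] == 1).all()

    def test_streamed_scores_equal_batch_predictions_bitwise(self, small_recording):
        clf = FogClassifier(ps=15, random_state=8).build(20)  # untrained weights suffice
        trace = run_stream(small_recording, clf, DetectorConfig(threshold=0.9))
        X, _ = batch_windows(small_recording, 15)
        assert np.array_equal(trace.scores[15:], clf.predict_score(X))

    def test_channel_mismatch_rejected(self, small_recording):
        stub = ScorePassthroughModel(n_channels=4)
        with pytest.raises(ValueError, match="channels"):
            run_stream(small_recording, stub)


class TestStreamingDetector:
    def test_step_matches_run_stream(self, stub_model):
        scores = np.array([0.0, 0.95, 0.0, 0.0], dtype=np.float32)
        rec = recording_with_scores(np.tile(scores, 30))
        det = StreamingDetector(stub_model, DetectorConfig(threshold=0.9))
        stepped = [det.step(s) for s in rec.signals]
        trace = run_stream(rec, stub_model, DetectorConfig(threshold=0.9))
        assert [r["fog_condition"] for r in stepped] == trace.fog_condition.tolist()
        assert [r["detected"] for r in stepped] == trace.detected.tolist()

    def test_detector_config_validation(self):
        with pytest.raises(ValueError):
            DetectorConfig(threshold=0.0)
        with pytest.raises(ValueError):
            DetectorConfig(threshold=1.5)
        with pytest.raises(ValueError):
            DetectorConfig(stim_intensity_level=11)
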