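import numpy as np
import pytest

from fogcue import FogClassifier, SimConfig, batch_windows, generate_recording
from fogcue.model import chronological_split
from fogcue.simulate import GaitRecording


@pytest.fixture(scope="session")
def small_recording():
    """2-minute synthetic recording with 5 freezing episodes at 10% prevalence."""
    cfg = SimConfig(duration_s=120.0, fog_prevalence=0.10, n_fog_episodes=5, seed=7)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def trained_model(small_recording):
    """A lightly trained ps=15 classifier on the chronological training split."""
    X, y = batch_windows(small_recording, 15)
    tr, _ = chronological_split(X.shape[0])
    clf = FogClassifier(ps=15, epochs=4, random_state=0)
    clf.fit(X[tr], y[tr])
    return clf


class ScorePassthroughModel:
    """Stub scoring model: the score of a window is its first feature.

    With ps=0 the window equals the sample, so a recording whose channel 0
    carries the desired score turns this stub into a fully controllable
    detector for state-machine and trace tests.
    """

    def __init__(self, ps: int = 0, n_channels: int = 20):
        self.ps = ps
        self.n_channels_ = n_channels

    def predict_score(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        return np.clip(X[:, 0], 0.0, 1.0).astype(np.float32)


@pytest.fixture
def stub_model():
    return ScorePassthroughModel()


def recording_with_scores(scores, labels=None):
    """Build a 20-channel recording whose channel 0 equals ``scores``."""
    scores = np.asarray(scores, dtype=np.float32)
    t = scores.size
    signals = np.zeros((t, 20), dtype=np.float32)
    signals[:, 0] = scores
    if labels is None:
        labels = np.zeros(t, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    activity = np.where(labels == 1, "fog", "walk").astype(object)
    return GaitRecording(
        signals=signals, labels=labels, activity=activity, sampling_rate_hz=40.0
    )
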