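"""Past-samples (PS) windowing, identical in batch and streaming form.

The classifier's input for sample t is the flattened single-precision vector

    v = [u1,t ... u20,t, u1,t-1 ... u20,t-1, ..., u20,t-PS]

i.e. the current 20-channel sample followed by its PS predecessors, newest
first, giving 20*(PS+1) features (800 for the canonical PS = 39).  Offline the
whole window matrix is built in one shot; online a rolling buffer shifts one
position per incoming sample.  The two paths must agree bit for bit — the
streaming detector's scores are only trustworthy if its preprocessing is the
same arithmetic as the one the model was trained on.

No window is emitted until the buffer holds PS+1 samples: the first PS samples
of a stream produce no prediction (at 40 Hz the warm-up is at most 2.5 s for
the PS values in use), rather than fabricating history by padding.
"""

from __future__ import annotations

import numpy as np

from .simulate import GaitRecording

__all__ = [
    "RollingBuffer",
    "batch_windows",
    "window_length",
    "normalize_static",
    "complementary_filter",
    "PastSamplesWindower",
]


def window_length(ps: int, n_channels: int = 20) -> int:
    """Flattened window length: n_channels * (ps + 1)."""
    if ps < 0:
        raise ValueError("ps must be non-negative")
    return n_channels * (ps + 1)


class RollingBuffer:
    """Streaming counterpart of :func:`batch_windows`.

    Holds the most recent PS+1 samples; each :meth:`push` shifts the memory
    one position and, once full, emits the flattened window for the newest
    sample in the exact feature order documented above.
    """

    def __init__(self, ps: int, n_channels: int = 20):
        if ps < 0:
            raise ValueError("ps must be non-negative")
        if n_channels < 1:
            raise ValueError("n_channels must be positive")
        self.ps = ps
        self.n_channels = n_channels
        # newest sample first, matching the emitted feature order
        self._buf = np.zeros((ps + 1, n_channels), dtype=np.float32)
        self.fill_count = 0

    @property
    def capacity(self) -> int:
        return (self.ps + 1) * self.n_channels

    @property
    def full(self) -> bool:
        return self.fill_count >= self.ps + 1

    def push(self, sample: np.ndarray) -> np.ndarray | None:
        """Add one sample; return the flattened window once the buffer is full."""
        sample = np.asarray(sample, dtype=np.float32).ravel()
        if sample.shape != (self.n_channels,):
            raise ValueError(
                f"expected a sample with exactly {self.n_channels} values, "
                f"got shape {sample.shape}"
            )
        if not np.isfinite(sample).all():
            raise ValueError("sample contains non-finite values")
        self._buf[1:] = self._buf[:-1]
        self._buf[0] = sample
        if self.fill_count < self.ps + 1:
            self.fill_count += 1
        if self.full:
            return self._buf.reshape(-1).copy()
        return None


def batch_windows(
    recording: GaitRecording | np.ndarray,
    ps: int,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Build all windows of a recording at once.

    Returns ``(X, y)`` where ``X`` has shape ``(T - ps, n_channels*(ps+1))``
    (float32) and row k is the window for sample index ``k + ps``; ``y`` is
    the label vector aligned the same way (``None`` if no labels available).
    Row k is bit-identical to the window a :class:`RollingBuffer` emits at
    that sample index.
    """
    if isinstance(recording, GaitRecording):
        signals = recording.signals
        if labels is None:
            labels = recording.labels
    else:
        signals = np.asarray(recording, dtype=np.float32)
    t, c = signals.shape
    if ps < 0:
        raise ValueError("ps must be non-negative")
    if t <= ps:
        raise ValueError(f"recording has {t} samples; need more than ps={ps}")
    n_win = t - ps
    # stacked shifted views, newest first: column block j holds sample t-j
    blocks = [signals[ps - j : ps - j + n_win] for j in range(ps + 1)]
    x = np.concatenate(blocks, axis=1).astype(np.float32, copy=False)
    y = None if labels is None else np.asarray(labels)[ps:]
    return x, y


def normalize_static(x, mu, sigma):
    """Legacy whole-dataset standardization y = (x - mu) / sigma, float32.

    Kept for parity with offline pipelines that normalize with dataset-wide
    moments; the deployed model instead normalizes inside its first layer.
    """
    sigma = np.asarray(sigma, dtype=np.float32)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    x = np.asarray(x, dtype=np.float32)
    mu = np.asarray(mu, dtype=np.float32)
    return ((x - mu) / sigma).astype(np.float32)


def complementary_filter(acc_angle, gyro_rate, alpha: float = 0.98, dt: float = 0.025):
    """First-order fusion of integrated gyro rate with accelerometer angle.

    theta_t = alpha * (theta_{t-1} + gyro_t * dt) + (1 - alpha) * acc_angle_t,
    theta_0 = acc_angle_0.  alpha close to 1 trusts the (drifting but smooth)
    gyro integral; alpha = 0 returns the (noisy but unbiased) accelerometer
    angle unchanged.
    """
    acc_angle = np.asarray(acc_angle, dtype=np.float64)
    gyro_rate = np.asarray(gyro_rate, dtype=np.float64)
    if acc_angle.shape != gyro_rate.shape:
        raise ValueError("acc_angle and gyro_rate must have equal length")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    theta = np.empty_like(acc_angle)
    if theta.size == 0:
        return theta.astype(np.float32)
    theta[0] = acc_angle[0]
    for i in range(1, theta.size):
        theta[i] = alpha * (theta[i - 1] + gyro_rate[i] * dt) + (1 - alpha) * acc_angle[i]
    return theta.astype(np.float32)


class PastSamplesWindower:
    """Sklearn-style transformer: (T, C) signal matrix -> (T-ps, C*(ps+1)) windows.

    Stateless apart from its parameters; ``fit`` only validates.  Compatible
    with sklearn pipelines and ``clone`` via get_params/set_params.
    """

    def __init__(self, ps: int = 39):
        self.ps = ps

    def get_params(self, deep: bool = True) -> dict:
        return {"ps": self.ps}

    def set_params(self, **params) -> "PastSamplesWindower":
        for k, v in params.items():
            if k != "ps":
                raise ValueError(f"unknown parameter {k!r}")
            self.ps = v
        return self

    def fit(self, X, y=None) -> "PastSamplesWindower":
        if self.ps < 0:
            raise ValueError("ps must be non-negative")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return batch_windows(np.asarray(X, dtype=np.float32), self.ps)[0]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
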