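"""FoG classifier: a compact CNN+RNN over past-samples windows.

:class:`FogClassifier` is an sklearn-compatible estimator.  ``X`` is a window
matrix from :func:`fogcue.windowing.batch_windows` (one row per sample, length
``n_channels * (ps + 1)``), ``y`` the aligned binary FoG labels.  The network
normalizes inside its first layer (learned beta/gamma with running moments),
so no external standardization step is needed — or wanted, since the deployed
streaming pipeline feeds raw sensor windows.

Scoring is always routed through one fixed-chunk forward pass
(:meth:`FogClassifier.predict_score`): the streaming detector calls the same
routine on the same window sequence, which makes the offline and online score
sequences bit-identical by construction.
"""

from __future__ import annotations

import io
import json
import zipfile

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import F32, Adam, FogNet, bce_loss_and_grad
from .simulate import GaitRecording
from .windowing import batch_windows

__all__ = [
    "FogClassifier",
    "load_model",
    "tune_past_samples",
    "chronological_split",
]

_PREDICT_CHUNK = 512
_MODEL_FORMAT = "fogcue-model"
_MODEL_VERSION = 1


class FogClassifier(ClassifierMixin, BaseEstimator):
    """CNN + two recurrent layers + sigmoid head over past-samples windows.

    Parameters
    ----------
    ps : number of past samples per window (window length is
        ``n_channels * (ps + 1)``; the canonical setting 39 gives 800 inputs).
    conv_filters, conv_kernel : 1-D convolution along the time axis, same
        padding; with the defaults the conv block flattens to
        ``32 * (ps + 1)`` features (1280 at ps=39).
    recurrent_units : sizes of the two tanh RNN layers.
    epochs, batch_size, learning_rate : Adam training schedule.
    class_weight : "balanced" applies inverse-frequency sample weights —
        FoG is rare (a few percent of samples), so unweighted training tends
        to collapse to the majority class; None disables.
    threshold : score threshold for :meth:`predict`; detection is strict
        (score must exceed the threshold).
    random_state : seed for weight init and minibatch shuffling.
    """

    def __init__(
        self,
        ps: int = 39,
        conv_filters: int = 32,
        conv_kernel: int = 5,
        recurrent_units: tuple[int, int] = (64, 32),
        epochs: int = 10,
        batch_size: int = 128,
        learning_rate: float = 1e-3,
        class_weight: str | None = "balanced",
        threshold: float = 0.9,
        random_state: int = 0,
    ):
        self.ps = ps
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.recurrent_units = recurrent_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.class_weight = class_weight
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------ building

    def _infer_channels(self, n_features: int) -> int:
        if n_features % (self.ps + 1) != 0:
            raise ValueError(
                f"window length {n_features} is not a multiple of ps+1={self.ps + 1}"
            )
        return n_features // (self.ps + 1)

    def build(self, n_channels: int = 20) -> "FogClassifier":
        """Initialize an untrained network (also done implicitly by fit)."""
        rng = np.random.default_rng(self.random_state)
        self.net_ = FogNet(
            ps=self.ps,
            n_channels=n_channels,
            conv_filters=self.conv_filters,
            conv_kernel=self.conv_kernel,
            recurrent_units=tuple(self.recurrent_units),
            rng=rng,
        )
        self.n_channels_ = n_channels
        self.n_features_in_ = self.net_.input_len
        self.flatten_size_ = self.net_.flatten_len
        self.classes_ = np.array([0, 1])
        self.history_ = []
        return self

    # ------------------------------------------------------------ training

    def fit(self, X, y) -> "FogClassifier":
        X = np.asarray(X, dtype=F32)
        y = np.asarray(y).astype(np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_windows, window_len) aligned with y")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ValueError("labels must be binary {0, 1}")
        if classes.size < 2:
            raise ValueError(
                "training split contains a single class; regenerate or extend "
                "the recording so both FoG and non-FoG samples are present"
            )
        self.build(self._infer_channels(X.shape[1]))

        if self.class_weight == "balanced":
            n_pos = float(y.sum())
            n_neg = float(y.size - n_pos)
            w_pos = y.size / (2.0 * n_pos)
            w_neg = y.size / (2.0 * n_neg)
            weights = np.where(y == 1.0, w_pos, w_neg)
        elif self.class_weight is None:
            weights = np.ones_like(y)
        else:
            raise ValueError("class_weight must be 'balanced' or None")

        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state) & 0x7FFFFFFF, 2])
        )
        opt = Adam(self.net_, lr=self.learning_rate)
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb, wb = X[idx], y[idx], weights[idx]
                scores, cache = self.net_.forward(xb, training=True)
                loss, dz = bce_loss_and_grad(cache["z"], scores, yb, wb)
                grads = self.net_.backward(cache, dz)
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            self.history_.append(epoch_loss / max(n_batches, 1))
        return self

    # ----------------------------------------------------------- inference

    def predict_score(self, X) -> np.ndarray:
        """Raw sigmoid FoG scores in [0, 1], float32, fixed-chunk evaluation."""
        self._check_fitted()
        X = np.asarray(X, dtype=F32)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[None, :]
        out = np.empty(X.shape[0], dtype=F32)
        for start in range(0, X.shape[0], _PREDICT_CHUNK):
            chunk = np.ascontiguousarray(X[start : start + _PREDICT_CHUNK])
            out[start : start + chunk.shape[0]] = self.net_.forward(chunk)[0]
        return out[0] if squeeze else out

    def predict_proba(self, X) -> np.ndarray:
        s = np.atleast_1d(self.predict_score(X))
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        """Binary FoG decision: 1 iff score strictly exceeds the threshold."""
        s = np.atleast_1d(self.predict_score(X))
        return (s > self.threshold).astype(np.uint8)

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not built/fitted; call fit() or build()")

    # --------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Write a self-describing container: JSON header + float32 arrays."""
        self._check_fitted()
        header = {
            "format": _MODEL_FORMAT,
            "version": _MODEL_VERSION,
            "config": {
                "ps": self.ps,
                "n_channels": self.n_channels_,
                "conv_filters": self.conv_filters,
                "conv_kernel": self.conv_kernel,
                "recurrent_units": list(self.recurrent_units),
                "threshold": self.threshold,
            },
        }
        buf = io.BytesIO()
        np.savez(buf, **self.net_.to_arrays())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("header.json", json.dumps(header, indent=1))
            zf.writestr("arrays.npz", buf.getvalue())


def load_model(path, expected_ps: int | None = None) -> FogClassifier:
    """Load a model container written by :meth:`FogClassifier.save`."""
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
            arrays = {k: arrays[k] for k in arrays.files}
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as e:
        raise ValueError(f"not a valid model container: {e}") from e
    if header.get("format") != _MODEL_FORMAT or header.get("version") != _MODEL_VERSION:
        raise ValueError("unrecognized model container format/version")
    cfg = header["config"]
    if expected_ps is not None and cfg["ps"] != expected_ps:
        raise ValueError(f"model was trained with ps={cfg['ps']}, expected {expected_ps}")
    clf = FogClassifier(
        ps=cfg["ps"],
        conv_filters=cfg["conv_filters"],
        conv_kernel=cfg["conv_kernel"],
        recurrent_units=tuple(cfg["recurrent_units"]),
        threshold=cfg["threshold"],
    )
    clf.build(cfg["n_channels"])
    clf.net_.load_arrays(arrays)
    return clf


# ------------------------------------------------------------------ tuning


def chronological_split(n: int, train_fraction: float = 0.6) -> tuple[slice, slice]:
    """First 60% of samples for training, the rest for testing (no shuffling:
    gait data are autocorrelated, so a random split would leak)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    cut = int(n * train_fraction)
    return slice(0, cut), slice(cut, n)


def _f1(pred: np.ndarray, target: np.ndarray) -> float:
    tp = int(np.sum((pred == 1) & (target == 1)))
    fp = int(np.sum((pred == 1) & (target == 0)))
    fn = int(np.sum((pred == 0) & (target == 1)))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def tune_past_samples(
    recording: GaitRecording,
    ps_grid: tuple[int, ...] = (15, 30, 40, 60, 100),
    train_fraction: float = 0.6,
    **fit_params,
) -> tuple[int, pd.DataFrame]:
    """Personalize the PS hyperparameter on one recording.

    Trains one model per grid value on the chronological 60% split, scores
    sample-level F1 on the held-out 40%, and returns the argmax (ties broken
    toward the smaller PS, i.e. the cheaper deployed model) plus the full
    score table.
    """
    if len(ps_grid) == 0:
        raise ValueError("ps_grid must be non-empty")
    rows = []
    for ps in ps_grid:
        clf = FogClassifier(ps=ps, **fit_params)
        X, y = batch_windows(recording, ps)
        tr, te = chronological_split(X.shape[0], train_fraction)
        clf.fit(X[tr], y[tr])
        f1 = _f1(clf.predict(X[te]), np.asarray(y[te]))
        rows.append({"ps": ps, "f1": f1})
    table = pd.DataFrame(rows)
    # stable argmax with smaller-PS tie-break
    best = table.sort_values(["f1", "ps"], ascending=[False, True]).iloc[0]
    return int(best["ps"]), table
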