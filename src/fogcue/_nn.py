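"""Single-precision CNN+RNN network core with manual backpropagation.

The detection model is deliberately tiny — it has to run every 25 ms on an
embedded-class CPU — so it is implemented directly on NumPy rather than
through a deep-learning framework:

    batch-norm (learned beta/gamma, running moments)
      -> reshape to (time, channels), newest sample first
      -> 1-D convolution along time (same padding) + ReLU
      -> simple tanh RNN (return sequences)
      -> simple tanh RNN (return last state)
      -> dense + sigmoid, one output unit (FoG score)

Every parameter, activation and gradient is float32; the forward pass is the
same arithmetic whether one window or a batch is scored, which is what makes
bit-identical offline/online behaviour enforceable one level up.

Flattened feature count between the conv block and the recurrent block is
conv_filters * (ps + 1): 32 filters at PS = 39 give the canonical 1280.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32
BN_EPS = F32(1e-3)
BN_MOMENTUM = F32(0.99)  # running = m*running + (1-m)*batch


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0] if len(shape) == 2 else int(np.prod(shape[:-1])), shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(F32)


class FogNet:
    """Parameter container + forward/backward for the detection network."""

    PARAM_NAMES = (
        "bn_gamma", "bn_beta", "conv_W", "conv_b",
        "rnn1_Wx", "rnn1_Wh", "rnn1_b",
        "rnn2_Wx", "rnn2_Wh", "rnn2_b",
        "dense_W", "dense_b",
    )
    STATE_NAMES = ("bn_mean", "bn_var")

    def __init__(
        self,
        ps: int,
        n_channels: int = 20,
        conv_filters: int = 32,
        conv_kernel: int = 5,
        recurrent_units: tuple[int, int] = (64, 32),
        rng: np.random.Generator | None = None,
    ):
        if ps < 0:
            raise ValueError("ps must be non-negative")
        if conv_kernel < 1 or conv_filters < 1:
            raise ValueError("conv_kernel and conv_filters must be positive")
        self.ps = ps
        self.n_channels = n_channels
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.recurrent_units = tuple(recurrent_units)
        self.input_len = n_channels * (ps + 1)
        self.flatten_len = conv_filters * (ps + 1)

        rng = rng or np.random.default_rng(0)
        c, f, k = n_channels, conv_filters, conv_kernel
        u1, u2 = self.recurrent_units
        L = self.input_len
        self.params: dict[str, np.ndarray] = {
            "bn_gamma": np.ones(L, dtype=F32),
            "bn_beta": np.zeros(L, dtype=F32),
            "conv_W": _glorot(rng, (k, c, f)),
            "conv_b": np.zeros(f, dtype=F32),
            "rnn1_Wx": _glorot(rng, (f, u1)),
            "rnn1_Wh": _orthogonal(rng, u1),
            "rnn1_b": np.zeros(u1, dtype=F32),
            "rnn2_Wx": _glorot(rng, (u1, u2)),
            "rnn2_Wh": _orthogonal(rng, u2),
            "rnn2_b": np.zeros(u2, dtype=F32),
            "dense_W": _glorot(rng, (u2, 1)),
            "dense_b": np.zeros(1, dtype=F32),
        }
        self.state: dict[str, np.ndarray] = {
            "bn_mean": np.zeros(L, dtype=F32),
            "bn_var": np.ones(L, dtype=F32),
        }

    # ------------------------------------------------------------------ fwd

    def forward(self, x: np.ndarray, training: bool = False):
        """Score a batch of windows.

        Returns (scores, cache); cache is None unless training.  ``x`` must be
        float32 of shape (B, input_len).
        """
        p = self.params
        if x.ndim != 2 or x.shape[1] != self.input_len:
            raise ValueError(
                f"expected windows of length {self.input_len}, got shape {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=F32)
        B = x.shape[0]
        T = self.ps + 1

        # batch norm over the flat feature axis
        if training:
            mu = x.mean(axis=0, dtype=F32)
            var = x.var(axis=0, dtype=F32)
            m = BN_MOMENTUM
            self.state["bn_mean"] = (m * self.state["bn_mean"] + (1 - m) * mu).astype(F32)
            self.state["bn_var"] = (m * self.state["bn_var"] + (1 - m) * var).astype(F32)
        else:
            mu = self.state["bn_mean"]
            var = self.state["bn_var"]
        inv_std = F32(1.0) / np.sqrt(var + BN_EPS, dtype=F32)
        xhat = (x - mu) * inv_std
        y = p["bn_gamma"] * xhat + p["bn_beta"]

        # windows are stored newest-first; flip so the recurrent scan runs
        # oldest -> newest and the last hidden state is anchored on the
        # current sample (the one being classified)
        seq = np.ascontiguousarray(y.reshape(B, T, self.n_channels)[:, ::-1, :])

        # 1-D conv along time, same padding
        k = self.conv_kernel
        pad_l, pad_r = (k - 1) // 2, k - 1 - (k - 1) // 2
        seq_p = np.pad(seq, ((0, 0), (pad_l, pad_r), (0, 0)))
        wc = p["conv_W"].reshape(k * self.n_channels, self.conv_filters)
        # unrolled input: (B, T, k*C)
        unroll = np.empty((B, T, k * self.n_channels), dtype=F32)
        for j in range(k):
            unroll[:, :, j * self.n_channels : (j + 1) * self.n_channels] = seq_p[:, j : j + T, :]
        conv_pre = unroll.reshape(B * T, -1) @ wc
        conv_pre = conv_pre.reshape(B, T, self.conv_filters) + p["conv_b"]
        conv_out = np.maximum(conv_pre, F32(0.0))

        h1 = self._rnn_forward(conv_out, "rnn1")
        h2 = self._rnn_forward(h1, "rnn2")
        z = h2[:, -1, :] @ p["dense_W"] + p["dense_b"]  # (B, 1) logits
        z = z[:, 0]
        scores = (F32(1.0) / (F32(1.0) + np.exp(-z))).astype(F32)

        cache = None
        if training:
            cache = dict(
                x=x, mu=mu, inv_std=inv_std, xhat=xhat,
                unroll=unroll, conv_pre=conv_pre, conv_out=conv_out,
                h1=h1, h2=h2, z=z,
            )
        return scores, cache

    def _rnn_forward(self, x_seq: np.ndarray, name: str) -> np.ndarray:
        """Simple tanh RNN over (B, T, in) -> hidden sequence (B, T, units)."""
        p = self.params
        wx, wh, b = p[f"{name}_Wx"], p[f"{name}_Wh"], p[f"{name}_b"]
        B, T, _ = x_seq.shape
        units = wx.shape[1]
        h = np.zeros((B, T, units), dtype=F32)
        prev = np.zeros((B, units), dtype=F32)
        xw = x_seq.reshape(B * T, -1) @ wx
        xw = xw.reshape(B, T, units) + b
        for t in range(T):
            prev = np.tanh(xw[:, t, :] + prev @ wh)
            h[:, t, :] = prev
        return h

    # ------------------------------------------------------------------ bwd

    def backward(self, cache: dict, dz: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter.

        ``dz`` is dLoss/dlogit, shape (B,) float32.
        """
        p = self.params
        B = dz.shape[0]
        T = self.ps + 1
        g: dict[str, np.ndarray] = {}

        h2_last = cache["h2"][:, -1, :]
        g["dense_W"] = h2_last.T @ dz[:, None]
        g["dense_b"] = dz.sum(keepdims=True).astype(F32)
        dh2 = np.zeros_like(cache["h2"])
        dh2[:, -1, :] = dz[:, None] * p["dense_W"][:, 0][None, :]

        dh1 = self._rnn_backward(cache["h1"], cache["h2"], dh2, "rnn2", g)
        dconv = self._rnn_backward(cache["conv_out"], cache["h1"], dh1, "rnn1", g)

        # ReLU
        dconv = dconv * (cache["conv_pre"] > 0)

        # conv
        k, c, f = self.conv_kernel, self.n_channels, self.conv_filters
        g["conv_b"] = dconv.sum(axis=(0, 1)).astype(F32)
        unroll2 = cache["unroll"].reshape(B * T, k * c)
        dmat = dconv.reshape(B * T, f)
        g["conv_W"] = (unroll2.T @ dmat).reshape(k, c, f)
        dunroll = (dmat @ self._conv_wc().T).reshape(B, T, k, c)
        pad_l = (k - 1) // 2
        pad_r = k - 1 - pad_l
        dseq_p = np.zeros((B, T + k - 1, c), dtype=F32)
        for j in range(k):
            dseq_p[:, j : j + T, :] += dunroll[:, :, j, :]
        dseq = dseq_p[:, pad_l : pad_l + T, :]
        dy = dseq[:, ::-1, :].reshape(B, self.input_len)  # undo the time flip

        # batch norm
        xhat, inv_std = cache["xhat"], cache["inv_std"]
        g["bn_gamma"] = (dy * xhat).sum(axis=0).astype(F32)
        g["bn_beta"] = dy.sum(axis=0).astype(F32)
        dxhat = dy * p["bn_gamma"]
        # gradient of (x - mu(x)) * inv_std(x): standard batch-norm backward
        n = F32(B)
        dx = (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=0)
            - xhat * (dxhat * xhat).sum(axis=0)
        )
        g["_dx"] = dx.astype(F32)  # unused by the optimizer; kept for checks
        return g

    def _conv_wc(self) -> np.ndarray:
        return self.params["conv_W"].reshape(
            self.conv_kernel * self.n_channels, self.conv_filters
        )

    def _rnn_backward(
        self, x_seq: np.ndarray, h: np.ndarray, dh: np.ndarray, name: str,
        g: dict[str, np.ndarray],
    ) -> np.ndarray:
        """BPTT for one simple RNN layer; returns gradient w.r.t. its input."""
        p = self.params
        wx, wh = p[f"{name}_Wx"], p[f"{name}_Wh"]
        B, T, units = h.shape
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros(units, dtype=F32)
        dx_seq = np.zeros_like(x_seq)
        dnext = np.zeros((B, units), dtype=F32)
        for t in range(T - 1, -1, -1):
            dtot = dh[:, t, :] + dnext
            da = dtot * (F32(1.0) - h[:, t, :] * h[:, t, :])  # tanh'
            db += da.sum(axis=0)
            dwx += x_seq[:, t, :].T @ da
            if t > 0:
                dwh += h[:, t - 1, :].T @ da
                dnext = da @ wh.T
            else:
                dnext = np.zeros((B, units), dtype=F32)
            dx_seq[:, t, :] = da @ wx.T
        g[f"{name}_Wx"] = dwx.astype(F32)
        g[f"{name}_Wh"] = dwh.astype(F32)
        g[f"{name}_b"] = db
        return dx_seq

    # ------------------------------------------------------------ serialize

    def to_arrays(self) -> dict[str, np.ndarray]:
        out = {f"param_{k}": v for k, v in self.params.items()}
        out.update({f"state_{k}": v for k, v in self.state.items()})
        return out

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_NAMES:
            a = np.asarray(arrays[f"param_{k}"], dtype=F32)
            if a.shape != self.params[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: file {a.shape} vs model {self.params[k].shape}"
                )
            self.params[k] = a
        for k in self.STATE_NAMES:
            self.state[k] = np.asarray(arrays[f"state_{k}"], dtype=F32)


class Adam:
    """Adam optimizer on a FogNet parameter dict, float32 moments.

    Gradients are clipped to a global L2 norm before the update: BPTT through
    the tanh recurrences can explode on occasional minibatches, and a single
    unclipped step is enough to derail the whole fit.
    """

    def __init__(self, net: FogNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7, clip_norm: float = 1.0):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = F32(lr), F32(beta1), F32(beta2), F32(eps)
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            sq = sum(float(np.sum(grads[k].astype(np.float64) ** 2))
                     for k in self.net.params)
            gnorm = np.sqrt(sq)
            if gnorm > self.clip_norm:
                scale = F32(self.clip_norm / gnorm)
                grads = {k: v * scale if k in self.net.params else v
                         for k, v in grads.items()}
        self.t += 1
        b1t = F32(1.0) - self.b1 ** self.t
        b2t = F32(1.0) - self.b2 ** self.t
        for k, param in self.net.params.items():
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (F32(1.0) - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (F32(1.0) - self.b2) * gk * gk
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss_and_grad(
    z: np.ndarray, scores: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy from logits; returns (mean loss, dL/dz)."""
    z64 = z.astype(np.float64)
    # log(1 + e^z) computed stably
    softplus = np.logaddexp(0.0, z64)
    loss = float(np.mean(w * (softplus - y * z64)))
    dz = (w * (scores.astype(np.float64) - y) / z.shape[0]).astype(F32)
    return loss, dz
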