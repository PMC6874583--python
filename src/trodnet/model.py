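"""Per-condition convolutional ERP classifier.

The network ingests one observation (192 rows x 332 samples: 64 channels
from each of three conditions) and predicts concussed vs control. Layer
stack:

* per-condition spatial convolution — each condition's 64-channel block is
  convolved with M = 5 kernels of size (64, 1), i.e. each kernel learns one
  scalp topography whose temporal activation is the filter output; ReLU;
* concatenation of the three 5-map outputs into 15 feature maps;
* valid max-pooling over time, pool (1, 10), stride (1, 5) -> 65 samples;
* dense layer of 100 units, ReLU;
* 2-way softmax output.

L2 regularization (lambda = 0.25) is applied to all weights (not biases);
training uses Adam (alpha = 5e-4) for 500 steps, each on a batch of 160
observations sampled without replacement within the step.

Because the spatial kernels span all 64 channels at a single time point,
every convolution reduces to a matrix product, so the whole network is
implemented directly on NumPy arrays with an explicit backward pass. This
keeps the model dependency-free and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import _arrayzip

logger = logging.getLogger(__name__)

try:  # fused max-pool kernels; the pure-NumPy path below is equivalent
    import numba

    @numba.njit(cache=False)
    def _maxpool_fwd(Fm, stride, pool, n_windows, Pm, arg):
        B, nm, _ = Fm.shape
        for b in range(B):
            for j in range(nm):
                for w in range(n_windows):
                    base = w * stride
                    mx = Fm[b, j, base]
                    am = 0
                    for k in range(1, pool):
                        v = Fm[b, j, base + k]
                        if v > mx:
                            mx = v
                            am = k
                    Pm[b, j, w] = mx
                    arg[b, j, w] = am

    @numba.njit(cache=False)
    def _maxpool_bwd(dPm, arg, stride, dFm):
        B, nm, n_windows = dPm.shape
        for b in range(B):
            for j in range(nm):
                for w in range(n_windows):
                    dFm[b, j, w * stride + arg[b, j, w]] += dPm[b, j, w]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class ModelConfig:
    n_conditions: int = 3
    n_channels: int = 64
    n_samples: int = 332
    n_maps: int = 5
    pool_size: int = 10
    pool_stride: int = 5
    dense_units: int = 100
    n_classes: int = 2
    l2: float = 0.25
    learning_rate: float = 5e-4
    n_steps: int = 500
    batch_size: int = 160
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7

    def __post_init__(self):
        for name in (
            "n_conditions", "n_channels", "n_samples", "n_maps", "pool_size",
            "pool_stride", "dense_units", "n_classes", "n_steps", "batch_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.l2 < 0 or self.learning_rate <= 0:
            raise ValueError("invalid l2 or learning rate")

    @property
    def n_rows(self) -> int:
        return self.n_conditions * self.n_channels

    @property
    def pooled_length(self) -> int:
        """Valid pooling: floor((S - pool) / stride) + 1."""
        return (self.n_samples - self.pool_size) // self.pool_stride + 1

    @property
    def n_features(self) -> int:
        return self.pooled_length * self.n_conditions * self.n_maps

    def parameter_count(self) -> int:
        c = self.n_conditions * (self.n_channels * self.n_maps + self.n_maps)
        d = self.n_features * self.dense_units + self.dense_units
        o = self.dense_units * self.n_classes + self.n_classes
        return c + d + o


def _glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class TRODNet:
    """The classifier: configuration plus a flat dict of parameter arrays.

    Parameters: ``W_conv`` (conditions, channels, maps), ``b_conv``
    (conditions, maps), ``W_dense`` (features, dense_units), ``b_dense``,
    ``W_out`` (dense_units, classes), ``b_out``.
    """

    WEIGHT_KEYS = ("W_conv", "W_dense", "W_out")

    def __init__(self, config: ModelConfig | None = None, seed=0):
        self.config = config or ModelConfig()
        self.params = self._init_params(np.random.default_rng(seed))
        self._ws: dict = {}

    def _buf(self, name: str, shape, dtype=np.float32) -> np.ndarray:
        """Reusable workspace array; per-step allocation otherwise dominates."""
        key = (name, shape, np.dtype(dtype).str)
        if key not in self._ws:
            self._ws[key] = np.zeros(shape, dtype)
        return self._ws[key]

    def _init_params(self, rng) -> dict:
        c = self.config
        params = {
            "W_conv": _glorot_uniform(
                rng, (c.n_conditions, c.n_channels, c.n_maps), c.n_channels, c.n_maps
            ),
            "b_conv": np.zeros((c.n_conditions, c.n_maps)),
            "W_dense": _glorot_uniform(
                rng, (c.n_features, c.dense_units), c.n_features, c.dense_units
            ),
            "b_dense": np.zeros(c.dense_units),
            "W_out": _glorot_uniform(
                rng, (c.dense_units, c.n_classes), c.dense_units, c.n_classes
            ),
            "b_out": np.zeros(c.n_classes),
        }
        return {k: v.astype(np.float32) for k, v in params.items()}

    # -- forward -----------------------------------------------------------

    def _pool_windows(self):
        c = self.config
        starts = c.pool_stride * np.arange(c.pooled_length)
        return starts[:, None] + np.arange(c.pool_size)[None, :]

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """Forward pass on a batch (B, 192, 332) -> logits (B, 2)."""
        c = self.config
        X = np.ascontiguousarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (c.n_rows, c.n_samples):
            raise ValueError(
                f"expected observations of shape {(c.n_rows, c.n_samples)}, "
                f"got {X.shape[1:]}"
            )
        B = X.shape[0]
        Xc = X.reshape(B, c.n_conditions, c.n_channels, c.n_samples)
        # spatial convolution == per-condition matrix product over channels:
        # (1, D, M, C) @ (B, D, C, S) -> (B, D, M, S)
        nm = c.n_conditions * c.n_maps
        Wt = np.ascontiguousarray(self.params["W_conv"].transpose(0, 2, 1))
        Z1 = np.matmul(
            Wt[None], Xc, out=self._buf("Z1", (B, c.n_conditions, c.n_maps, c.n_samples))
        )
        Z1 += self.params["b_conv"][None, :, :, None]
        A1 = np.maximum(Z1, 0.0, out=Z1)  # ReLU in place; pre-activations not needed
        # condition-major map axis; pooling runs over the contiguous time axis
        Fm = A1.reshape(B, nm, c.n_samples)
        win = None
        if _HAVE_NUMBA:
            Pm = self._buf("Pm", (B, nm, c.pooled_length))
            arg = self._buf("arg", (B, nm, c.pooled_length), np.int64)
            _maxpool_fwd(Fm, c.pool_stride, c.pool_size, c.pooled_length, Pm, arg)
            if not want_cache:
                arg = None
        else:
            win = self._pool_windows()
            Fw = Fm[:, :, win]  # (B, maps, pooled, pool_size)
            Pm = Fw.max(axis=3)
            if want_cache:
                # first-maximum index; argmax on bool short-circuits
                arg = (Fw == Pm[..., None]).argmax(axis=3)
            else:
                arg = None
        # flatten as (pooled, maps) row-major to match the stated layout
        flat = self._buf("flat", (B, c.n_features))
        flat.reshape(B, c.pooled_length, nm)[...] = Pm.transpose(0, 2, 1)
        Zd = flat @ self.params["W_dense"] + self.params["b_dense"]
        H = np.maximum(Zd, 0.0)
        logits = H @ self.params["W_out"] + self.params["b_out"]
        if not want_cache:
            return logits
        cache = dict(Xc=Xc, A1=A1, Fm=Fm, win=win, arg=arg, flat=flat, Zd=Zd, H=H)
        return logits, cache

    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def predict_proba(self, X: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Per-observation class probabilities (rows sum to 1)."""
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        out = [self.softmax(self.forward(X[i : i + chunk])) for i in range(0, X.shape[0], chunk)]
        return np.concatenate(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- loss and gradients ------------------------------------------------

    def _weight_penalty(self) -> float:
        return self.config.l2 * sum(
            float((self.params[k] ** 2).sum()) for k in self.WEIGHT_KEYS
        )

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        ce = -np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean()
        return float(ce + self._weight_penalty())

    def _backward(self, X, y):
        c = self.config
        y = np.asarray(y)
        logits, cache = self.forward(X, want_cache=True)
        B = logits.shape[0]
        p = self.softmax(logits)
        ce = -np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean()
        loss = ce + self._weight_penalty()

        dlogits = p.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {}
        grads["W_out"] = cache["H"].T @ dlogits + 2 * c.l2 * self.params["W_out"]
        grads["b_out"] = dlogits.sum(axis=0)
        dH = dlogits @ self.params["W_out"].T
        dZd = dH * (cache["Zd"] > 0)
        grads["W_dense"] = cache["flat"].T @ dZd + 2 * c.l2 * self.params["W_dense"]
        grads["b_dense"] = dZd.sum(axis=0)
        dflat = dZd @ self.params["W_dense"].T
        # back to (B, maps, pooled), then scatter into time via the argmax
        nm = c.n_conditions * c.n_maps
        dPm = dflat.reshape(B, c.pooled_length, nm).transpose(0, 2, 1)
        dFm = self._buf("dFm", (B, nm, c.n_samples))
        dFm.fill(0.0)
        if _HAVE_NUMBA:
            _maxpool_bwd(np.ascontiguousarray(dPm), cache["arg"], c.pool_stride, dFm)
        else:
            cols = cache["win"][None, None, :, 0] + cache["arg"]  # time index
            bidx = np.arange(B)[:, None, None]
            jidx = np.arange(nm)[None, :, None]
            np.add.at(dFm, (bidx, jidx, cols), dPm)
        dA1 = dFm.reshape(B, c.n_conditions, c.n_maps, c.n_samples)
        relu_mask = np.greater(cache["A1"], 0, out=self._buf("relu", dA1.shape, bool))
        dZ1 = np.multiply(dA1, relu_mask, out=self._buf("dZ1", dA1.shape))
        dZ1t = self._buf("dZ1t", (B, c.n_conditions, c.n_samples, c.n_maps))
        dZ1t[...] = dZ1.transpose(0, 1, 3, 2)
        grads["W_conv"] = (
            np.matmul(
                cache["Xc"], dZ1t,
                out=self._buf("dWc", (B, c.n_conditions, c.n_channels, c.n_maps)),
            ).sum(axis=0)
            + 2 * c.l2 * self.params["W_conv"]
        )
        grads["b_conv"] = dZ1.sum(axis=(0, 3))
        return float(loss), grads


@dataclass
class TrainResult:
    loss_trace: np.ndarray

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])


def build_model(config: ModelConfig | None = None, seed=0) -> TRODNet:
    """An untrained network with seeded variance-scaling initialization."""
    return TRODNet(config, seed=seed)


def train(
    model: TRODNet,
    X: np.ndarray,
    y: np.ndarray,
    seed=0,
    reinitialize: bool = True,
) -> TrainResult:
    """Train in place; returns the per-step loss trace.

    Each of the ``config.n_steps`` optimization steps draws
    ``config.batch_size`` observations uniformly without replacement (the
    full set, once, if fewer are available) and applies one Adam update to
    the cross-entropy + L2 objective. Deterministic under a fixed seed.
    """
    c = model.config
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must align")
    rng = np.random.default_rng(seed)
    if reinitialize:
        model.params = model._init_params(rng)

    n = X.shape[0]
    batch = c.batch_size
    if n < batch:
        logger.info("only %d observations (< batch size %d); using full set", n, batch)
        batch = n

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    trace = np.empty(c.n_steps)
    X = np.ascontiguousarray(X, dtype=np.float32)
    # reused batch buffer: per-step allocation (and its page faults) dominate
    # the gather cost otherwise
    Xbuf = np.zeros((batch,) + X.shape[1:], dtype=np.float32)
    for step in range(c.n_steps):
        # sorted indices: the same uniform without-replacement draw, but a
        # cache-friendly gather (batch order does not affect the gradient)
        idx = np.sort(rng.choice(n, size=batch, replace=False))
        X.take(idx, axis=0, out=Xbuf, mode="clip")
        loss, grads = model._backward(Xbuf, y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at step {step}; last finite losses: "
                f"{trace[max(0, step - 5) : step]}"
            )
        trace[step] = loss
        t = step + 1
        for k, g in grads.items():
            m[k] = c.adam_beta1 * m[k] + (1 - c.adam_beta1) * g
            v[k] = c.adam_beta2 * v[k] + (1 - c.adam_beta2) * g * g
            mhat = m[k] / (1 - c.adam_beta1**t)
            vhat = v[k] / (1 - c.adam_beta2**t)
            model.params[k] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)
    return TrainResult(loss_trace=trace)


def predict_proba(model: TRODNet, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: TRODNet, path) -> None:
    path = str(path).removesuffix(".npz")
    _arrayzip.savez(path, **model.params)
    with open(path + ".json", "w") as fh:
        json.dump(asdict(model.config), fh, indent=1)


def load_checkpoint(path) -> TRODNet:
    path = str(path).removesuffix(".npz")
    with open(path + ".json") as fh:
        config = ModelConfig(**json.load(fh))
    model = TRODNet(config)
    with np.load(path + ".npz") as npz:
        model.params = {k: npz[k] for k in npz.files}
    return model
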