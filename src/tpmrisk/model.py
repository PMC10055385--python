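"""The 8-hidden-layer convolutional risk model, implemented on NumPy.

Layer stack: time-axis convolution (32 filters, 1 x 131, same padding,
ReLU) -> 2x2 average pooling -> time-axis convolution (2 filters, 1 x 131,
same padding, ReLU) -> 1x3 max pooling -> flatten -> concatenation with
age/sex -> dense 128 (LeakyReLU) -> dropout 0.3 -> sigmoid output.  Trained
with Adam on binary cross-entropy.

No deep-learning framework is assumed: convolutions use a single-row kernel,
so each is a 1-D convolution along the week axis and is evaluated as one
matrix product against an unrolled (Toeplitz) kernel matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConstructionError, InferenceError, TrainingError
from .vocab_tpm import TemporalPhenomicMap, stack_maps

__all__ = ["ModelSpec", "Network", "TrainedModel", "build_model", "train", "predict"]

HIDDEN_LAYERS = (
    "conv2d",
    "average_pooling2d",
    "conv2d",
    "max_pooling2d",
    "flatten",
    "concatenate",
    "dense",
    "dropout",
)


@dataclass
class ModelSpec:
    conv1_filters: int = 32
    conv2_filters: int = 2
    conv_kernel_weeks: int = 131
    pool1: tuple[int, int] = (2, 2)  # average pooling (rows, weeks)
    pool2: tuple[int, int] = (1, 3)  # max pooling (rows, weeks)
    dense_units: int = 128
    dropout_rate: float = 0.3
    leaky_alpha: float = 0.3  # dense-layer leaky rectifier slope
    # rectifier slope for the convolutional layers: a hair above zero so the
    # 2-filter second block cannot die wholesale and freeze training
    conv_leaky_alpha: float = 0.01
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 64
    seed: int = 0
    class_weighted: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConstructionError("dropout_rate must lie in [0, 1)")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ConstructionError("epochs and batch_size must be positive")


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _toeplitz(kern: np.ndarray, width: int, out: np.ndarray | None = None) -> np.ndarray:
    """Unroll a (c_out, c_in, k) same-padding kernel into a
    (c_in * padded_width, c_out * width) matrix.  ``out`` may be a buffer
    from a previous call with the same shape (only the nonzero band of the
    unrolled matrix is rewritten)."""
    c_out, c_in, kw = kern.shape
    wp = width + kw - 1
    if out is None:
        out = np.zeros((c_in, wp, c_out, width), dtype=np.float32)
    a4 = out.reshape(c_in, wp, c_out, width)
    kt = kern.transpose(1, 2, 0)  # (c_in, kw, c_out)
    for w in range(width):
        a4[:, w : w + kw, :, w] = kt
    return a4.reshape(c_in * wp, c_out * width)


def _fold_toeplitz_grad(da: np.ndarray, c_out: int, c_in: int, kw: int, width: int) -> np.ndarray:
    da4 = da.reshape(c_in, width + kw - 1, c_out, width)
    dk = np.zeros((c_out, c_in, kw), dtype=np.float32)
    for w in range(width):
        dk += da4[:, w : w + kw, :, w].transpose(2, 0, 1)
    return dk


class _ConvTime:
    """Same-padded convolution along the last (week) axis, ReLU activation."""

    def __init__(self, c_in: int, c_out: int, kw: int, rng: np.random.Generator, alpha: float = 0.0):
        self.c_in, self.c_out, self.kw = c_in, c_out, kw
        self.alpha = alpha
        fan_in, fan_out = c_in * kw, c_out * kw
        self.kern = _glorot(rng, (c_out, c_in, kw), fan_in, fan_out)
        # small positive bias keeps the few wide rectifier filters alive at
        # the start of training (with only 2 filters in the second block, a
        # zero init lets whole layers die and freeze the network at chance)
        self.bias = np.full(c_out, 0.05, dtype=np.float32)
        self._cache = None
        self._buf: dict[str, np.ndarray] = {}

    def _scratch(self, key: str, shape, zero: bool = False) -> np.ndarray:
        # fresh 10-100 MB allocations per batch are page-fault bound on
        # small machines, so scratch buffers are reused across batches
        buf = self._buf.get(key)
        if buf is None or buf.shape != tuple(shape):
            buf = np.zeros(shape, dtype=np.float32)
            self._buf[key] = buf
        elif zero:
            buf.fill(0.0)
        return buf

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # bias-add and ReLU run in the contiguous (b, r, c_out, w) layout;
        # broadcasting over the transposed view is an order of magnitude slower
        b, c_in, r, w = x.shape
        pl = (self.kw - 1) // 2
        wp = w + self.kw - 1
        xm4 = self._scratch("xm4", (b, r, c_in, wp), zero=True)
        xm4[:, :, :, pl : pl + w] = x.transpose(0, 2, 1, 3)
        xm = xm4.reshape(b * r, c_in * wp)
        a_buf = self._buf.get("a")
        a = _toeplitz(self.kern, w, out=a_buf if a_buf is not None and a_buf.size == c_in * wp * self.c_out * w else None)
        self._buf["a"] = a
        ym = self._scratch("ym", (b * r, self.c_out * w))
        np.matmul(xm, a, out=ym)
        y4 = ym.reshape(b, r, self.c_out, w)
        y4 += self.bias[None, None, :, None]
        if self.alpha > 0:
            y4[y4 < 0] *= self.alpha
        else:
            np.maximum(y4, 0.0, out=y4)
        if train:
            self._cache = (xm, a, y4, (b, r, w, pl))
        yout = self._scratch("yout", (b, self.c_out, r, w))
        np.copyto(yout, y4.transpose(0, 2, 1, 3))
        return yout

    def backward(self, g: np.ndarray):
        xm, a, y4, (b, r, w, pl) = self._cache
        gm4 = self._scratch("gm4", (b, r, self.c_out, w))
        np.copyto(gm4, g.transpose(0, 2, 1, 3))
        if self.alpha > 0:
            # post-activation sign matches pre-activation sign when alpha > 0
            gm4[y4 < 0] *= self.alpha
        else:
            gm4 *= y4 > 0  # ReLU gate
        self.dbias = gm4.sum(axis=(0, 1, 3))
        gm = gm4.reshape(b * r, self.c_out * w)
        da = self._scratch("da", (xm.shape[1], gm.shape[1]))
        np.matmul(xm.T, gm, out=da)
        self.dkern = _fold_toeplitz_grad(da, self.c_out, self.c_in, self.kw, w)
        dxm = self._scratch("dxm", (b * r, xm.shape[1]))
        np.matmul(gm, a.T, out=dxm)
        dxp = dxm.reshape(b, r, self.c_in, -1)
        dx = self._scratch("dx", (b, self.c_in, r, w))
        np.copyto(dx, dxp[:, :, :, pl : pl + w].transpose(0, 2, 1, 3))
        self._cache = None
        return dx

    @property
    def params(self):
        return [("kern", self.kern), ("bias", self.bias)]


class Network:
    """Built (and, after :func:`train`, fitted) model instance."""

    def __init__(self, spec: ModelSpec, input_shape: tuple[int, int]):
        self.spec = spec
        self.input_shape = tuple(input_shape)
        r, w = input_shape
        if r < 1 or w < 1:
            raise ConstructionError("input shape must be positive")
        rng = np.random.default_rng(spec.seed)
        self.conv1 = _ConvTime(
            1, spec.conv1_filters, spec.conv_kernel_weeks, rng, alpha=spec.conv_leaky_alpha
        )
        p1r, p1w = spec.pool1
        if r < p1r or w < p1w:
            raise ConstructionError(
                f"average_pooling2d: input {r}x{w} smaller than pool {p1r}x{p1w}"
            )
        r1, w1 = r // p1r, w // p1w
        self.conv2 = _ConvTime(
            spec.conv1_filters, spec.conv2_filters, spec.conv_kernel_weeks, rng,
            alpha=spec.conv_leaky_alpha,
        )
        p2r, p2w = spec.pool2
        if r1 < p2r or w1 < p2w:
            raise ConstructionError(
                f"max_pooling2d: input {r1}x{w1} smaller than pool {p2r}x{p2w}"
            )
        r2, w2 = r1 // p2r, w1 // p2w
        self.flat_dim = spec.conv2_filters * r2 * w2
        dense_in = self.flat_dim + 2  # + age, sex
        self.w_dense = _glorot(rng, (dense_in, spec.dense_units), dense_in, spec.dense_units)
        self.b_dense = np.zeros(spec.dense_units, dtype=np.float32)
        self.w_out = _glorot(rng, (spec.dense_units, 1), spec.dense_units, 1)
        self.b_out = np.zeros(1, dtype=np.float32)
        self.history: list[dict] = []
        self.trained = False
        self._pool_dims = (r1, w1, r2, w2)
        self._buf: dict[str, np.ndarray] = {}

    def _scratch(self, key: str, shape) -> np.ndarray:
        buf = self._buf.get(key)
        if buf is None or buf.shape != tuple(shape):
            buf = np.empty(shape, dtype=np.float32)
            self._buf[key] = buf
        return buf

    # ------------------------------------------------------------------ #
    @property
    def hidden_layers(self) -> tuple[str, ...]:
        return HIDDEN_LAYERS

    @property
    def n_hidden_layers(self) -> int:
        return len(HIDDEN_LAYERS)

    @property
    def dense_units(self) -> int:
        return self.spec.dense_units

    @property
    def dropout_rate(self) -> float:
        return self.spec.dropout_rate

    # ------------------------------------------------------------------ #
    def _forward(self, x: np.ndarray, aux: np.ndarray, train: bool, rng=None):
        spec = self.spec
        b = x.shape[0]
        h = self.conv1.forward(x[:, None, :, :].astype(np.float32), train)
        # average pooling
        p1r, p1w = spec.pool1
        r, w = h.shape[2], h.shape[3]
        r1, w1 = r // p1r, w // p1w
        hc = h[:, :, : r1 * p1r, : w1 * p1w]
        p1 = hc.reshape(b, h.shape[1], r1, p1r, w1, p1w).mean(axis=(3, 5))
        h2 = self.conv2.forward(p1.astype(np.float32), train)
        # max pooling
        p2r, p2w = spec.pool2
        r2, w2 = h2.shape[2] // p2r, h2.shape[3] // p2w
        h2c = h2[:, :, : r2 * p2r, : w2 * p2w]
        h2r = h2c.reshape(b, h2.shape[1], r2, p2r, w2, p2w)
        h2m = h2r.max(axis=(3, 5))
        flat = h2m.reshape(b, -1)
        z = np.concatenate([flat, aux.astype(np.float32)], axis=1)
        pre = z @ self.w_dense + self.b_dense
        alpha = spec.leaky_alpha
        act = np.where(pre > 0, pre, alpha * pre).astype(np.float32)
        if train and spec.dropout_rate > 0:
            keep = (rng.random(act.shape) >= spec.dropout_rate).astype(np.float32)
            drop_mask = keep / (1.0 - spec.dropout_rate)
        else:
            drop_mask = None
        d = act * drop_mask if drop_mask is not None else act
        logit = (d @ self.w_out + self.b_out)[:, 0]
        cache = None
        if train:
            # one-hot argmax mask for max-pool backward (first maximum wins)
            h2f = np.ascontiguousarray(h2r.transpose(0, 1, 2, 4, 3, 5)).reshape(
                b, h2.shape[1], r2, w2, p2r * p2w
            )
            am = h2f.argmax(axis=-1)
            mp_mask = np.zeros_like(h2f, dtype=np.float32)
            np.put_along_axis(mp_mask, am[..., None], 1.0, axis=-1)
            cache = (x.shape, p1, mp_mask, z, pre, act, drop_mask, d,
                     (r, w, r1, w1, r2, w2))
        return logit, cache

    def _backward(self, dlogit: np.ndarray, cache):
        spec = self.spec
        (xshape, p1, mp_mask, z, pre, act, drop_mask, d, dims) = cache
        r, w, r1, w1, r2, w2 = dims
        b = dlogit.shape[0]
        self.dw_out = d.T @ dlogit[:, None]
        self.db_out = dlogit.sum(keepdims=True)
        gd = dlogit[:, None] @ self.w_out.T
        if drop_mask is not None:
            gd = gd * drop_mask
        gd = gd * np.where(pre > 0, 1.0, spec.leaky_alpha)
        gd = gd.astype(np.float32)
        self.dw_dense = z.T @ gd
        self.db_dense = gd.sum(axis=0)
        gz = gd @ self.w_dense.T
        gflat = gz[:, : self.flat_dim]
        # max-pool backward
        c2 = spec.conv2_filters
        p2r, p2w = spec.pool2
        gm = gflat.reshape(b, c2, r2, w2)
        gh2f = mp_mask * gm[..., None]
        gh2 = gh2f.reshape(b, c2, r2, w2, p2r, p2w).transpose(0, 1, 2, 4, 3, 5)
        gh2 = gh2.reshape(b, c2, r2 * p2r, w2 * p2w)
        gh2_full = np.zeros((b, c2, r1, w1), dtype=np.float32)
        gh2_full[:, :, : r2 * p2r, : w2 * p2w] = gh2
        gp1 = self.conv2.backward(gh2_full)
        # average-pool backward
        c1 = spec.conv1_filters
        p1r, p1w = spec.pool1
        gh1 = self._scratch("gh1", (b, c1, r, w))
        gh1.fill(0.0)
        scaled = gp1 * (1.0 / (p1r * p1w))
        for i in range(p1r):
            for j in range(p1w):
                gh1[:, :, i : r1 * p1r : p1r, j : w1 * p1w : p1w] = scaled
        self.conv1.backward(gh1)

    # ------------------------------------------------------------------ #
    def _parameters(self):
        return [
            (self.conv1, "kern"), (self.conv1, "bias"),
            (self.conv2, "kern"), (self.conv2, "bias"),
            (self, "w_dense"), (self, "b_dense"),
            (self, "w_out"), (self, "b_out"),
        ]

    def _gradients(self):
        return [
            self.conv1.dkern, self.conv1.dbias,
            self.conv2.dkern, self.conv2.dbias,
            self.dw_dense, self.db_dense,
            self.dw_out, self.db_out.reshape(1),
        ]


def build_model(spec: ModelSpec, input_shape: tuple[int, int]) -> Network:
    """Construct the untrained network for maps of shape (n_rows, n_weeks)."""
    return Network(spec, input_shape)


def _coerce(maps, labels=None):
    if isinstance(maps, (list, tuple)) and maps and isinstance(maps[0], TemporalPhenomicMap):
        X, aux, y, _ = stack_maps(list(maps))
        if labels is None:
            labels = y
        return X, aux, np.asarray(labels)
    if isinstance(maps, tuple) and len(maps) == 2:
        X, aux = maps
        return np.asarray(X), np.asarray(aux), (None if labels is None else np.asarray(labels))
    raise InferenceError("maps must be a list of TemporalPhenomicMap or an (X, aux) tuple")


def train(net: Network, maps, labels=None, spec: ModelSpec | None = None) -> Network:
    """Fit the network in place; returns it with per-epoch history attached.

    ``maps`` is either a list of normalized TemporalPhenomicMaps (labels
    taken from the maps unless given) or an ``(X, aux)`` tuple with
    ``labels`` supplied.
    """
    spec = spec or net.spec
    X, aux, y = _coerce(maps, labels)
    y = np.asarray(y, dtype=np.float32)
    if X.shape[1:] != net.input_shape:
        raise InferenceError(f"map shape {X.shape[1:]} != model input {net.input_shape}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training data contains a single class")
    n = len(y)
    rng = np.random.default_rng(spec.seed + 1)
    if spec.class_weighted:
        w_pos = n / (2.0 * max(y.sum(), 1.0))
        w_neg = n / (2.0 * max((1 - y).sum(), 1.0))
        sample_w = np.where(y == 1, w_pos, w_neg).astype(np.float32)
    else:
        sample_w = np.ones(n, dtype=np.float32)

    adam_m = [np.zeros_like(g) for g in _param_arrays(net)]
    adam_v = [np.zeros_like(g) for g in _param_arrays(net)]
    t = 0
    b1, b2, eps = 0.9, 0.999, 1e-7
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        probs_epoch = np.empty(n, dtype=np.float32)
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, ab, yb, wb = X[idx], aux[idx], y[idx], sample_w[idx]
            logit, cache = net._forward(xb, ab, train=True, rng=rng)
            # binary cross-entropy with logits
            loss = np.logaddexp(0.0, logit) - yb * logit
            losses.append(float(np.average(loss, weights=wb)))
            prob = _sigmoid(logit)
            probs_epoch[idx] = prob
            dlogit = ((prob - yb) * wb / wb.sum()).astype(np.float32)
            net._backward(dlogit, cache)
            t += 1
            params = _param_arrays(net)
            grads = net._gradients()
            for p, g, m, v in zip(params, grads, adam_m, adam_v):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mh = m / (1 - b1**t)
                vh = v / (1 - b2**t)
                p -= spec.learning_rate * mh / (np.sqrt(vh) + eps)
        net.history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "train_auroc": _safe_auroc(y, probs_epoch),
            }
        )
    net.trained = True
    return net


def _param_arrays(net: Network):
    return [
        net.conv1.kern, net.conv1.bias, net.conv2.kern, net.conv2.bias,
        net.w_dense, net.b_dense, net.w_out, net.b_out,
    ]


def _safe_auroc(y, scores) -> float | None:
    from scipy.stats import rankdata

    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def predict(net: Network, maps, batch_size: int = 256) -> np.ndarray:
    """Per-sample risk probabilities in [0, 1]; deterministic (no dropout)."""
    X, aux, _ = _coerce(maps, None)
    if X.shape[1:] != net.input_shape:
        raise InferenceError(f"map shape {X.shape[1:]} != model input {net.input_shape}")
    out = np.empty(len(X), dtype=np.float64)
    for start in range(0, len(X), batch_size):
        xb = X[start : start + batch_size]
        ab = aux[start : start + batch_size]
        logit, _ = net._forward(xb, ab, train=False)
        out[start : start + len(xb)] = _sigmoid(logit)
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


TrainedModel = Network
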