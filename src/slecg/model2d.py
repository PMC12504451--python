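"""Compact 2-D CNN for binary segment classification.

The network is four blocks of (convolution -> ReLU -> max-pool ->
dropout) followed by flatten -> dropout -> dense(96, ReLU) ->
dense(1, sigmoid), trained with binary cross-entropy and Adam.  With the
default configuration on a 96x96x1 input the per-layer trainable
parameter counts are

    conv1 (3x3, 1->32)    320
    conv2 (3x1, 32->64)   6,208
    conv3 (3x1, 64->128)  24,704
    conv4 (3x1, 128->128) 49,280
    dense (3072->96)      295,008

summing to 375,520 (the output layer adds 97 more).  The pooling
schedule (2,2)x3 then (3,2) takes the 96x96 map down to 4x6, giving the
3072-feature flatten the dense count implies.

The whole network — im2col convolutions, pooling with argmax routing,
inverted dropout, Adam — is implemented directly on numpy arrays, with
all randomness drawn from a single seeded generator so training runs are
reproducible.  A sigmoid score near 1 means normal rhythm and near 0
means AFib, matching the label encoding norm=1 / afib=0 used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DTYPE = np.float32  # network compute precision

__all__ = [
    "ModelConfig", "LayerParamReport", "NetworkHandle",
    "build_model", "count_parameters", "train", "predict_segment",
    "save_model", "load_model",
]


@dataclass
class ModelConfig:
    input_shape: tuple[int, int, int] = (96, 96, 1)
    conv_filters: tuple[int, ...] = (32, 64, 128, 128)
    conv_kernels: tuple[tuple[int, int], ...] = ((3, 3), (3, 1), (3, 1), (3, 1))
    pool_sizes: tuple[tuple[int, int], ...] = ((2, 2), (2, 2), (2, 2), (3, 2))
    dense_units: int = 96
    dropout: tuple[float, ...] = (0.25, 0.25, 0.4, 0.5)
    flatten_dropout: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 15
    validation_split: float = 0.2
    early_stopping_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.conv_filters) != (32, 64, 128, 128):
            raise ValueError("conv_filters must be (32, 64, 128, 128)")
        if self.dense_units != 96:
            raise ValueError("dense_units must be 96")
        rates = (*self.dropout, self.flatten_dropout)
        if any(not 0.25 <= r <= 0.50 for r in rates):
            raise ValueError("dropout rates must lie in [0.25, 0.50]")
        if len(self.conv_kernels) != 4 or len(self.pool_sizes) != 4:
            raise ValueError("need 4 kernels and 4 pool sizes")
        if any(kh % 2 == 0 or kw % 2 == 0 for kh, kw in self.conv_kernels):
            raise ValueError("kernel dims must be odd for same padding")


@dataclass
class LayerParamReport:
    conv: tuple[int, int, int, int]
    dense: int
    output: int

    @property
    def core_total(self) -> int:
        """Sum over the four conv layers and the 96-unit dense layer."""
        return sum(self.conv) + self.dense

    @property
    def grand_total(self) -> int:
        return self.core_total + self.output


# ---------------------------------------------------------------------------
# layers

class Conv2D:
    """Same-padding, stride-1 convolution on NHWC tensors.

    Computed as a sum of shifted matmuls — one (pixels, cin) @ (cin, cout)
    product per kernel offset — which matches im2col FLOP-for-FLOP while
    avoiding its large gather copies.
    """

    def __init__(self, kh: int, kw: int, cin: int, cout: int,
                 rng: np.random.Generator):
        fan_in, fan_out = kh * kw * cin, kh * kw * cout
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.w = rng.uniform(-limit, limit,
                             size=(kh, kw, cin, cout)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.kh, self.kw = kh, kw

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        n, h, w, cin = x.shape
        cout = self.w.shape[-1]
        out = np.empty((n, h, w, cout), dtype=x.dtype)
        out[...] = self.b
        for i in range(self.kh):
            for j in range(self.kw):
                shift = xp[:, i:i + h, j:j + w, :].reshape(-1, cin)
                out += (shift @ self.w[i, j]).reshape(n, h, w, cout)
        if train:
            self._cache = (xp, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        n, h, w, cin = xshape
        cout = self.w.shape[-1]
        ph, pw = self.kh // 2, self.kw // 2
        dflat = dout.reshape(-1, cout)
        self.dw = np.empty_like(self.w)
        self.db = dflat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                shift = xp[:, i:i + h, j:j + w, :].reshape(-1, cin)
                self.dw[i, j] = shift.T @ dflat
                dxp[:, i:i + h, j:j + w, :] += (
                    dflat @ self.w[i, j].T).reshape(n, h, w, cin)
        return dxp[:, ph:ph + h, pw:pw + w, :]

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class ReLU:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class MaxPool2D:
    """Non-overlapping max pooling; trailing rows/cols are dropped."""

    n_params = 0

    def __init__(self, ph: int, pw: int):
        self.ph, self.pw = ph, pw

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return h // self.ph, w // self.pw

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = self.out_shape(h, w)
        if ho < 1 or wo < 1:
            raise ValueError(f"pool ({self.ph},{self.pw}) collapses {h}x{w} map")
        blocks = x[:, : ho * self.ph, : wo * self.pw, :].reshape(
            n, ho, self.ph, wo, self.pw, c)
        out = blocks.max(axis=(2, 4))
        if train:
            self._cache = (blocks, out, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        blocks, out, xshape = self._cache
        n, ho, wo, c = dout.shape
        # route gradient to the maxima; exact ties share it equally
        mask = (blocks == out[:, :, None, :, None, :])
        count = mask.sum(axis=(2, 4), keepdims=True)
        dblocks = mask * (dout[:, :, None, :, None, :] / count)
        dx = np.zeros(xshape, dtype=dout.dtype)
        dx[:, : ho * self.ph, : wo * self.pw, :] = dblocks.reshape(
            n, ho * self.ph, wo * self.pw, c)
        return dx

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity at inference time."""

    n_params = 0

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class Flatten:
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, fan_in: int, units: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (fan_in + units))  # Glorot uniform
        self.w = rng.uniform(-limit, limit,
                             size=(fan_in, units)).astype(DTYPE)
        self.b = np.zeros(units, dtype=DTYPE)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


# ---------------------------------------------------------------------------
# network

@dataclass
class NetworkHandle:
    config: ModelConfig
    layers: list = field(default_factory=list)
    flatten_size: int = 0
    history: dict = field(default_factory=lambda: {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []})
    trained: bool = False

    # layer indices of the four convs, the hidden dense and the output dense
    conv_ix: tuple[int, ...] = ()
    dense_ix: int = -1
    output_ix: int = -1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return _sigmoid(x[:, 0])

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_model(config: ModelConfig | None = None) -> NetworkHandle:
    """Construct the (untrained) network for the given configuration."""
    config = config or ModelConfig()
    rng = np.random.default_rng(config.seed)
    h, w, c = config.input_shape
    layers: list = []
    conv_ix: list[int] = []
    for (kh, kw), cout, (ph, pw), rate in zip(
            config.conv_kernels, config.conv_filters,
            config.pool_sizes, config.dropout):
        conv_ix.append(len(layers))
        layers.append(Conv2D(kh, kw, c, cout, rng))
        layers.append(ReLU())
        pool = MaxPool2D(ph, pw)
        h, w = pool.out_shape(h, w)
        if h < 1 or w < 1:
            raise ValueError(
                f"pooling schedule incompatible with input shape "
                f"{config.input_shape}: spatial map vanished")
        layers.append(pool)
        layers.append(Dropout(rate, rng))
        c = cout
    layers.append(Flatten())
    layers.append(Dropout(config.flatten_dropout, rng))
    flat = h * w * c
    dense_ix = len(layers)
    layers.append(Dense(flat, config.dense_units, rng))
    layers.append(ReLU())
    output_ix = len(layers)
    layers.append(Dense(config.dense_units, 1, rng))
    return NetworkHandle(config=config, layers=layers, flatten_size=flat,
                         conv_ix=tuple(conv_ix), dense_ix=dense_ix,
                         output_ix=output_ix)


def count_parameters(model: NetworkHandle) -> LayerParamReport:
    """Exact trainable-parameter counts per layer."""
    conv = tuple(model.layers[i].n_params for i in model.conv_ix)
    return LayerParamReport(
        conv=conv,  # type: ignore[arg-type]
        dense=model.layers[model.dense_ix].n_params,
        output=model.layers[model.output_ix].n_params,
    )


# ---------------------------------------------------------------------------
# training / inference

def _as_batch(images: np.ndarray, input_shape: tuple[int, int, int]) -> np.ndarray:
    x = np.asarray(images, dtype=DTYPE)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[1:] != tuple(input_shape):
        raise ValueError(
            f"image shape {x.shape[1:]} does not match model input "
            f"{tuple(input_shape)}")
    return x


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params  # list of (layer, name, gradname)
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n, _ in params]
        self.v = [np.zeros_like(getattr(l, n)) for l, n, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (layer, name, gname) in enumerate(self.params):
            g = getattr(layer, gname)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            getattr(layer, name)[...] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _collect_params(model: NetworkHandle):
    out = []
    for layer in model.layers:
        for name, _, gname in layer.params():
            out.append((layer, name, gname))
    return out


def _snapshot(model: NetworkHandle):
    return [getattr(l, n).copy() for l, n, _ in _collect_params(model)]


def _restore(model: NetworkHandle, snap) -> None:
    for (layer, name, _), arr in zip(_collect_params(model), snap):
        getattr(layer, name)[...] = arr


def train(model: NetworkHandle, images: np.ndarray, labels: np.ndarray,
          config: ModelConfig | None = None) -> NetworkHandle:
    """Train in place with Adam + binary cross-entropy; returns the model.

    ``labels`` are 1 for normal and 0 for AFib.  A validation split is
    held out for per-epoch monitoring and early stopping on validation
    loss (best weights restored).  With ``epochs=0`` the model is
    returned untouched with an empty history.
    """
    config = config or model.config
    y = np.asarray(labels, dtype=float)
    x = _as_batch(images, config.input_shape)
    if x.shape[0] != y.shape[0]:
        raise ValueError("images and labels disagree in length")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if config.epochs == 0:
        return model

    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(x.shape[0])
    n_val = max(1, int(round(config.validation_split * x.shape[0])))
    val_ix, train_ix = order[:n_val], order[n_val:]
    xt, yt = x[train_ix], y[train_ix]
    xv, yv = x[val_ix], y[val_ix]

    opt = _Adam(_collect_params(model), config.learning_rate)
    best_val, best_snap, since_best = np.inf, None, 0

    for _epoch in range(config.epochs):
        perm = rng.permutation(xt.shape[0])
        losses, accs = [], []
        for start in range(0, xt.shape[0], config.batch_size):
            bi = perm[start:start + config.batch_size]
            xb, yb = xt[bi], yt[bi]
            p = model.forward(xb, train=True)
            losses.append(_bce(p, yb))
            accs.append(float(np.mean((p >= 0.5) == (yb == 1.0))))
            model.backward(((p - yb) / yb.size).astype(DTYPE))
            opt.step()
        pv = model.forward(xv, train=False)
        vloss = _bce(pv, yv)
        model.history["loss"].append(float(np.mean(losses)))
        model.history["accuracy"].append(float(np.mean(accs)))
        model.history["val_loss"].append(vloss)
        model.history["val_accuracy"].append(
            float(np.mean((pv >= 0.5) == (yv == 1.0))))
        if vloss < best_val - 1e-6:
            best_val, best_snap, since_best = vloss, _snapshot(model), 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break
    if best_snap is not None:
        _restore(model, best_snap)
    model.trained = True
    return model


def predict_segment(model: NetworkHandle, images) -> np.ndarray | float:
    """Sigmoid score(s) in [0, 1]; near 1 = normal, near 0 = AFib.

    Accepts a single image (2-D array or :class:`~slecg.render.ImagePatch`)
    or a batch; dropout is disabled, so repeated calls are identical.
    """
    single = False
    if hasattr(images, "pixels"):
        images, single = images.pixels, True
    elif isinstance(images, np.ndarray) and images.ndim == 2:
        single = True
    elif isinstance(images, (list, tuple)):
        images = np.stack([im.pixels if hasattr(im, "pixels") else im
                           for im in images])
    x = _as_batch(images, model.config.input_shape)
    scores = model.forward(x, train=False)
    return float(scores[0]) if single else scores


# ---------------------------------------------------------------------------
# persistence

def save_model(model: NetworkHandle, path: str | Path) -> None:
    arrays = {f"p{i}": getattr(l, n)
              for i, (l, n, _) in enumerate(_collect_params(model))}
    cfg = {k: v for k, v in vars(model.config).items()}
    np.savez(Path(path), __config__=json.dumps(cfg), **arrays)


def load_model(path: str | Path) -> NetworkHandle:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        for key in ("input_shape",):
            cfg[key] = tuple(cfg[key])
        for key in ("conv_filters", "dropout", "dense_units"):
            if isinstance(cfg.get(key), list):
                cfg[key] = tuple(cfg[key])
        cfg["conv_kernels"] = tuple(tuple(k) for k in cfg["conv_kernels"])
        cfg["pool_sizes"] = tuple(tuple(p) for p in cfg["pool_sizes"])
        model = build_model(ModelConfig(**cfg))
        _restore(model, [data[f"p{i}"]
                         for i in range(len(_collect_params(model)))])
    model.trained = True
    return model
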