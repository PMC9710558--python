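"""A compact NumPy residual convolutional network with manual backprop.

Implements the two standard residual arrangements used by the
classifiers: the 50-layer network of bottleneck blocks (3-4-6-3) and the
18-layer variant of basic blocks (2-2-2-2). Residual blocks add the
block input to its output through an identity (or 1×1-projection)
shortcut, which makes identity mappings trivial to learn and deep
networks trainable. A ``base_width`` parameter scales all channel widths
uniformly (64 reproduces the standard widths; small widths make CPU
training of desk-scale fixtures fast).

Everything is float32; convolutions are im2col + matmul; training is
Adam with cross-entropy loss and a step learning-rate decay. After the
last epoch the batch-norm running statistics are re-estimated with a
calibration pass over the training data (a short run sees too few
batches for the exponential moving averages to converge).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["ResNet", "build_resnet", "train_network", "save_network", "load_network"]


# ---------------------------------------------------------------------------
# im2col helpers

def _out_size(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    ho, wo = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo)


def col2im(
    cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int, pad: int
) -> np.ndarray:
    n, c, h, w = x_shape
    ho, wo = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


# ---------------------------------------------------------------------------
# layers

class Conv2d:
    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None):
        scale = np.sqrt(2.0 / (cin * k * k))  # He init
        self.w = (rng.standard_normal((cout, cin, k, k)) * scale).astype(np.float32)
        self.dw = np.zeros_like(self.w)
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train):
        cols = im2col(x, self.k, self.k, self.stride, self.pad)
        wm = self.w.reshape(self.w.shape[0], -1)
        out = np.matmul(wm, cols)  # (N, cout, L)
        n = x.shape[0]
        ho = _out_size(x.shape[2], self.k, self.stride, self.pad)
        wo = _out_size(x.shape[3], self.k, self.stride, self.pad)
        if train:
            self._cache = (x.shape, cols)
        return out.reshape(n, -1, ho, wo)

    def backward(self, dout):
        x_shape, cols = self._cache
        n = dout.shape[0]
        dflat = dout.reshape(n, dout.shape[1], -1)
        self.dw += np.einsum("nol,nkl->ok", dflat, cols).reshape(self.w.shape)
        wm = self.w.reshape(self.w.shape[0], -1)
        dcols = np.matmul(wm.T, dflat)
        self._cache = None
        return col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)

    def params(self):
        return [(self.w, self.dw)]


class BatchNorm2d:
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._cache = None
        return dx.astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class MaxPool2d:
    def __init__(self, k=3, stride=2, pad=1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train):
        n, c, h, w = x.shape
        cols = im2col(x.reshape(n * c, 1, h, w), self.k, self.k, self.stride, self.pad)
        # padded entries are zero; activations can be zero too, so pad with -inf
        if self.pad:
            mask_cols = im2col(
                np.ones((1, 1, h, w), dtype=np.float32), self.k, self.k, self.stride, self.pad
            )
            cols = np.where(mask_cols > 0, cols, np.float32(-np.inf))
        arg = cols.argmax(axis=1)
        out = np.take_along_axis(cols, arg[:, None, :], axis=1)[:, 0, :]
        ho = _out_size(h, self.k, self.stride, self.pad)
        wo = _out_size(w, self.k, self.stride, self.pad)
        if train:
            self._cache = (x.shape, arg, cols.shape)
        return out.reshape(n, c, ho, wo)

    def backward(self, dout):
        x_shape, arg, cols_shape = self._cache
        n, c, h, w = x_shape
        dcols = np.zeros(cols_shape, dtype=np.float32)
        dflat = dout.reshape(n * c, 1, -1)
        np.put_along_axis(dcols, arg[:, None, :], dflat, axis=1)
        dx = col2im(dcols, (n * c, 1, h, w), self.k, self.k, self.stride, self.pad)
        self._cache = None
        return dx.reshape(x_shape)

    def params(self):
        return []


class GlobalAvgPool:
    def __init__(self):
        self._hw = None

    def forward(self, x, train):
        if train:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        h, w = self._hw
        return np.broadcast_to(dout[:, :, None, None] / (h * w), dout.shape + (h, w)).astype(
            np.float32
        )

    def params(self):
        return []


class Linear:
    def __init__(self, cin, cout, rng):
        scale = np.sqrt(2.0 / cin)
        self.w = (rng.standard_normal((cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw += self._x.T @ dout
        self.db += dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class _Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class _ResBlock:
    """Residual block: main branch + identity/projection shortcut, then ReLU."""

    def __init__(self, main_layers, shortcut_layers):
        self.main = _Sequential(main_layers)
        self.shortcut = _Sequential(shortcut_layers) if shortcut_layers else None
        self.relu = ReLU()

    def forward(self, x, train):
        out = self.main.forward(x, train)
        sc = self.shortcut.forward(x, train) if self.shortcut else x
        return self.relu.forward(out + sc, train)

    def backward(self, dout):
        dout = self.relu.backward(dout)
        dx = self.main.backward(dout)
        if self.shortcut:
            dx = dx + self.shortcut.backward(dout)
        else:
            dx = dx + dout
        return dx

    def params(self):
        out = self.main.params() + self.relu.params()
        if self.shortcut:
            out += self.shortcut.params()
        return out


def _basic_block(cin, cout, stride, rng):
    main = [
        Conv2d(cin, cout, 3, stride, 1, rng),
        BatchNorm2d(cout),
        ReLU(),
        Conv2d(cout, cout, 3, 1, 1, rng),
        BatchNorm2d(cout),
    ]
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = [Conv2d(cin, cout, 1, stride, 0, rng), BatchNorm2d(cout)]
    return _ResBlock(main, shortcut)


def _bottleneck_block(cin, mid, stride, rng):
    cout = mid * 4
    main = [
        Conv2d(cin, mid, 1, 1, 0, rng),
        BatchNorm2d(mid),
        ReLU(),
        Conv2d(mid, mid, 3, stride, 1, rng),
        BatchNorm2d(mid),
        ReLU(),
        Conv2d(mid, cout, 1, 1, 0, rng),
        BatchNorm2d(cout),
    ]
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = [Conv2d(cin, cout, 1, stride, 0, rng), BatchNorm2d(cout)]
    return _ResBlock(main, shortcut)


_ARRANGEMENTS = {18: ("basic", (2, 2, 2, 2)), 50: ("bottleneck", (3, 4, 6, 3))}


class ResNet:
    """Residual network with a softmax head; see :func:`build_resnet`."""

    def __init__(self, depth, in_channels, n_classes, base_width, input_size, seed=0):
        if depth not in _ARRANGEMENTS:
            raise ValueError(f"unsupported depth {depth}; choose from {sorted(_ARRANGEMENTS)}")
        self.depth = depth
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.base_width = base_width
        self.input_size = input_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        kind, counts = _ARRANGEMENTS[depth]
        w = base_width
        layers = [
            Conv2d(in_channels, w, 7, 2, 3, rng),
            BatchNorm2d(w),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ]
        cin = w
        for stage, n_blocks in enumerate(counts):
            cw = w * (2**stage)
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                if kind == "basic":
                    layers.append(_basic_block(cin, cw, stride, rng))
                    cin = cw
                else:
                    layers.append(_bottleneck_block(cin, cw, stride, rng))
                    cin = cw * 4
        layers.append(GlobalAvgPool())
        self.head = Linear(cin, n_classes, rng)
        self.body = _Sequential(layers)

    # -- inference ---------------------------------------------------------
    def logits(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        feats = self.body.forward(x, train)
        return self.head.forward(feats, train)

    def predict_proba(self, x, batch_size=64):
        x = np.asarray(x, dtype=np.float32)
        if len(x) == 0:
            return np.zeros((0, self.n_classes), dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(_softmax(self.logits(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    # -- training ----------------------------------------------------------
    def params(self):
        return self.body.params() + self.head.params()

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0

    def train_step(self, x, y, lr, opt_state, weight_decay=1e-4):
        """One Adam step on a minibatch; returns (loss, batch accuracy)."""
        self.zero_grad()
        logits = self.logits(x, train=True)
        probs = _softmax(logits)
        n = len(x)
        loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dfeats = self.head.backward(dlogits.astype(np.float32))
        self.body.backward(dfeats)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        opt_state["t"] += 1
        t = opt_state["t"]
        for i, (p, g) in enumerate(self.params()):
            g = g + weight_decay * p
            m1, m2 = opt_state["m"][i], opt_state["v"][i]
            m1 *= beta1
            m1 += (1 - beta1) * g
            m2 *= beta2
            m2 += (1 - beta2) * g * g
            mhat = m1 / (1 - beta1**t)
            vhat = m2 / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        acc = float((probs.argmax(axis=1) == y).mean())
        return float(loss), acc

    def spec_dict(self):
        return {
            "depth": self.depth,
            "in_channels": self.in_channels,
            "n_classes": self.n_classes,
            "base_width": self.base_width,
            "input_size": self.input_size,
            "seed": self.seed,
        }


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_resnet(depth, in_channels, n_classes, base_width=64, input_size=64, seed=0) -> ResNet:
    return ResNet(depth, in_channels, n_classes, base_width, input_size, seed)


def _augment(x, rng, intensity_jitter=True):
    """Random flips, 90° rotations and optional mild intensity scaling."""
    x = x.copy()
    n = len(x)
    flips_h = rng.random(n) < 0.5
    flips_v = rng.random(n) < 0.5
    rots = rng.integers(0, 4, n)
    if intensity_jitter:
        scales = rng.uniform(0.85, 1.15, n).astype(np.float32)
    else:
        scales = np.ones(n, dtype=np.float32)
    for i in range(n):
        xi = x[i]
        if flips_h[i]:
            xi = xi[:, :, ::-1]
        if flips_v[i]:
            xi = xi[:, ::-1, :]
        if rots[i]:
            xi = np.rot90(xi, k=int(rots[i]), axes=(1, 2))
        x[i] = xi * scales[i]
    return x


def train_network(
    model: ResNet,
    x: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int = 20,
    batch_size: int = 64,
    lr: float = 1e-3,
    weight_decay: float = 1e-4,
    augment: bool = True,
    intensity_jitter: bool = True,
    seed: int = 0,
    val_frac: float = 0.1,
) -> list[dict]:
    """Adam training loop; returns a per-epoch log of loss and accuracy.

    The learning rate steps down 10× at two-thirds of the epochs. A
    stratified ``val_frac`` split is held out for the logged validation
    accuracy (skipped when any class is too small to split).
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("empty training set")
    if x.ndim == 3:
        x = x[:, None]
    rng = np.random.default_rng(seed)
    # stratified split
    val_idx: list[int] = []
    if val_frac > 0:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            n_val = int(len(idx) * val_frac)
            if n_val >= 1:
                val_idx.extend(rng.permutation(idx)[:n_val].tolist())
    val_idx_arr = np.array(sorted(val_idx), dtype=int)
    train_mask = np.ones(len(y), dtype=bool)
    train_mask[val_idx_arr] = False
    xt, yt = x[train_mask], y[train_mask]
    xv, yv = x[val_idx_arr], y[val_idx_arr]
    opt_state = {
        "t": 0,
        "m": [np.zeros_like(p) for p, _ in model.params()],
        "v": [np.zeros_like(p) for p, _ in model.params()],
    }
    step_epoch = max(1, (2 * epochs) // 3)
    log = []
    for epoch in range(epochs):
        cur_lr = lr * (0.1 if epoch >= step_epoch else 1.0)
        order = rng.permutation(len(xt))
        losses, accs = [], []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            xb = xt[idx]
            if augment:
                xb = _augment(xb, rng, intensity_jitter)
            loss, acc = model.train_step(xb, yt[idx], cur_lr, opt_state, weight_decay)
            losses.append(loss)
            accs.append(acc)
        entry = {
            "epoch": epoch,
            "lr": cur_lr,
            "loss": float(np.mean(losses)),
            "train_accuracy": float(np.mean(accs)),
        }
        if len(xv):
            pv = model.predict_proba(xv, batch_size=batch_size)
            entry["val_accuracy"] = float((pv.argmax(axis=1) == yv).mean())
        log.append(entry)
    _calibrate_batchnorm(model, xt, batch_size)
    if len(xv):
        pv = model.predict_proba(xv, batch_size=batch_size)
        log[-1]["val_accuracy"] = float((pv.argmax(axis=1) == yv).mean())
    return log


def _calibrate_batchnorm(model: ResNet, x: np.ndarray, batch_size: int) -> None:
    """Replace BN running stats by cumulative averages over the data."""
    bns = [l for l in _iter_layers(model) if isinstance(l, BatchNorm2d)]
    if not bns or len(x) == 0:
        return
    saved = [(bn.momentum) for bn in bns]
    for bn in bns:
        bn.running_mean[...] = 0
        bn.running_var[...] = 0
    for bi, i in enumerate(range(0, len(x), batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (bi + 1)
        model.logits(x[i : i + batch_size], train=True)
    for bn, m in zip(bns, saved):
        bn.momentum = m
        bn._cache = None


# ---------------------------------------------------------------------------
# persistence: weights as .npz + JSON sidecar

def _state_arrays(model: ResNet) -> dict[str, np.ndarray]:
    arrays = {}
    i = 0
    for p, _ in model.params():
        arrays[f"p{i}"] = p
        i += 1
    # batch-norm running stats are state but not parameters
    j = 0
    for layer in _iter_layers(model):
        if isinstance(layer, BatchNorm2d):
            arrays[f"rm{j}"] = layer.running_mean
            arrays[f"rv{j}"] = layer.running_var
            j += 1
    return arrays


def _iter_layers(model: ResNet):
    def walk(obj):
        if isinstance(obj, _Sequential):
            for sub in obj.layers:
                yield from walk(sub)
        elif isinstance(obj, _ResBlock):
            yield from walk(obj.main)
            if obj.shortcut:
                yield from walk(obj.shortcut)
            yield obj.relu
        else:
            yield obj

    yield from walk(model.body)
    yield model.head


def save_network(model: ResNet, directory: str | Path, extra_meta: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **_state_arrays(model))
    meta = model.spec_dict()
    if extra_meta:
        meta.update(extra_meta)
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_network(directory: str | Path) -> tuple[ResNet, dict]:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    model = ResNet(
        meta["depth"],
        meta["in_channels"],
        meta["n_classes"],
        meta["base_width"],
        meta["input_size"],
        meta.get("seed", 0),
    )
    with np.load(directory / "weights.npz") as data:
        i = 0
        for p, _ in model.params():
            p[...] = data[f"p{i}"]
            i += 1
        j = 0
        for layer in _iter_layers(model):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = data[f"rm{j}"]
                layer.running_var[...] = data[f"rv{j}"]
                j += 1
    return model, meta
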