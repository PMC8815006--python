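"""A small NumPy neural-network engine: layers, backprop, and Adam.

Implements exactly the pieces the wood-identification models need — 3×3/7×7
convolutions (im2col forward, kernel-slice backward), batch normalisation
(2-D and 1-D), ReLU, 2×2 max pooling, residual blocks, global average+max
pooling with concatenation, dropout, linear layers, softmax cross-entropy,
and an Adam optimiser whose learning rate and first-moment coefficient
(momentum) can be rescheduled every step. Everything is float64-free
(float32 throughout) and deterministic given the generators passed in.

Layers expose ``forward(x, training, rng)`` / ``backward(dout)`` and keep
their parameters in ``params`` with matching gradients in ``grads`` after a
backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Sequential", "Conv2d", "BatchNorm2d", "BatchNorm1d", "ReLU",
    "MaxPool2d", "GlobalAvgMaxConcat", "Dropout", "Linear", "BasicBlock",
    "BottleneckBlock", "softmax", "softmax_cross_entropy", "Adam",
]


class Layer:
    """Base layer: parameter/gradient registries plus optional buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def named_parameters(self, prefix=""):
        for k in self.params:
            yield f"{prefix}{k}", self, k

    def named_buffers(self, prefix=""):
        for k in self.buffers:
            yield f"{prefix}{k}", self, k

    def sublayers(self):
        return ()


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_parameters(self, prefix=""):
        for i, layer in enumerate(self.layers):
            yield from layer.named_parameters(f"{prefix}{i}.")

    def named_buffers(self, prefix=""):
        for i, layer in enumerate(self.layers):
            yield from layer.named_buffers(f"{prefix}{i}.")

    def sublayers(self):
        return tuple(self.layers)


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution, NCHW layout, zero 'same'-style padding, no bias.

    Bias is omitted because every convolution here is followed by batch
    normalisation.
    """

    def __init__(self, in_ch, out_ch, ksize=3, stride=1, pad=None, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        self.stride = int(stride)
        self.k = int(ksize)
        self.pad = self.k // 2 if pad is None else int(pad)
        fan_in = in_ch * self.k * self.k
        self.params["W"] = he_normal(rng, (out_ch, in_ch, self.k, self.k), fan_in)

    def forward(self, x, training=False, rng=None):
        W = self.params["W"]
        s, k, p = self.stride, self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        from numpy.lib.stride_tricks import sliding_window_view

        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # win: (N, C, Ho, Wo, k, k)
        out = np.tensordot(win, W, axes=([1, 4, 5], [1, 2, 3]))
        out = np.transpose(out, (0, 3, 1, 2))
        self._cache = (xp, win, x.shape)
        return np.ascontiguousarray(out.astype(np.float32))

    def backward(self, dout):
        xp, win, xshape = self._cache
        W = self.params["W"]
        s, k, p = self.stride, self.k, self.pad
        N, O, Ho, Wo = dout.shape
        # dW: correlate input windows with the output gradient
        dW = np.tensordot(dout, win, axes=([0, 2, 3], [0, 2, 3]))
        self.grads["W"] = dW.astype(np.float32)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                # (N,O,Ho,Wo) x (O,C) -> (N,Ho,Wo,C)
                contrib = np.tensordot(dout, W[:, :, i, j], axes=([1], [0]))
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += np.transpose(
                    contrib, (0, 3, 1, 2)
                )
        _, _, H, Wd = xshape
        return np.ascontiguousarray(dxp[:, :, p : p + H, p : p + Wd])


class _BatchNorm(Layer):
    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(num_features, dtype=np.float32)
        self.params["beta"] = np.zeros(num_features, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(num_features, dtype=np.float32)
        self.buffers["running_var"] = np.ones(num_features, dtype=np.float32)

    _axes: tuple[int, ...] = (0,)

    def _reshape(self, v):
        return v

    def forward(self, x, training=False, rng=None):
        if training:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            m = self.momentum
            self.buffers["running_mean"] *= 1 - m
            self.buffers["running_mean"] += m * mean.astype(np.float32)
            self.buffers["running_var"] *= 1 - m
            self.buffers["running_var"] += m * var.astype(np.float32)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._reshape(mean)) * self._reshape(invstd)
        out = self._reshape(self.params["gamma"]) * xhat + self._reshape(
            self.params["beta"]
        )
        self._cache = (xhat, invstd, x.shape, training)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, invstd, xshape, training = self._cache
        g = self._reshape(self.params["gamma"])
        self.grads["gamma"] = np.sum(dout * xhat, axis=self._axes).astype(np.float32)
        self.grads["beta"] = np.sum(dout, axis=self._axes).astype(np.float32)
        if not training:
            return (dout * g * self._reshape(invstd)).astype(np.float32)
        m = np.prod([xshape[a] for a in self._axes])
        dxhat = dout * g
        dx = (
            dxhat
            - self._reshape(dxhat.mean(axis=self._axes))
            - xhat * self._reshape((dxhat * xhat).mean(axis=self._axes))
        ) * self._reshape(invstd)
        return dx.astype(np.float32)


class BatchNorm2d(_BatchNorm):
    _axes = (0, 2, 3)

    def _reshape(self, v):
        return v[None, :, None, None]


class BatchNorm1d(_BatchNorm):
    _axes = (0,)

    def _reshape(self, v):
        return v[None, :]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return (dout * self._mask).astype(np.float32)


class MaxPool2d(Layer):
    """2×2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, training=False, rng=None):
        N, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[:, :, : 2 * Ho, : 2 * Wo]
        xr = xc.reshape(N, C, Ho, 2, Wo, 2)
        out = xr.max(axis=(3, 5))
        self._cache = (xr, out, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        xr, out, xshape = self._cache
        mask = xr == out[:, :, :, None, :, None]
        # normalise so tied maxima split the gradient
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dx_r = mask * (dout[:, :, :, None, :, None] / counts)
        N, C, H, W = xshape
        dx = np.zeros(xshape, dtype=np.float32)
        Ho, Wo = H // 2, W // 2
        dx[:, :, : 2 * Ho, : 2 * Wo] = dx_r.reshape(N, C, 2 * Ho, 2 * Wo)
        return dx


class GlobalAvgMaxConcat(Layer):
    """Concatenate global average and max pooling: (N,C,H,W) → (N, 2C)."""

    def forward(self, x, training=False, rng=None):
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        self._cache = (x, mx)
        return np.concatenate([avg, mx], axis=1).astype(np.float32)

    def backward(self, dout):
        x, mx = self._cache
        N, C, H, W = x.shape
        davg, dmax = dout[:, :C], dout[:, C:]
        dx = np.broadcast_to(
            davg[:, :, None, None] / (H * W), x.shape
        ).astype(np.float32).copy()
        mask = x == mx[:, :, None, None]
        counts = mask.sum(axis=(2, 3), keepdims=True)
        dx += mask * (dmax[:, :, None, None] / counts)
        return dx


class Dropout(Layer):
    """Inverted dropout; requires an rng during training."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must lie in [0, 1)")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout needs an rng in training mode")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(np.float32)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        self.params["W"] = he_normal(rng, (out_features, in_features), in_features)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (dout.T @ self._x).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return (dout @ self.params["W"]).astype(np.float32)


class BasicBlock(Layer):
    """ResNet basic block: two 3×3 convs with identity (or 1×1) shortcut."""

    def __init__(self, in_ch, out_ch, stride=1, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng),
                BatchNorm2d(out_ch),
            )
        else:
            self.shortcut = None

    def forward(self, x, training=False, rng=None):
        out = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, training), training),
            training,
        )
        out = self.bn2.forward(self.conv2.forward(out, training), training)
        short = x if self.shortcut is None else self.shortcut.forward(x, training)
        return self.relu2.forward(out + short, training)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        dshort = d if self.shortcut is None else self.shortcut.backward(d)
        return dmain + dshort

    def sublayers(self):
        subs = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.shortcut is not None:
            subs.append(self.shortcut)
        return tuple(subs)

    def named_parameters(self, prefix=""):
        for name, layer in (
            ("conv1", self.conv1), ("bn1", self.bn1),
            ("conv2", self.conv2), ("bn2", self.bn2),
        ):
            yield from layer.named_parameters(f"{prefix}{name}.")
        if self.shortcut is not None:
            yield from self.shortcut.named_parameters(f"{prefix}shortcut.")

    def named_buffers(self, prefix=""):
        for name, layer in (("bn1", self.bn1), ("bn2", self.bn2)):
            yield from layer.named_buffers(f"{prefix}{name}.")
        if self.shortcut is not None:
            yield from self.shortcut.named_buffers(f"{prefix}shortcut.")


class BottleneckBlock(Layer):
    """ResNet bottleneck block (1×1 → 3×3 → 1×1, expansion 4)."""

    expansion = 4

    def __init__(self, in_ch, width, stride=1, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        out_ch = width * self.expansion
        self.body = _BottleneckBody(in_ch, width, out_ch, stride, rng)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng),
                BatchNorm2d(out_ch),
            )
        else:
            self.shortcut = None
        self.relu = ReLU()

    def forward(self, x, training=False, rng=None):
        out = self.body.forward(x, training=training, rng=rng)
        short = x if self.shortcut is None else self.shortcut.forward(x, training)
        return self.relu.forward(out + short, training)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dmain = self.body.backward(d)
        dshort = d if self.shortcut is None else self.shortcut.backward(d)
        return dmain + dshort

    def sublayers(self):
        subs = [self.body]
        if self.shortcut is not None:
            subs.append(self.shortcut)
        return tuple(subs)

    def named_parameters(self, prefix=""):
        yield from self.body.named_parameters(f"{prefix}body.")
        if self.shortcut is not None:
            yield from self.shortcut.named_parameters(f"{prefix}shortcut.")

    def named_buffers(self, prefix=""):
        yield from self.body.named_buffers(f"{prefix}body.")
        if self.shortcut is not None:
            yield from self.shortcut.named_buffers(f"{prefix}shortcut.")


def _BottleneckBody(in_ch, width, out_ch, stride, rng):
    return Sequential(
        Conv2d(in_ch, width, 1, pad=0, rng=rng), BatchNorm2d(width), ReLU(),
        Conv2d(width, width, 3, stride=stride, rng=rng), BatchNorm2d(width), ReLU(),
        Conv2d(width, out_ch, 1, pad=0, rng=rng), BatchNorm2d(out_ch),
    )


# ---------------------------------------------------------------------------
# Loss and optimiser


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``targets`` are integer class indices.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    loss = float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    """Adam over (layer, key) parameter references with per-step schedules.

    ``groups`` is a list of dicts ``{"params": [(layer, key), ...],
    "lr_scale": float}``; ``step`` takes the schedule's current learning
    rate and first-moment coefficient (the "momentum" being annealed).
    """

    def __init__(self, groups, beta2=0.99, eps=1e-6):
        self.groups = groups
        self.beta2 = beta2
        self.eps = eps
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    @classmethod
    def for_params(cls, param_refs, **kw):
        return cls([{"params": list(param_refs), "lr_scale": 1.0}], **kw)

    def step(self, lr: float, beta1: float) -> None:
        self.t += 1
        b2 = self.beta2
        for group in self.groups:
            glr = lr * group.get("lr_scale", 1.0)
            for layer, key in group["params"]:
                g = layer.grads.get(key)
                if g is None:
                    continue
                sid = id(layer.params[key])
                if sid not in self.state:
                    self.state[sid] = (
                        np.zeros_like(layer.params[key]),
                        np.zeros_like(layer.params[key]),
                    )
                m, v = self.state[sid]
                m *= beta1
                m += (1 - beta1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - beta1**self.t)
                vhat = v / (1 - b2**self.t)
                layer.params[key] -= (glr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    np.float32
                )
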