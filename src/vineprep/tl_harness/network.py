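"""A compact feed-forward CNN with exact backpropagation, in numpy.

Layer kinds mirror the declarative specs: convolution (im2col over NHWC
arrays), ReLU, cross-channel local response normalization, overlapping
max-pooling, fully connected, dropout, and a softmax head trained with
cross-entropy.  Every trainable layer carries a learning-rate multiplier so
transfer schemes can freeze layers exactly (a multiplier of zero skips the
update entirely, leaving weights bit-identical).

The optimizer is stochastic gradient descent with classical momentum and L2
weight decay, matching a training setup of base learning rate 1e-5, momentum
0.9 and weight decay 1e-1 at full scale (desk-scale runs pass their own
hyperparameters).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from vineprep.errors import NetworkStructureError
from vineprep.tl_harness.layers import LayerSpec, propagate_dims

__all__ = ["Network", "build_backbone"]


class _Layer:
    """Base layer: stateless unless it declares parameters."""

    name = ""
    lr_mult = 1.0

    def params(self) -> list[str]:
        return []

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Conv(_Layer):
    def __init__(self, name: str, spec: LayerSpec, c_in: int,
                 rng: np.random.Generator):
        self.name = name
        self.k = spec.kernel
        self.s = spec.stride
        self.p = spec.padding or 0
        fan_in = self.k * self.k * c_in
        self.W = (rng.standard_normal((spec.depth, c_in, self.k, self.k))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(spec.depth, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return ["W", "b"]

    def forward(self, x, train, rng):
        k, s, p = self.k, self.s, self.p
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp_shape = x.shape
        win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (N, Ho, Wo, C, k, k)
        n, ho, wo = win.shape[:3]
        cols = win.reshape(n, ho, wo, -1)
        self._cols = cols
        wmat = self.W.reshape(self.W.shape[0], -1)
        return cols @ wmat.T + self.b

    def backward(self, grad):
        n, ho, wo, cout = grad.shape
        wmat = self.W.reshape(cout, -1)
        gm = grad.reshape(-1, cout)
        self.dW = (gm.T @ self._cols.reshape(-1, wmat.shape[1])).reshape(
            self.W.shape)
        self.db = gm.sum(axis=0)
        dcols = (gm @ wmat).reshape(n, ho, wo, *self.W.shape[1:])
        # scatter back (col2im)
        dxp = np.zeros(self._xp_shape, dtype=grad.dtype)
        k, s, p = self.k, self.s, self.p
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + s * ho : s, kj : kj + s * wo : s, :] += (
                    dcols[:, :, :, :, ki, kj]
                )
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return dxp


class _ReLU(_Layer):
    def __init__(self, name):
        self.name = name

    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return grad * self._mask


class _CrossNorm(_Layer):
    """Local response normalization across channels.

    b_i = a_i / (k + alpha/n * sum_{j in window(i)} a_j^2) ** beta, with the
    window of ``n`` channels centered on i (clipped at the borders).
    """

    def __init__(self, name, n=5, k=2.0, alpha=1e-4, beta=0.75):
        self.name = name
        self.n, self.k, self.alpha, self.beta = n, k, alpha, beta

    def _window_sum(self, z):
        c = z.shape[-1]
        half = self.n // 2
        pad = np.pad(z, [(0, 0)] * (z.ndim - 1) + [(half, half)])
        csum = np.cumsum(pad, axis=-1)
        csum = np.concatenate(
            [np.zeros_like(csum[..., :1]), csum], axis=-1)
        return csum[..., self.n :] - csum[..., :c]

    def forward(self, x, train, rng):
        self._x = x
        self._denom = (self.k + (self.alpha / self.n)
                       * self._window_sum(x * x))
        self._out = x * self._denom ** (-self.beta)
        return self._out

    def backward(self, grad):
        # d a_i = g_i * denom_i^-beta
        #         - (2 alpha beta / n) a_i * sum_{j: i in win(j)} g_j b_j / denom_j
        t = grad * self._out / self._denom
        return (grad * self._denom ** (-self.beta)
                - (2 * self.alpha * self.beta / self.n) * self._x
                * self._window_sum(t))


class _MaxPool(_Layer):
    def __init__(self, name, spec: LayerSpec):
        self.name = name
        self.k = spec.kernel
        self.s = spec.stride

    def forward(self, x, train, rng):
        k, s = self.k, self.s
        self._x_shape = x.shape
        win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        self._win = win
        out = win.max(axis=(-2, -1))
        self._out = out
        return out

    def backward(self, grad):
        k, s = self.k, self.s
        n, ho, wo, c = grad.shape
        dx = np.zeros(self._x_shape, dtype=grad.dtype)
        for ki in range(k):
            for kj in range(k):
                sel = self._win[:, :, :, :, ki, kj] == self._out
                dx[:, ki : ki + s * ho : s, kj : kj + s * wo : s, :] += (
                    grad * sel
                )
        return dx


class _FC(_Layer):
    def __init__(self, name, spec: LayerSpec, n_in: int,
                 rng: np.random.Generator):
        self.name = name
        self.W = (rng.standard_normal((n_in, spec.depth))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(spec.depth, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return ["W", "b"]

    def forward(self, x, train, rng):
        self._in_shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        self._flat = flat
        return flat @ self.W + self.b

    def backward(self, grad):
        self.dW = self._flat.T @ grad
        self.db = grad.sum(axis=0)
        return (grad @ self.W.T).reshape(self._in_shape)


class _Dropout(_Layer):
    def __init__(self, name, p):
        self.name = name
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Network:
    """Sequential CNN built from layer specs; softmax cross-entropy head."""

    def __init__(self, layers: list[_Layer], specs: list[LayerSpec],
                 seed: int):
        self.layers = layers
        self.specs = specs
        self.rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)

    # -- forward / loss ---------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train, self.rng)
        return out.reshape(out.shape[0], -1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.logits(x, train=False)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        return self.logits(x, train=False).argmax(axis=1)

    def activations(self, x: np.ndarray, layer_name: str) -> np.ndarray:
        """Activation vectors at the named layer (e.g. the fc6 analogue)."""
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, False, self.rng)
            if layer.name == layer_name:
                return out.reshape(out.shape[0], -1)
        raise KeyError(f"no layer named {layer_name!r}")

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       train: bool = True) -> tuple[float, float]:
        """Cross-entropy loss and accuracy; fills per-layer gradients."""
        z = self.logits(x, train=train)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        n = len(y)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        acc = float((probs.argmax(axis=1) == y).mean())
        if train:
            grad = probs.copy()
            grad[np.arange(n), y] -= 1.0
            grad /= n
            out = grad
            for layer in reversed(self.layers):
                out = layer.backward(out)
        return loss, acc

    # -- parameters -------------------------------------------------------
    def trainable_layers(self) -> list[_Layer]:
        return [l for l in self.layers if l.params()]

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.trainable_layers():
            for p in layer.params():
                out[f"{layer.name}.{p}"] = getattr(layer, p).copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for layer in self.trainable_layers():
            for p in layer.params():
                key = f"{layer.name}.{p}"
                cur = getattr(layer, p)
                if weights[key].shape != cur.shape:
                    raise ValueError(
                        f"weight {key}: shape {weights[key].shape} does not "
                        f"match {cur.shape}"
                    )
                setattr(layer, p, weights[key].astype(cur.dtype).copy())

    def set_lr_mult(self, layer_names: list[str], mult: float) -> None:
        for layer in self.layers:
            if layer.name in layer_names:
                layer.lr_mult = mult

    def conv_layer_names(self) -> list[str]:
        return [l.name for l in self.layers if isinstance(l, _Conv)]


def build_backbone(
    specs: list[LayerSpec],
    n_classes: int,
    seed: int,
    pretrained: dict[str, np.ndarray] | str | None = None,
) -> Network:
    """Instantiate a network from a layer table, head sized to ``n_classes``.

    The final fc / softmax / classification rows are resized to ``n_classes``
    (replacing the classification part of a pretrained table).  Weights are
    randomly initialized under ``seed``; ``pretrained`` optionally supplies a
    mapping (or ``.npz`` path) of weights to load, whose shapes must match.
    """
    if specs[-1].kind != "classification" or specs[-2].kind != "softmax":
        raise NetworkStructureError(
            "layer table must end with softmax + classification rows")
    # resize the head
    import dataclasses

    specs = list(specs)
    for i in range(len(specs) - 1, -1, -1):
        if specs[i].kind == "fc":
            old = specs[i]
            specs[i] = dataclasses.replace(
                old, depth=n_classes,
                out_dims=(1, 1, n_classes) if old.out_dims else None)
            break
        if specs[i].out_dims is not None:
            specs[i] = dataclasses.replace(specs[i],
                                           out_dims=(1, 1, n_classes))
    input_dims = specs[0].out_dims
    if input_dims is None:
        raise NetworkStructureError("input row must declare its dimensions")
    dims = propagate_dims(specs, input_dims)

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    layers: list[_Layer] = []
    prev = input_dims
    for spec, d in zip(specs, dims):
        if spec.kind == "conv":
            layers.append(_Conv(spec.name, spec, prev[2], rng))
        elif spec.kind == "relu":
            layers.append(_ReLU(spec.name))
        elif spec.kind == "crossnorm":
            layers.append(_CrossNorm(spec.name))
        elif spec.kind == "maxpool":
            layers.append(_MaxPool(spec.name, spec))
        elif spec.kind == "fc":
            layers.append(_FC(spec.name, spec, prev[0] * prev[1] * prev[2],
                              rng))
        elif spec.kind == "dropout":
            layers.append(_Dropout(spec.name, spec.dropout_p or 0.5))
        # input / softmax / classification rows carry no computation here
        prev = d
    net = Network(layers, specs, seed)
    if pretrained is not None:
        if isinstance(pretrained, str):
            with np.load(pretrained) as data:
                pretrained = {k: data[k] for k in data.files}
        net.set_weights(pretrained)
    return net
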