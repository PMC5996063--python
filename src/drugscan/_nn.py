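"""Minimal feed-forward network engine (1-D convolution, pooling, dropout, dense).

A small, self-contained reverse-mode implementation in numpy, sized for the
binary-fingerprint regression networks in :mod:`drugscan.models`: layers keep
their parameters and Adam moments as plain arrays, forward passes cache what
backward needs, and all randomness (init, dropout masks, shuffling) flows
from a single ``numpy.random.Generator``.

Layout convention: convolutional layers operate on (batch, channels, length);
``Flatten`` moves to (batch, features) for dense layers.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError, DivergenceError

#: all parameters and activations are kept in single precision: the inputs
#: are binary and the regression targets span a few ln units, so float32
#: halves memory traffic at no practical cost in accuracy
DTYPE = np.float32


class Layer:
    """Base layer; parameter-free by default."""

    params: list  # list of [array, grad, m, v] slots

    def __init__(self):
        self.params = []

    def forward(self, x, train: bool, rng):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


def _init_dense(rng, fan_in, fan_out):
    scale = np.sqrt(2.0 / fan_in)
    w = rng.normal(0.0, scale, size=(fan_in, fan_out))
    return w.astype(DTYPE)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str = "linear", *, rng):
        super().__init__()
        self.activation = activation
        w = _init_dense(rng, n_in, n_out)
        b = np.zeros(n_out, dtype=DTYPE)
        self.params = [[w, np.zeros_like(w), np.zeros_like(w), np.zeros_like(w)],
                       [b, np.zeros_like(b), np.zeros_like(b), np.zeros_like(b)]]

    def forward(self, x, train, rng):
        self._x = x
        z = x @ self.params[0][0] + self.params[1][0]
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        if self.activation == "tanh":
            self._a = np.tanh(z)
            return self._a
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        elif self.activation == "tanh":
            grad = grad * (1.0 - self._a ** 2)
        self.params[0][1] += self._x.T @ grad
        self.params[1][1] += grad.sum(axis=0)
        return grad @ self.params[0][0].T


class Conv1D(Layer):
    """Valid cross-correlation along the last axis with stride, ReLU built in."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1, *, rng,
                 input_layer: bool = False):
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        # an input layer does not propagate gradients to its (data) input
        self.input_layer = input_layer
        w = _init_dense(rng, c_in * kernel, c_out)  # (c_in*k, c_out)
        b = np.zeros(c_out, dtype=DTYPE)
        self.params = [[w, np.zeros_like(w), np.zeros_like(w), np.zeros_like(w)],
                       [b, np.zeros_like(b), np.zeros_like(b), np.zeros_like(b)]]

    def out_length(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def forward(self, x, train, rng):
        # x: (N, C, L) -> windows (N, L_out, C*k)
        n, c, length = x.shape
        lo = self.out_length(length)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :][:, :, :lo, :]        # (N, C, L_out, k)
        cols = win.transpose(0, 2, 1, 3).reshape(n, lo, c * self.kernel)
        self._cols, self._in_shape = cols, x.shape
        z = cols @ self.params[0][0] + self.params[1][0]        # (N, L_out, c_out)
        self._z = z
        return np.maximum(z, 0.0).transpose(0, 2, 1)            # (N, c_out, L_out)

    def backward(self, grad):
        grad = grad.transpose(0, 2, 1) * (self._z > 0)          # (N, L_out, c_out)
        n, lo, _ = grad.shape
        w = self.params[0][0]
        d = self.c_in * self.kernel
        self.params[0][1] += self._cols.reshape(n * lo, d).T @ grad.reshape(n * lo, self.c_out)
        self.params[1][1] += grad.sum(axis=(0, 1))
        if self.input_layer:
            return None
        gcols = (grad @ w.T).reshape(n, lo, self.c_in, self.kernel)
        gx = np.zeros(self._in_shape, dtype=DTYPE)
        for j in range(self.kernel):
            # windows at fixed kernel offset j touch disjoint, strided positions
            gx[:, :, j: j + lo * self.stride: self.stride] += gcols[:, :, :, j].transpose(0, 2, 1)
        return gx


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder positions are dropped."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, train, rng):
        n, c, length = x.shape
        lo = length // self.pool
        xt = x[:, :, : lo * self.pool].reshape(n, c, lo, self.pool)
        self._arg = xt.argmax(axis=3)
        self._in_shape, self._lo = x.shape, lo
        return xt.max(axis=3)

    def backward(self, grad):
        n, c, length = self._in_shape
        gx = np.zeros((n, c, self._lo, self.pool), dtype=DTYPE)
        np.put_along_axis(gx, self._arg[..., None], grad[..., None], axis=3)
        out = np.zeros(self._in_shape, dtype=DTYPE)
        out[:, :, : self._lo * self.pool] = gx.reshape(n, c, self._lo * self.pool)
        return out


class Dropout(Layer):
    """Inverted dropout; identity at inference.

    Masks are per element.  In full-batch reference mode (``share_mask``
    set by the training loop) the mask is drawn per feature and shared
    across the batch, which makes full-batch training invariant to
    instance order.
    """

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ConfigurationError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.share_mask = False

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        shape = ((1,) + x.shape[1:]) if self.share_mask else x.shape
        self._mask = (rng.random(shape, dtype=DTYPE) >= self.rate).astype(DTYPE) / DTYPE(1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def all_params(self):
        return [p for layer in self.layers for p in getattr(layer, "params", [])]

    def forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class TwoBranchNet:
    """Two convolutional branches whose flattened outputs are concatenated
    ("virtual docking") and passed through a shared head.

    ``split`` is the boundary between the genomic block and the drug block in
    the concatenated input vector.
    """

    def __init__(self, genomic_branch: Sequential, drug_branch: Sequential,
                 head: Sequential, split: int):
        self.genomic_branch = genomic_branch
        self.drug_branch = drug_branch
        self.head = head
        self.split = split

    @property
    def all_params(self):
        return (self.genomic_branch.all_params + self.drug_branch.all_params
                + self.head.all_params)

    def forward(self, x, train, rng):
        xg = x[:, None, : self.split]
        xd = x[:, None, self.split:]
        hg = self.genomic_branch.forward(xg, train, rng)
        hd = self.drug_branch.forward(xd, train, rng)
        self._ng = hg.shape[1]
        h = np.concatenate([hg, hd], axis=1)
        return self.head.forward(h, train, rng)

    def backward(self, grad):
        gh = self.head.backward(grad)
        self.genomic_branch.backward(gh[:, : self._ng])
        self.drug_branch.backward(gh[:, self._ng:])


class SingleBranchNet:
    """The whole concatenated input convolved as one entity."""

    def __init__(self, body: Sequential):
        self.body = body

    @property
    def all_params(self):
        return self.body.all_params

    def forward(self, x, train, rng):
        return self.body.forward(x[:, None, :], train, rng)

    def backward(self, grad):
        self.body.backward(grad)


class Adam:
    """Adam with the standard published defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.lr = params, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for slot in self.params:
            w, g, m, v = slot
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            g[...] = 0.0

    def zero_grad(self):
        for slot in self.params:
            slot[1][...] = 0.0


def fit_network(net, X, y, *, epochs: int, batch_size, lr: float, rng,
                X_val=None, y_val=None, decay: float = 0.3):
    """Minibatch MSE training loop; returns per-epoch (train_mse, val_mse).

    ``batch_size=None`` trains full-batch, which makes the gradient (hence
    the fit) invariant to instance order.  The learning rate drops to
    ``decay * lr`` for the final third of the epochs, which settles Adam
    into a finer minimum.  Raises :class:`DivergenceError` on a non-finite
    loss.
    """
    n = X.shape[0]
    if batch_size is None:
        for layer in iter_layers(net):
            if isinstance(layer, Dropout):
                layer.share_mask = True
    opt = Adam(net.all_params, lr=lr)
    log = {"train_mse": [], "val_mse": []}
    for epoch in range(epochs):
        opt.lr = lr * decay if epochs >= 3 and epoch >= (2 * epochs) // 3 else lr
        order = np.arange(n) if batch_size is None else rng.permutation(n)
        bs = n if batch_size is None else batch_size
        sse = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = X[idx], y[idx]
            pred = net.forward(xb, True, rng).ravel()
            resid = pred.astype(np.float64) - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            sse += float(np.sum(resid ** 2))
            net.backward(((2.0 * resid / len(idx))[:, None]).astype(DTYPE))
            opt.step()
        log["train_mse"].append(sse / n)
        if X_val is not None:
            vp = predict_network(net, X_val)
            log["val_mse"].append(float(np.mean((vp - y_val) ** 2)))
    return log


def iter_layers(net):
    """All layers of a branch or single-stack network, in forward order."""
    if isinstance(net, TwoBranchNet):
        stacks = [net.genomic_branch, net.drug_branch, net.head]
    elif isinstance(net, SingleBranchNet):
        stacks = [net.body]
    else:
        stacks = [net]
    for stack in stacks:
        yield from stack.layers


def predict_network(net, X, batch_size: int = 512):
    out = [net.forward(X[i:i + batch_size], False, None).ravel()
           for i in range(0, X.shape[0], batch_size)]
    return np.concatenate(out) if out else np.zeros(0)
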