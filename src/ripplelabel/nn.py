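"""Neural-network building blocks on the :mod:`ripplelabel.autodiff` engine.

Layers follow the conventional (batch, channels, length) layout for 1-D
signals.  Every layer draws its initial weights from a caller-supplied
:class:`numpy.random.Generator`, so a model built twice from the same seed
has bit-identical parameters; training on a single thread is then fully
deterministic.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "MaxPool1d",
    "Dropout",
    "ReLU",
    "Flatten",
    "Sequential",
    "GRU",
    "Adam",
    "softmax",
    "log_softmax",
    "softmax_cross_entropy",
]


class Module:
    """Base class: parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Tensor) and value.requires_grad:
                    params.append(value)
        return params

    def train(self, mode: bool = True):
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, mod in enumerate(self.modules()):
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor):
                    state[f"{i}.{type(mod).__name__}.{name}"] = value.data.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, mod in enumerate(self.modules()):
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor):
                    value.data = state[f"{i}.{type(mod).__name__}.{name}"].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padded 1-D convolution over channels-last (N, L, C) input.

    Computed as a sum of K shifted GEMMs, which keeps every memory access
    contiguous; the weight is stored per kernel tap as (K, C_in, C_out).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        fan_in = in_channels * kernel_size
        bound = math.sqrt(2.0 / fan_in)  # He init for the ReLU blocks
        self.weight = Tensor(
            rng.normal(0.0, bound, size=(kernel_size, in_channels, out_channels)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        n, length, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k = self.kernel_size
        pad_l = (k - 1) // 2
        xp = np.pad(x.data, ((0, 0), (pad_l, k - 1 - pad_l), (0, 0)))
        w, b = self.weight, self.bias
        if c * k <= 64:
            # few input features: one im2col GEMM beats k small ones
            windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
            # (N, L, C, K) -> (N*L, K*C) matching the (K, C, O) weight layout
            cols = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(
                n * length, k * c
            )
            w2 = w.data.reshape(k * c, -1)
            out = (cols @ w2 + b.data).reshape(n, length, -1)

            def backward(g):
                g2 = g.reshape(n * length, -1)
                gb = g2.sum(axis=0)
                gw = (cols.T @ g2).reshape(w.data.shape)
                gcols = (g2 @ w2.T).reshape(n, length, k, c)
                gxp = np.zeros_like(xp)
                for j in range(k):
                    gxp[:, j : j + length, :] += gcols[:, :, j, :]
                return gxp[:, pad_l : pad_l + length, :], gw, gb

            return Tensor._from_op(out, (x, w, b), backward)

        out = np.empty((n, length, self.out_channels), dtype=np.float32)
        out[:] = b.data
        for j in range(k):
            out += xp[:, j : j + length, :] @ w.data[j]

        def backward(g):
            g2 = g.reshape(n * length, -1)
            gb = g2.sum(axis=0)
            gw = np.empty_like(w.data)
            gxp = np.zeros_like(xp)
            for j in range(k):
                gw[j] = xp[:, j : j + length, :].reshape(n * length, c).T @ g2
                gxp[:, j : j + length, :] += g @ w.data[j].T
            return gxp[:, pad_l : pad_l + length, :], gw, gb

        return Tensor._from_op(out, (x, w, b), backward)


class MaxPool1d(Module):
    """Non-overlapping max pooling over the time axis of (N, L, C) input.

    The pool width must be a power of two and divide the length; the max
    and its gradient routing are computed by a tournament of pairwise
    comparisons, which avoids the slow short-axis reductions of a generic
    argmax (ties route the gradient to the earlier sample).
    """

    def __init__(self, size: int):
        super().__init__()
        if size < 2 or size & (size - 1):
            raise ValueError("pool size must be a power of two >= 2")
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        n, length, c = x.shape
        s = self.size
        if length % s:
            raise ValueError(f"length {length} not divisible by pool {s}")
        cur = x.data
        masks = []
        for _ in range(int(math.log2(s))):
            pair = cur.reshape(n, cur.shape[1] // 2, 2, c)
            left, right = pair[:, :, 0, :], pair[:, :, 1, :]
            masks.append(left >= right)
            cur = np.maximum(left, right)

        def backward(g):
            gcur = g
            for mask in reversed(masks):
                half = mask.shape[1]
                gleft = gcur * mask
                pair = np.empty((n, half, 2, c), dtype=np.float32)
                pair[:, :, 0, :] = gleft
                pair[:, :, 1, :] = gcur - gleft
                gcur = pair.reshape(n, half * 2, c)
            return (gcur,)

        return Tensor._from_op(cur, (x,), backward)


class BatchNorm1d(Module):
    """Batch normalisation over (N, L, C) or (N, C) activations."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) if x.ndim == 2 else (0, 1)
        shape = (1, -1) if x.ndim == 2 else (1, 1, -1)
        count = x.data.shape[0] if x.ndim == 2 else x.data.shape[0] * x.data.shape[1]
        gamma, beta = self.gamma, self.beta
        if self.training:
            mean = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.ravel()
        else:
            mean = self.running_mean.reshape(shape)
            var = self.running_var.reshape(shape)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean) * inv_std
        out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
        training = self.training

        def backward(g):
            gbeta = g.sum(axis=axes)
            ggamma = (g * xhat).sum(axis=axes)
            gxhat = g * gamma.data.reshape(shape)
            if training:
                gx = (
                    inv_std
                    / count
                    * (
                        count * gxhat
                        - gxhat.sum(axis=axes, keepdims=True)
                        - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True)
                    )
                )
            else:
                gx = gxhat * inv_std
            return gx, ggamma, gbeta

        return Tensor._from_op(out, (x, gamma, beta), backward)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = np.float32(1.0 - self.p)
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep) * (
            np.float32(1.0) / keep
        )
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class GRU(Module):
    """Single-layer gated recurrent unit over (N, T, D) sequences.

    The input projections of all three gates are batched into one GEMM over
    the whole sequence; only the recurrent products run per timestep.
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_dim = hidden_dim

        def mat(rows, cols):
            bound = math.sqrt(6.0 / (rows + cols))
            return Tensor(rng.uniform(-bound, bound, (rows, cols)), requires_grad=True)

        # gate order along columns: update (z), reset (r), candidate
        self.w_in = mat(input_dim, 3 * hidden_dim)
        self.b_in = Tensor(np.zeros(3 * hidden_dim), requires_grad=True)
        self.u_zr = mat(hidden_dim, 2 * hidden_dim)
        self.u_cand = mat(hidden_dim, hidden_dim)

    def forward(self, x: Tensor, return_sequence: bool = False):
        n, t, d = x.shape
        hd = self.hidden_dim
        h = Tensor(np.zeros((n, hd), dtype=np.float32))
        xw = (x.reshape(n * t, d) @ self.w_in + self.b_in).reshape(n, t, 3 * hd)
        states = []
        for step in range(t):
            xt = xw[:, step, :]
            hu = h @ self.u_zr
            z = (xt[:, :hd] + hu[:, :hd]).sigmoid()
            r = (xt[:, hd : 2 * hd] + hu[:, hd:]).sigmoid()
            cand = (xt[:, 2 * hd :] + (r * h) @ self.u_cand).tanh()
            h = z * h + (1.0 - z) * cand
            if return_sequence:
                states.append(h)
        return states if return_sequence else h


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shift = logits - Tensor(logits.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(logits, axis=axis).exp()


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``targets`` under ``logits``."""
    n = logits.shape[0]
    lsm = log_softmax(logits, axis=-1)
    return -lsm[np.arange(n), np.asarray(targets)].mean()


class Adam:
    """Adam optimiser with the standard bias-corrected moments."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)
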