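"""Minimal reverse-mode autodiff engine and CNN layers on NumPy.

Everything the network needs — strided convolution (im2col + BLAS matmul),
batch normalisation, max pooling, squeeze-and-excitation gating, linear
layers, softmax and base-2 cross-entropy — with exact analytic backward
passes, validated against finite differences in the test suite.  Tensors wrap
``numpy.ndarray``; the default parameter dtype is float32 for throughput, and
float64 is supported for gradient checking.

This is deliberately small: single device, no graph optimisation, no
broadcasting beyond what the layers here use.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Tensor",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "SqueezeExcite",
    "BasicBlock",
    "Adam",
    "concat",
    "softmax",
    "nll_base2",
]

LOG2E = 1.0 / np.log(2.0)


# ---------------------------------------------------------------------------
# JIT kernels for the memory-bound inner loops (im2col/col2im, max pooling).
# Zero padding is implicit: out-of-bounds taps are skipped.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _im2col(x, k, s, p, oh, ow, cols):
    n, c, h, w = x.shape
    for b in range(n):
        row = b * oh * ow
        for y in range(oh):
            for xx in range(ow):
                col = 0
                for ch in range(c):
                    for i in range(k):
                        yy = y * s + i - p
                        for j in range(k):
                            xj = xx * s + j - p
                            if 0 <= yy < h and 0 <= xj < w:
                                cols[row, col] = x[b, ch, yy, xj]
                            else:
                                cols[row, col] = 0.0
                            col += 1
                row += 1


@njit(cache=True)
def _col2im(dcols, k, s, p, oh, ow, dx):
    n, c, h, w = dx.shape
    for b in range(n):
        row = b * oh * ow
        for y in range(oh):
            for xx in range(ow):
                col = 0
                for ch in range(c):
                    for i in range(k):
                        yy = y * s + i - p
                        for j in range(k):
                            xj = xx * s + j - p
                            if 0 <= yy < h and 0 <= xj < w:
                                dx[b, ch, yy, xj] += dcols[row, col]
                            col += 1
                row += 1


@njit(cache=True)
def _bn_fwd(x, mean, inv_std, gamma, beta, xhat, y):
    n, c, h, w = x.shape
    for b in range(n):
        for ch in range(c):
            mu = mean[ch]
            istd = inv_std[ch]
            g = gamma[ch]
            bb = beta[ch]
            for i in range(h):
                for j in range(w):
                    v = (x[b, ch, i, j] - mu) * istd
                    xhat[b, ch, i, j] = v
                    y[b, ch, i, j] = g * v + bb


@njit(cache=True)
def _bn_bwd(g, xhat, gamma, inv_std, use_batch_stats, dx, dgamma, dbeta):
    n, c, h, w = g.shape
    cnt = n * h * w
    for ch in range(c):
        sum_g = 0.0
        sum_gx = 0.0
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    gv = g[b, ch, i, j]
                    sum_g += gv
                    sum_gx += gv * xhat[b, ch, i, j]
        dgamma[ch] += sum_gx
        dbeta[ch] += sum_g
        ga = gamma[ch]
        istd = inv_std[ch]
        if use_batch_stats:
            mg = ga * sum_g / cnt
            mgx = ga * sum_gx / cnt
            for b in range(n):
                for i in range(h):
                    for j in range(w):
                        dx[b, ch, i, j] = istd * (
                            ga * g[b, ch, i, j] - mg - xhat[b, ch, i, j] * mgx
                        )
        else:
            for b in range(n):
                for i in range(h):
                    for j in range(w):
                        dx[b, ch, i, j] = ga * g[b, ch, i, j] * istd


@njit(cache=True)
def _maxpool_fwd(x, k, s, p, oh, ow, out, idx):
    n, c, h, w = x.shape
    for b in range(n):
        for ch in range(c):
            for y in range(oh):
                for xx in range(ow):
                    best = -np.inf
                    best_i = 0
                    for i in range(k):
                        yy = y * s + i - p
                        if yy < 0 or yy >= h:
                            continue
                        for j in range(k):
                            xj = xx * s + j - p
                            if xj < 0 or xj >= w:
                                continue
                            v = x[b, ch, yy, xj]
                            if v > best:
                                best = v
                                best_i = i * k + j
                    out[b, ch, y, xx] = best
                    idx[b, ch, y, xx] = best_i


@njit(cache=True)
def _maxpool_bwd(g, idx, k, s, p, dx):
    n, c, oh, ow = g.shape
    for b in range(n):
        for ch in range(c):
            for y in range(oh):
                for xx in range(ow):
                    flat = idx[b, ch, y, xx]
                    yy = y * s + flat // k - p
                    xj = xx * s + flat % k - p
                    dx[b, ch, yy, xj] += g[b, ch, y, xx]


# ---------------------------------------------------------------------------
# Tensor and autodiff core
# ---------------------------------------------------------------------------


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic used by layers ------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out = _result(np.add(self.data, other.data), self, other)
        if out._parents:

            def bwd(g):
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(g, other.data.shape))

            out._backward = bwd
        return out

    def __mul__(self, other: "Tensor") -> "Tensor":
        out = _result(np.multiply(self.data, other.data), self, other)
        if out._parents:

            def bwd(g):
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))

            out._backward = bwd
        return out


def _tracked(t: Tensor) -> bool:
    return t.requires_grad or bool(t._parents)


def _result(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    tracked = tuple(p for p in parents if _tracked(p))
    out._parents = tracked
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    out = _result(np.maximum(x.data, 0), x)
    if out._parents:
        mask = x.data > 0

        def bwd(g):
            x._accumulate(g * mask)

        out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _result(s, x)
    if out._parents:

        def bwd(g):
            x._accumulate(g * s * (1.0 - s))

        out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _result(np.concatenate([t.data for t in tensors], axis=axis), *tensors)
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if _tracked(t):
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = bwd
    return out


def matmul(x: Tensor, w: Tensor) -> Tensor:
    out = _result(x.data @ w.data, x, w)
    if out._parents:

        def bwd(g):
            if _tracked(x):
                x._accumulate(g @ w.data.T)
            if _tracked(w):
                w._accumulate(x.data.T @ g)

        out._backward = bwd
    return out


def softmax(x: Tensor) -> Tensor:
    """Row-wise softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    out = _result(p, x)
    if out._parents:

        def bwd(g):
            dot = (g * p).sum(axis=-1, keepdims=True)
            x._accumulate(p * (g - dot))

        out._backward = bwd
    return out


def nll_base2(
    probs: Tensor, labels: np.ndarray, reduction: str = "mean", eps: float = 1e-7
) -> Tensor:
    """Negative log2-likelihood of the true class.

    ``probs`` is an (N, n_classes) probability matrix; probabilities are
    clamped to [eps, 1] before the log so degenerate outputs stay finite.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
    labels = np.asarray(labels)
    n = probs.data.shape[0]
    idx = np.arange(n)
    p_true = probs.data[idx, labels]
    clamped = np.clip(p_true, eps, 1.0)
    loss = -np.log2(clamped)
    value = loss.sum() if reduction == "sum" else loss.mean()
    out = _result(np.asarray(value, dtype=probs.data.dtype), probs)
    if out._parents:
        scale = 1.0 if reduction == "sum" else 1.0 / n
        active = (p_true >= eps) & (p_true <= 1.0)  # flat outside the clamp

        def bwd(g):
            dp = np.zeros_like(probs.data)
            dp[idx, labels] = np.where(active, -LOG2E / clamped * scale, 0.0) * g
            probs._accumulate(dp)

        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery, train/eval mode, named state."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        """All parameters and buffers, keyed by attribute path."""
        state: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v.named_state(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.named_state(f"{key}.{i}."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in list(self.__dict__.items()):
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = state[key].copy()
            elif isinstance(v, np.ndarray):
                self.__dict__[name] = state[key].copy()
            elif isinstance(v, Module):
                v.load_state(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, f"{key}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Conv2d(Module):
    """2-D convolution via im2col; NCHW layout, He-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = False,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)).astype(dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x.data.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        if k == 1 and p == 0:
            # pointwise: plain matmul over channels, no column matrix
            cols = np.ascontiguousarray(
                x.data[:, :, ::s, ::s].transpose(0, 2, 3, 1)
            ).reshape(n * oh * ow, c)
        else:
            cols = np.empty((n * oh * ow, c * k * k), dtype=x.data.dtype)
            _im2col(x.data, k, s, p, oh, ow, cols)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out2d = cols @ wmat.T
        if self.bias is not None:
            out2d += self.bias.data
        out = _result(
            out2d.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2),
            x,
            self.weight,
            *( [self.bias] if self.bias is not None else [] ),
        )
        if out._parents:

            def bwd(g):
                g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
                    n * oh * ow, self.out_channels
                )
                self.weight._accumulate((g2d.T @ cols).reshape(self.weight.data.shape))
                if self.bias is not None:
                    self.bias._accumulate(g2d.sum(axis=0))
                if _tracked(x):
                    dcols = g2d @ wmat
                    dx = np.zeros((n, c, h, w), dtype=x.data.dtype)
                    if k == 1 and p == 0:
                        dx[:, :, ::s, ::s] = dcols.reshape(n, oh, ow, c).transpose(
                            0, 3, 1, 2
                        )
                    else:
                        _col2im(dcols, k, s, p, oh, ow, dx)
                    x._accumulate(dx)

            out._backward = bwd
        return out


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mean = self.running_mean
            var = self.running_var
        dtype = x.data.dtype
        mean = np.ascontiguousarray(mean, dtype=dtype)
        inv_std = np.ascontiguousarray(1.0 / np.sqrt(var + self.eps), dtype=dtype)
        xhat = np.empty_like(x.data)
        y = np.empty_like(x.data)
        _bn_fwd(x.data, mean, inv_std, self.weight.data, self.bias.data, xhat, y)
        out = _result(y, x, self.weight, self.bias)
        if out._parents:
            use_batch_stats = self.training
            gamma = self.weight.data.copy()  # pre-update value for backward

            def bwd(g):
                dx = np.empty_like(xhat)
                dgamma = np.zeros_like(gamma)
                dbeta = np.zeros_like(gamma)
                _bn_bwd(
                    np.ascontiguousarray(g),
                    xhat,
                    gamma,
                    inv_std,
                    use_batch_stats,
                    dx,
                    dgamma,
                    dbeta,
                )
                self.weight._accumulate(dgamma)
                self.bias._accumulate(dbeta)
                if _tracked(x):
                    x._accumulate(dx)

            out._backward = bwd
        return out


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, h, w = x.data.shape
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        pooled = np.empty((n, c, oh, ow), dtype=x.data.dtype)
        idx = np.empty((n, c, oh, ow), dtype=np.int8)
        _maxpool_fwd(x.data, k, s, p, oh, ow, pooled, idx)
        out = _result(pooled, x)
        if out._parents:

            def bwd(g):
                dx = np.zeros((n, c, h, w), dtype=x.data.dtype)
                _maxpool_bwd(np.ascontiguousarray(g), idx, k, s, p, dx)
                x._accumulate(dx)

            out._backward = bwd
        return out


class GlobalAvgPool2d(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        out = _result(x.data.mean(axis=(2, 3)), x)
        if out._parents:

            def bwd(g):
                x._accumulate(
                    np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).astype(
                        x.data.dtype
                    )
                )

            out._backward = bwd
        return out


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, std, (in_features, out_features)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        return out + self.bias


class SqueezeExcite(Module):
    """Squeeze-and-excitation channel attention: GAP -> FC -> ReLU -> FC -> sigmoid gate."""

    def __init__(self, channels: int, reduction: int, *, rng, dtype=np.float32):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.pool = GlobalAvgPool2d()
        self.fc1 = Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        s = sigmoid(self.fc2(relu(self.fc1(self.pool(x)))))
        gate = _result(s.data[:, :, None, None], s)
        if gate._parents:

            def bwd(g):
                s._accumulate(g.sum(axis=(2, 3)))

            gate._backward = bwd
        return x * gate


class BasicBlock(Module):
    """Two 3x3 convolutions with identity (or 1x1 projected) shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride: int, *, rng, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride, 1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_channels, dtype=dtype)
        self.conv2 = Conv2d(out_channels, out_channels, 3, 1, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_channels, dtype=dtype)
        if stride != 1 or in_channels != out_channels:
            self.short_conv = Conv2d(in_channels, out_channels, 1, stride, 0, rng=rng, dtype=dtype)
            self.short_bn = BatchNorm2d(out_channels, dtype=dtype)
        else:
            self.short_conv = None
            self.short_bn = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(relu(self.bn1(self.conv1(x)))))
        shortcut = x if self.short_conv is None else self.short_bn(self.short_conv(x))
        return relu(y + shortcut)


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
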