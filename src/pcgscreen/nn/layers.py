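"""Layers with explicit forward/backward passes.

Tensors are NCHW ``numpy`` arrays.  Each layer caches what its backward pass
needs during ``forward`` and releases it after ``backward``.  Stochastic layers
(dropout) draw from the generator carried by the :class:`Context`, so a fixed
seed reproduces a training run bit-for-bit on fixed hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Context:
    """Per-forward-pass state.

    ``training`` activates batch statistics and dropout; ``mc_dropout`` keeps
    dropout active at inference (batch norm stays in eval mode), which is what
    turns repeated forward passes into Monte-Carlo samples from the
    approximate posterior predictive.
    """

    training: bool = False
    mc_dropout: bool = False
    rng: np.random.Generator | None = None


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base class: parameter/child registration and traversal."""

    def __init__(self) -> None:
        self._params: dict[str, Param] = {}
        self._children: dict[str, Module] = {}

    def register(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def add_param(self, name: str, value: np.ndarray) -> Param:
        p = Param(value)
        self._params[name] = p
        return p

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Param]]:
        out = [(f"{prefix}{n}", p) for n, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix=f"{prefix}{cname}."))
        return out

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for child in self._children.values():
            out.extend(child.modules())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.value.copy() for n, p in self.named_parameters()}
        for name, mod in self._named_buffers():
            state[name] = mod.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.value[...] = state[n]
        for name, _ in self._named_buffers():
            self._set_buffer(name, state[name])

    # buffers (batch-norm running stats) --------------------------------
    def _named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        if isinstance(self, BatchNorm2d):
            out.append((f"{prefix}running_mean", self.running_mean))
            out.append((f"{prefix}running_var", self.running_var))
        for cname, child in self._children.items():
            out.extend(child._named_buffers(prefix=f"{prefix}{cname}."))
        return out

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        mod: Module = self
        for part in parts[:-1]:
            mod = mod._children[part]
        setattr(mod, parts[-1], value.copy())

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        return self.forward(x, ctx)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self.register(str(i), layer)

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, ctx)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, ho, wo, kh, kw),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    # (n, ho*wo, c*kh*kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, ho * wo, c * kh * kw
    )
    return cols, ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[
                :, :, :, :, i, j
            ]
    return dx[:, :, pad : pad + h, pad : pad + w] if pad else dx


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col; He-initialised."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.weight = self.add_param("weight", w.astype(dtype))
        self.bias = self.add_param("bias", np.zeros(out_ch, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        wflat = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wflat.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, x.shape) if ctx.training else None
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.out_ch, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, f, ho, wo = grad.shape
        g = grad.reshape(n, f, ho * wo).transpose(0, 2, 1)  # (n, L, F)
        wflat = self.weight.value.reshape(self.out_ch, -1)
        self.weight.grad += np.einsum("nlf,nlk->fk", g, cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 1))
        dcols = g @ wflat
        self._cache = None
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.add_param("gamma", np.ones(ch, dtype=dtype))
        self.beta = self.add_param("beta", np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        if ctx.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if ctx.training:
            self._cache = (xhat, inv)
        return out.astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        axes = (0, 2, 3)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dgamma = (grad * xhat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        self.gamma.grad += dgamma.astype(self.gamma.grad.dtype)
        self.beta.grad += dbeta.astype(self.beta.grad.dtype)
        g = self.gamma.value[None, :, None, None]
        dx = (
            g
            * inv[None, :, None, None]
            * (grad - dbeta[None, :, None, None] / m - xhat * dgamma[None, :, None, None] / m)
        )
        return dx.astype(grad.dtype)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        mask = x > 0
        if ctx.training:
            self._mask = mask
        return np.where(mask, x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, grad, 0)


class Dropout(Module):
    """Inverted dropout; active in training and in Monte-Carlo inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def active(self, ctx: Context) -> bool:
        return self.rate > 0.0 and (ctx.training or ctx.mc_dropout)

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        if not self.active(ctx):
            return x
        if ctx.rng is None:
            raise ValueError("active dropout requires a random generator in the context")
        mask = (ctx.rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        if ctx.training:
            self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        mask, self._mask = self._mask, None
        return grad * mask


class AvgPool2d(Module):
    """Non-overlapping average pooling (kernel == stride); truncates remainders."""

    def __init__(self, kh: int, kw: int | None = None):
        super().__init__()
        self.kh, self.kw = kh, kw if kw is not None else kh
        self._in_shape = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // self.kh, w // self.kw
        trimmed = x[:, :, : ho * self.kh, : wo * self.kw]
        out = trimmed.reshape(n, c, ho, self.kh, wo, self.kw).mean(axis=(3, 5))
        if ctx.training:
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        self._in_shape = None
        ho, wo = grad.shape[2], grad.shape[3]
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        expanded = np.repeat(np.repeat(grad, self.kh, axis=2), self.kw, axis=3)
        dx[:, :, : ho * self.kh, : wo * self.kw] = expanded / (self.kh * self.kw)
        return dx


class MaxPool2d(Module):
    """Max pooling with arbitrary kernel/stride/padding (im2col based)."""

    def __init__(self, kernel: int, stride: int, pad: int = 0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        n, c, h, w = x.shape
        xi = x.reshape(n * c, 1, h, w)
        cols, ho, wo = _im2col(xi, self.kernel, self.kernel, self.stride, self.pad)
        cols = cols.reshape(n * c, ho * wo, self.kernel * self.kernel)
        arg = np.argmax(cols, axis=2)
        out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]
        if ctx.training:
            self._cache = (arg, x.shape, ho, wo)
        return out.reshape(n, c, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, x_shape, ho, wo = self._cache
        self._cache = None
        n, c, h, w = x_shape
        dcols = np.zeros((n * c, ho * wo, self.kernel * self.kernel), dtype=grad.dtype)
        np.put_along_axis(dcols, arg[:, :, None], grad.reshape(n * c, ho * wo, 1), axis=2)
        dxi = _col2im(dcols, (n * c, 1, h, w), self.kernel, self.kernel, self.stride, self.pad)
        return dxi.reshape(n, c, h, w)


class GlobalAvgPool2d(Module):
    def __init__(self):
        super().__init__()
        self._in_shape = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        if ctx.training:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        self._in_shape = None
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Flatten(Module):
    def __init__(self):
        super().__init__()
        self._in_shape = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        if ctx.training:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape, self._in_shape = self._in_shape, None
        return grad.reshape(shape)


class Linear(Module):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.weight = self.add_param("weight", w.astype(dtype))
        self.bias = self.add_param("bias", np.zeros(out_dim, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray, ctx: Context) -> np.ndarray:
        if ctx.training:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.weight.grad += grad.T @ x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


# ---------------------------------------------------------------------------
# loss / activations
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=np.float64)
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    per = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y
    wsum = w.sum()
    loss = float((w * per).sum() / wsum)
    grad = w * (sigmoid(z) - y) / wsum
    return loss, grad.astype(np.float64)
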