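"""Minimal numpy neural-network engine.

Self-contained module system used by the fusion architectures: layers hold
their weights as :class:`Param` objects, ``forward`` returns the output
together with an opaque per-call cache, and ``backward`` consumes that
cache so the same module object can be evaluated several times in one
forward pass (as the shared trunk of a late-fusion model is) without the
calls clobbering each other's state. Gradients accumulate into
``Param.grad``.

Convolutional layers implement both passes; transformer primitives
(attention, layer norm) and batch norm are inference-only, which covers
complexity accounting and structural checks for the large backbones while
training runs on the small norm-free convolutional models.

Complexity accounting convention: one multiply-accumulate counts as one
FLOP for convolutions, linear layers and attention matrix products; bias
additions, normalisation, activations, element-wise sums and upsampling
count one FLOP per output element.
"""
from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

Shape = Tuple[int, ...]  # (C, H, W) for image tensors


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: explicit children, deduplicated parameter traversal."""

    def children(self) -> List["Module"]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(m for m in v if isinstance(m, Module))
        return out

    def own_params(self) -> List[Param]:
        return [v for v in self.__dict__.values() if isinstance(v, Param)]

    def parameters(self) -> List[Param]:
        seen, out = set(), []

        def visit(mod):
            if id(mod) in seen:  # shared submodules contribute once
                return
            seen.add(id(mod))
            for p in mod.own_params():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
            for c in mod.children():
                visit(c)

        visit(self)
        return out

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- interface -----------------------------------------------------------
    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, gout, cache):
        raise NotImplementedError(
            f"{type(self).__name__} does not support backpropagation"
        )

    def complexity(self, in_shape):
        """Return (flops, out_shape) for one input sample of ``in_shape``."""
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train)


class Identity(Module):
    def forward(self, x, train=False):
        return x, None

    def backward(self, gout, cache):
        return gout

    def complexity(self, in_shape):
        return 0, in_shape


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = [l for l in layers if l is not None]

    def forward(self, x, train=False):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, train)
            caches.append(c)
        return x, caches

    def backward(self, gout, cache):
        for layer, c in zip(reversed(self.layers), reversed(cache)):
            gout = layer.backward(gout, c)
        return gout

    def complexity(self, in_shape):
        total = 0
        for layer in self.layers:
            f, in_shape = layer.complexity(in_shape)
            total += f
        return total, in_shape

    def __iter__(self):
        return iter(self.layers)


# ---------------------------------------------------------------------------
# convolution

def _pad_hw(x, pad):
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


def _im2col(x, k, stride, pad):
    """(N, C, H, W) -> (N, C, Ho, Wo, k, k) view of sliding windows."""
    xp = _pad_hw(x, pad)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=None, bias=True, groups=1,
                 rng: Optional[np.random.Generator] = None):
        if cin % groups or cout % groups:
            raise ValueError("channels must divide groups")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.groups = stride, groups
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin // groups * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), (cout, cin // groups, k, k))
        self.weight = Param(w)
        self.bias = Param(np.zeros(cout)) if bias else None

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if self.groups == 1:
            cols = _im2col(x, self.k, self.stride, self.pad)
            y = np.tensordot(cols, self.weight.value, axes=([1, 4, 5], [1, 2, 3]))
            y = np.moveaxis(y, 3, 1)
        else:
            cg_in = self.cin // self.groups
            cg_out = self.cout // self.groups
            outs = []
            for g in range(self.groups):
                cols = _im2col(
                    x[:, g * cg_in : (g + 1) * cg_in], self.k, self.stride, self.pad
                )
                wg = self.weight.value[g * cg_out : (g + 1) * cg_out]
                yg = np.tensordot(cols, wg, axes=([1, 4, 5], [1, 2, 3]))
                outs.append(np.moveaxis(yg, 3, 1))
            y = np.concatenate(outs, axis=1)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y, (x.shape, x if train else None)

    def backward(self, gout, cache):
        in_shape, x = cache
        if x is None:
            raise RuntimeError("forward was not run with train=True")
        if self.groups != 1:
            raise NotImplementedError("backward for grouped conv is not needed")
        n, _, h, w = in_shape
        cols = _im2col(x, self.k, self.stride, self.pad)
        # d weight
        self.weight.grad += np.tensordot(
            gout, cols, axes=([0, 2, 3], [0, 2, 3])
        )
        if self.bias is not None:
            self.bias.grad += gout.sum(axis=(0, 2, 3))
        # d input: scatter-add each kernel tap
        gx = np.zeros((n, self.cin, h + 2 * self.pad, w + 2 * self.pad),
                      dtype=np.float32)
        ho, wo = gout.shape[2], gout.shape[3]
        # (N, Ho, Wo, Cin, k, k) contributions
        contrib = np.tensordot(gout, self.weight.value, axes=([1], [0]))
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                gx[:, :, ki : ki + ho * s : s, kj : kj + wo * s : s] += (
                    np.moveaxis(contrib[..., ki, kj], 3, 1)
                )
        if self.pad:
            gx = gx[:, :, self.pad : -self.pad or None, self.pad : -self.pad or None]
        return gx

    def out_hw(self, h, w):
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        return ho, wo

    def complexity(self, in_shape):
        c, h, w = in_shape
        ho, wo = self.out_hw(h, w)
        flops = ho * wo * self.cout * (self.cin // self.groups) * self.k * self.k
        if self.bias is not None:
            flops += ho * wo * self.cout
        return flops, (self.cout, ho, wo)


class ConvTranspose2d(Module):
    """Stride-2 deconvolution (heatmap decoder of the plain-ViT models).

    Inference-only; output size is ``stride * H`` (k = 4, pad 1, out-pad 0
    convention).
    """

    def __init__(self, cin, cout, k=4, stride=2, pad=1,
                 rng: Optional[np.random.Generator] = None):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, math.sqrt(2.0 / (cin * k * k)), (cin, cout, k, k))
        self.weight = Param(w)
        self.bias = Param(np.zeros(cout))

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        full = np.zeros((n, self.cout, ho + 2 * self.pad, wo + 2 * self.pad),
                        dtype=np.float32)
        contrib = np.tensordot(x, self.weight.value, axes=([1], [0]))
        for ki in range(self.k):
            for kj in range(self.k):
                full[:, :, ki : ki + h * self.stride : self.stride,
                     kj : kj + w * self.stride : self.stride] += np.moveaxis(
                    contrib[..., ki, kj], 3, 1
                )
        y = full[:, :, self.pad : self.pad + ho, self.pad : self.pad + wo]
        y += self.bias.value[None, :, None, None]
        return y, None

    def complexity(self, in_shape):
        c, h, w = in_shape
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        flops = h * w * self.cin * self.cout * self.k * self.k + ho * wo * self.cout
        return flops, (self.cout, ho, wo)


class BatchNorm2d(Module):
    """Inference-mode batch norm (running statistics)."""

    def __init__(self, c, eps=1e-5):
        self.c, self.eps = c, eps
        self.weight = Param(np.ones(c))
        self.bias = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x, train=False):
        scale = self.weight.value / np.sqrt(self.running_var + self.eps)
        shift = self.bias.value - self.running_mean * scale
        return x * scale[None, :, None, None] + shift[None, :, None, None], None

    def complexity(self, in_shape):
        c, h, w = in_shape
        return c * h * w, in_shape


class ReLU(Module):
    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        return y, (x > 0) if train else None

    def backward(self, gout, cache):
        return gout * cache

    def complexity(self, in_shape):
        return int(np.prod(in_shape)), in_shape


class GELU(Module):
    def forward(self, x, train=False):
        return 0.5 * x * (1.0 + np.tanh(0.7978845608 * (x + 0.044715 * x**3))), None

    def complexity(self, in_shape):
        return int(np.prod(in_shape)), in_shape


class Upsample(Module):
    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x, train=False):
        f = self.factor
        return np.repeat(np.repeat(x, f, axis=2), f, axis=3), None

    def complexity(self, in_shape):
        c, h, w = in_shape
        out = (c, h * self.factor, w * self.factor)
        return int(np.prod(out)), out


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.weight = Param(rng.normal(0, math.sqrt(1.0 / cin), (cout, cin)))
        self.bias = Param(np.zeros(cout)) if bias else None

    def forward(self, x, train=False):
        y = x @ self.weight.value.T
        if self.bias is not None:
            y = y + self.bias.value
        return y, None

    def complexity(self, in_shape):
        *lead, c = in_shape
        tokens = int(np.prod(lead)) if lead else 1
        flops = tokens * c * self.cout
        if self.bias is not None:
            flops += tokens * self.cout
        return flops, (*lead, self.cout)


class LayerNorm(Module):
    def __init__(self, c, eps=1e-6):
        self.c, self.eps = c, eps
        self.weight = Param(np.ones(c))
        self.bias = Param(np.zeros(c))

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        y = (x - mu) / np.sqrt(var + self.eps)
        return y * self.weight.value + self.bias.value, None

    def complexity(self, in_shape):
        return int(np.prod(in_shape)), in_shape


def _softmax(x, axis=-1):
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def _rel_pos_index(w: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(w), np.arange(w), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel + (w - 1)
    return rel[0] * (2 * w - 1) + rel[1]  # (w*w, w*w)


class WindowAttention(Module):
    """Local-window multi-head self-attention with relative position bias.

    Operates on (N, C, H, W); the map is zero-padded to a multiple of the
    window size, partitioned into non-overlapping windows, attended within
    each window and stitched back.
    """

    def __init__(self, c, heads, window=7, rng=None):
        if c % heads:
            raise ValueError("heads must divide channels")
        rng = rng or np.random.default_rng(0)
        self.c, self.heads, self.window = c, heads, window
        self.qkv = Linear(c, 3 * c, rng=rng)
        self.proj = Linear(c, c, rng=rng)
        self.rel_bias = Param(
            rng.normal(0, 0.02, ((2 * window - 1) ** 2, heads))
        )
        self._index = _rel_pos_index(window)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        win = self.window
        ph, pw = (-h) % win, (-w) % win
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        hh, ww = xp.shape[2], xp.shape[3]
        nh, nw = hh // win, ww // win
        t = win * win
        tok = (
            xp.reshape(n, c, nh, win, nw, win)
            .transpose(0, 2, 4, 3, 5, 1)
            .reshape(n * nh * nw, t, c)
        )
        qkv, _ = self.qkv.forward(tok)
        dh = c // self.heads
        qkv = qkv.reshape(-1, t, 3, self.heads, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, heads, T, dh)
        attn = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh)
        bias = self.rel_bias.value[self._index]  # (T, T, heads)
        attn = attn + bias.transpose(2, 0, 1)[None]
        attn = _softmax(attn, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(-1, t, c)
        out, _ = self.proj.forward(out)
        y = (
            out.reshape(n, nh, nw, win, win, c)
            .transpose(0, 5, 1, 3, 2, 4)
            .reshape(n, c, hh, ww)
        )
        return y[:, :, :h, :w], None

    def complexity(self, in_shape):
        c, h, w = in_shape
        win = self.window
        hh, ww = h + (-h) % win, w + (-w) % win
        nwin = (hh // win) * (ww // win)
        t = win * win
        f_qkv, _ = self.qkv.complexity((nwin * t, c))
        f_proj, _ = self.proj.complexity((nwin * t, c))
        f_mat = 2 * nwin * t * t * c  # QK^T and AV
        f_soft = 2 * nwin * self.heads * t * t  # softmax + bias add
        return f_qkv + f_proj + f_mat + f_soft, in_shape


class TokenAttention(Module):
    """Full multi-head self-attention over a token sequence (N, T, C)."""

    def __init__(self, c, heads, rng=None):
        rng = rng or np.random.default_rng(0)
        self.c, self.heads = c, heads
        self.qkv = Linear(c, 3 * c, rng=rng)
        self.proj = Linear(c, c, rng=rng)

    def forward(self, x, train=False):
        n, t, c = x.shape
        dh = c // self.heads
        qkv, _ = self.qkv.forward(x)
        qkv = qkv.reshape(n, t, 3, self.heads, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = _softmax(q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, c)
        return self.proj.forward(out)[0], None

    def complexity(self, in_shape):
        t, c = in_shape
        f_qkv, _ = self.qkv.complexity((t, c))
        f_proj, _ = self.proj.complexity((t, c))
        f_mat = 2 * t * t * c
        f_soft = self.heads * t * t
        return f_qkv + f_proj + f_mat + f_soft, in_shape


class Add(Module):
    """Element-wise sum of a list of equally shaped tensors."""

    def forward(self, xs, train=False):
        out = xs[0].copy()
        for x in xs[1:]:
            out += x
        return out, len(xs)

    def backward(self, gout, cache):
        return [gout] * cache

    def complexity(self, in_shapes):
        shape = in_shapes[0]
        return (len(in_shapes) - 1) * int(np.prod(shape)), shape


def tree_sum(features):
    """Sum a list of feature pytrees (tensor, or list of tensors)."""
    first = features[0]
    if isinstance(first, (list, tuple)):
        return [tree_sum([f[i] for f in features]) for i in range(len(first))]
    out = first.copy()
    for f in features[1:]:
        out += f
    return out


def copy_params_into(dst: Module, src: Module) -> None:
    """Copy parameters of ``src`` into structurally identical ``dst``."""
    ps, pd = src.parameters(), dst.parameters()
    if len(ps) != len(pd):
        raise ValueError("parameter structure mismatch")
    for a, b in zip(pd, ps):
        if a.value.shape != b.value.shape:
            raise ValueError("parameter shape mismatch")
        a.value[...] = b.value
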