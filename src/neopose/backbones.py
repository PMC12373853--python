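"""Stage-partitioned pose backbones.

Every backbone is organised as ``stem -> four stages -> key-point head`` so
that fusion models can split it at a stage boundary X into an
image-type-specific *Part 1* (stem + stages 1..X) and a shared *Part 2*
(stages X+1..4 + head). Composing Part 1 and Part 2 reproduces the
unpartitioned forward pass exactly, because both views reference the same
layer objects.

Families:

* ``hrnet_w32`` / ``hrnet_w48`` — four-stage multi-resolution convolutional
  networks (basic residual blocks, conv-based cross-resolution fusion).
* ``hrformer_s`` / ``hrformer_b`` — the transformer counterpart: the same
  multi-resolution layout with local-window self-attention blocks,
  depth-wise-conv FFNs and separable-conv fusion.
* ``vit_s`` / ``vit_b`` — a plain vision transformer with a deconvolution
  heatmap decoder; each stage is a quarter of the transformer blocks, with
  the patch embedding included in the first stage.
* ``tiny`` — a norm-free reduced convolutional backbone (full forward and
  backward support) used for desk-scale training experiments.

Inter-stage transitions are counted with the stage they feed.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import (
    Add,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    GELU,
    Identity,
    LayerNorm,
    Linear,
    Module,
    Param,
    ReLU,
    Sequential,
    TokenAttention,
    Upsample,
    WindowAttention,
)


# ---------------------------------------------------------------------------
# residual blocks

class BasicBlock(Module):
    """HRNet basic residual block (3x3 conv - BN - ReLU - 3x3 conv - BN)."""

    def __init__(self, c, rng):
        self.body = Sequential(
            Conv2d(c, c, 3, bias=False, rng=rng),
            BatchNorm2d(c),
            ReLU(),
            Conv2d(c, c, 3, bias=False, rng=rng),
            BatchNorm2d(c),
        )
        self.relu = ReLU()

    def forward(self, x, train=False):
        y, _ = self.body.forward(x)
        return self.relu.forward(x + y)[0], None

    def complexity(self, in_shape):
        f, out = self.body.complexity(in_shape)
        f += int(np.prod(out))  # residual add
        f += int(np.prod(out))  # relu
        return f, out


class Bottleneck(Module):
    """HRNet bottleneck block with expansion 4."""

    def __init__(self, cin, planes, rng):
        cout = planes * 4
        self.body = Sequential(
            Conv2d(cin, planes, 1, bias=False, rng=rng),
            BatchNorm2d(planes),
            ReLU(),
            Conv2d(planes, planes, 3, bias=False, rng=rng),
            BatchNorm2d(planes),
            ReLU(),
            Conv2d(planes, cout, 1, bias=False, rng=rng),
            BatchNorm2d(cout),
        )
        self.down = (
            Sequential(Conv2d(cin, cout, 1, bias=False, rng=rng), BatchNorm2d(cout))
            if cin != cout
            else Identity()
        )
        self.relu = ReLU()

    def forward(self, x, train=False):
        y, _ = self.body.forward(x)
        r, _ = self.down.forward(x)
        return self.relu.forward(r + y)[0], None

    def complexity(self, in_shape):
        f, out = self.body.complexity(in_shape)
        fd, _ = self.down.complexity(in_shape)
        return f + fd + 2 * int(np.prod(out)), out


class PlainResBlock(Module):
    """Norm-free residual block of the reduced backbone (trainable)."""

    def __init__(self, c, rng):
        self.conv1 = Conv2d(c, c, 3, rng=rng)
        self.conv2 = Conv2d(c, c, 3, rng=rng)
        self.relu1 = ReLU()
        self.relu2 = ReLU()

    def forward(self, x, train=False):
        h, c1 = self.conv1.forward(x, train)
        h, r1 = self.relu1.forward(h, train)
        h, c2 = self.conv2.forward(h, train)
        y, r2 = self.relu2.forward(x + h, train)
        return y, (c1, r1, c2, r2)

    def backward(self, gout, cache):
        c1, r1, c2, r2 = cache
        g = self.relu2.backward(gout, r2)
        gh = self.conv2.backward(g, c2)
        gh = self.relu1.backward(gh, r1)
        gh = self.conv1.backward(gh, c1)
        return g + gh

    def complexity(self, in_shape):
        f1, out = self.conv1.complexity(in_shape)
        f2, _ = self.relu1.complexity(out)
        f3, _ = self.conv2.complexity(out)
        return f1 + f2 + f3 + 2 * int(np.prod(out)), out


# ---------------------------------------------------------------------------
# transformer blocks

class ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of an (N, C, H, W) map."""

    def __init__(self, c):
        self.ln = LayerNorm(c)

    def forward(self, x, train=False):
        y, _ = self.ln.forward(np.moveaxis(x, 1, -1))
        return np.ascontiguousarray(np.moveaxis(y, -1, 1)), None

    def complexity(self, in_shape):
        return int(np.prod(in_shape)), in_shape


class MlpDWConv(Module):
    """HRFormer feed-forward: 1x1 conv, depth-wise 3x3, 1x1 conv (each BN)."""

    def __init__(self, c, ratio, rng):
        h = c * ratio
        self.body = Sequential(
            Conv2d(c, h, 1, rng=rng),
            BatchNorm2d(h),
            GELU(),
            Conv2d(h, h, 3, groups=h, rng=rng),
            BatchNorm2d(h),
            GELU(),
            Conv2d(h, c, 1, rng=rng),
            BatchNorm2d(c),
        )

    def forward(self, x, train=False):
        return self.body.forward(x)[0], None

    def complexity(self, in_shape):
        return self.body.complexity(in_shape)


class HRFormerBlock(Module):
    """Local-window attention block operating on an (N, C, H, W) map."""

    def __init__(self, c, heads, window, ratio, rng):
        self.norm1 = ChannelLayerNorm(c)
        self.attn = WindowAttention(c, heads, window, rng=rng)
        self.norm2 = ChannelLayerNorm(c)
        self.ffn = MlpDWConv(c, ratio, rng)

    def forward(self, x, train=False):
        x = x + self.attn.forward(self.norm1.forward(x)[0])[0]
        x = x + self.ffn.forward(self.norm2.forward(x)[0])[0]
        return x, None

    def complexity(self, in_shape):
        f = 0
        for mod in (self.norm1, self.attn, self.norm2, self.ffn):
            fi, _ = mod.complexity(in_shape)
            f += fi
        f += 2 * int(np.prod(in_shape))  # two residual adds
        return f, in_shape


class ViTBlock(Module):
    def __init__(self, c, heads, rng, ratio=4):
        self.norm1 = LayerNorm(c)
        self.attn = TokenAttention(c, heads, rng=rng)
        self.norm2 = LayerNorm(c)
        self.mlp = Sequential(
            Linear(c, ratio * c, rng=rng), GELU(), Linear(ratio * c, c, rng=rng)
        )

    def forward(self, x, train=False):
        x = x + self.attn.forward(self.norm1.forward(x)[0])[0]
        x = x + self.mlp.forward(self.norm2.forward(x)[0])[0]
        return x, None

    def complexity(self, in_shape):
        f = 0
        for mod in (self.norm1, self.attn, self.norm2, self.mlp):
            fi, _ = mod.complexity(in_shape)
            f += fi
        f += 2 * int(np.prod(in_shape))
        return f, in_shape


# ---------------------------------------------------------------------------
# multi-resolution plumbing

def _as_list(x):
    return x if isinstance(x, list) else [x]


def _conv_bn_relu(cin, cout, stride, rng, relu=True):
    layers = [Conv2d(cin, cout, 3, stride=stride, bias=False, rng=rng),
              BatchNorm2d(cout)]
    if relu:
        layers.append(ReLU())
    return Sequential(*layers)


class Transition(Module):
    """Adapt the previous stage's branches to the next stage's channel plan,
    creating one new lower-resolution branch when the plan grows."""

    def __init__(self, in_chs, out_chs, rng):
        self.per_branch = []
        for b, cout in enumerate(out_chs):
            if b < len(in_chs):
                self.per_branch.append(
                    Identity() if in_chs[b] == cout
                    else _conv_bn_relu(in_chs[b], cout, 1, rng)
                )
            else:
                self.per_branch.append(_conv_bn_relu(in_chs[-1], cout, 2, rng))

    def forward(self, xs, train=False):
        xs = _as_list(xs)
        out = []
        for b, mod in enumerate(self.per_branch):
            src = xs[b] if b < len(xs) else xs[-1]
            out.append(mod.forward(src)[0])
        return out, None

    def complexity(self, in_shapes):
        in_shapes = in_shapes if isinstance(in_shapes, list) else [in_shapes]
        total, out = 0, []
        for b, mod in enumerate(self.per_branch):
            src = in_shapes[b] if b < len(in_shapes) else in_shapes[-1]
            f, shape = mod.complexity(src)
            total += f
            out.append(shape)
        return total, out


def _fuse_down(cj, ci, steps, style, rng):
    """j -> i (finer to coarser) downsampling path of the fuse layer."""
    layers = []
    for k in range(steps):
        last = k == steps - 1
        cout = ci if last else cj
        if style == "conv":
            layers.append(Conv2d(cj, cout, 3, stride=2, bias=False, rng=rng))
            layers.append(BatchNorm2d(cout))
        else:  # separable (transformer stages)
            layers.append(Conv2d(cj, cj, 3, stride=2, groups=cj, bias=False,
                                 rng=rng))
            layers.append(BatchNorm2d(cj))
            layers.append(Conv2d(cj, cout, 1, bias=False, rng=rng))
            layers.append(BatchNorm2d(cout))
        if not last:
            layers.append(ReLU())
    return Sequential(*layers)


class FuseLayers(Module):
    """HRNet-style cross-resolution fusion at the end of a module."""

    def __init__(self, channels, style, rng, multi_scale_output=True):
        self.n = len(channels)
        self.n_out = self.n if multi_scale_output else 1
        self.paths = []  # [i][j]
        for i in range(self.n_out):
            row = []
            for j in range(self.n):
                if j == i:
                    row.append(Identity())
                elif j > i:
                    row.append(
                        Sequential(
                            Conv2d(channels[j], channels[i], 1, bias=False,
                                   rng=rng),
                            BatchNorm2d(channels[i]),
                            Upsample(2 ** (j - i)),
                        )
                    )
                else:
                    row.append(_fuse_down(channels[j], channels[i], i - j,
                                          style, rng))
            self.paths.append(row)
        self.relu = ReLU()

    def children(self):
        return [m for row in self.paths for m in row] + [self.relu]

    def forward(self, xs, train=False):
        out = []
        for i in range(self.n_out):
            acc = None
            for j in range(self.n):
                y, _ = self.paths[i][j].forward(xs[j])
                acc = y if acc is None else acc + y
            out.append(self.relu.forward(acc)[0])
        return out, None

    def complexity(self, in_shapes):
        total, out = 0, []
        for i in range(self.n_out):
            shape_i = None
            for j in range(self.n):
                f, shape = self.paths[i][j].complexity(in_shapes[j])
                total += f
                if j == i or shape_i is None:
                    shape_i = shape
            total += (self.n - 1) * int(np.prod(shape_i))  # sums
            total += int(np.prod(shape_i))  # relu
            out.append(shape_i)
        return total, out


class HRModule(Module):
    """Per-branch block stacks followed by cross-resolution fusion."""

    def __init__(self, channels, make_branch_blocks, style, rng,
                 multi_scale_output=True):
        self.branches = [make_branch_blocks(c) for c in channels]
        self.fuse = (
            FuseLayers(channels, style, rng, multi_scale_output)
            if len(channels) > 1
            else None
        )

    def forward(self, xs, train=False):
        ys = [b.forward(x)[0] for b, x in zip(self.branches, xs)]
        if self.fuse is not None:
            ys, _ = self.fuse.forward(ys)
        return ys, None

    def complexity(self, in_shapes):
        total, shapes = 0, []
        for b, s in zip(self.branches, in_shapes):
            f, out = b.complexity(s)
            total += f
            shapes.append(out)
        if self.fuse is not None:
            f, shapes = self.fuse.complexity(shapes)
            total += f
        return total, shapes


class HRStage(Module):
    """Transition into a channel plan plus a run of HR modules."""

    def __init__(self, in_chs, out_chs, num_modules, make_branch_blocks, style,
                 rng, final_multi_scale=True):
        self.transition = Transition(in_chs, out_chs, rng)
        self.modules_ = [
            HRModule(
                out_chs,
                make_branch_blocks,
                style,
                rng,
                multi_scale_output=(m < num_modules - 1) or final_multi_scale,
            )
            for m in range(num_modules)
        ]

    def forward(self, xs, train=False):
        xs, _ = self.transition.forward(xs)
        for mod in self.modules_:
            xs, _ = mod.forward(xs)
        return xs, None

    def complexity(self, in_shapes):
        total, shapes = self.transition.complexity(in_shapes)
        for mod in self.modules_:
            f, shapes = mod.complexity(shapes)
            total += f
        return total, shapes


class BranchZeroHead(Module):
    """1x1 conv key-point head on the highest-resolution branch."""

    def __init__(self, cin, num_keypoints, rng):
        self.conv = Conv2d(cin, num_keypoints, 1, rng=rng)

    def forward(self, xs, train=False):
        x = xs[0] if isinstance(xs, list) else xs
        return self.conv.forward(x, train)

    def backward(self, gout, cache):
        return self.conv.backward(gout, cache)

    def complexity(self, in_shapes):
        shape = in_shapes[0] if isinstance(in_shapes, list) else in_shapes
        return self.conv.complexity(shape)


# ---------------------------------------------------------------------------
# ViT plumbing

class PatchEmbed(Module):
    def __init__(self, in_ch, embed, patch, img_hw, rng):
        self.proj = Conv2d(in_ch, embed, patch, stride=patch, pad=0, rng=rng)
        self.grid = (img_hw[0] // patch, img_hw[1] // patch)
        t = self.grid[0] * self.grid[1]
        self.pos = Param(rng.normal(0, 0.02, (t, embed)))

    def forward(self, x, train=False):
        y, _ = self.proj.forward(x)
        n, c = y.shape[0], y.shape[1]
        tok = y.reshape(n, c, -1).transpose(0, 2, 1)
        return tok + self.pos.value, None

    def complexity(self, in_shape):
        f, (c, h, w) = self.proj.complexity(in_shape)
        return f + h * w * c, (h * w, c)


class TokensToMap(Module):
    def __init__(self, grid):
        self.grid = grid

    def forward(self, x, train=False):
        n, t, c = x.shape
        h, w = self.grid
        return x.transpose(0, 2, 1).reshape(n, c, h, w), None

    def complexity(self, in_shape):
        t, c = in_shape
        return 0, (c, self.grid[0], self.grid[1])


# ---------------------------------------------------------------------------
# backbone assembly

@dataclass
class StagePartitionedBackbone:
    """A stem, four stages and a key-point head with split-point support."""

    name: str
    stem: Module
    stages: List[Module]
    head: Module
    first_conv: Conv2d
    input_size: Tuple[int, int]
    heatmap_stride: int
    trainable: bool = False

    def part1(self, x: int) -> Sequential:
        if not 1 <= x <= 4:
            raise ValueError("split point X must be in 1..4")
        return Sequential(self.stem, *self.stages[:x])

    def part2(self, x: int) -> Sequential:
        if not 1 <= x <= 4:
            raise ValueError("split point X must be in 1..4")
        return Sequential(*self.stages[x:], self.head)

    def full(self) -> Sequential:
        return Sequential(self.stem, *self.stages, self.head)

    def num_params(self) -> int:
        return self.full().num_params()


def _hr_stem(in_ch, rng):
    conv1 = Conv2d(in_ch, 64, 3, stride=2, bias=False, rng=rng)
    stem = Sequential(
        conv1, BatchNorm2d(64), ReLU(),
        Conv2d(64, 64, 3, stride=2, bias=False, rng=rng), BatchNorm2d(64), ReLU(),
    )
    return stem, conv1


def build_hrnet(width, in_ch, num_keypoints, input_size, rng) -> StagePartitionedBackbone:
    chs = [width, 2 * width, 4 * width, 8 * width]
    stem, first_conv = _hr_stem(in_ch, rng)
    stage1 = Sequential(
        Bottleneck(64, 64, rng), *[Bottleneck(256, 64, rng) for _ in range(3)]
    )

    def blocks(c):
        return Sequential(*[BasicBlock(c, rng) for _ in range(4)])

    stage2 = HRStage([256], chs[:2], 1, blocks, "conv", rng)
    stage3 = HRStage(chs[:2], chs[:3], 4, blocks, "conv", rng)
    stage4 = HRStage(chs[:3], chs, 3, blocks, "conv", rng,
                     final_multi_scale=False)
    head = BranchZeroHead(chs[0], num_keypoints, rng)
    return StagePartitionedBackbone(
        name=f"hrnet_w{width}", stem=stem,
        stages=[stage1, stage2, stage3, stage4], head=head,
        first_conv=first_conv, input_size=input_size, heatmap_stride=4,
    )


def build_hrformer(size, in_ch, num_keypoints, input_size, rng) -> StagePartitionedBackbone:
    if size == "s":
        chs, heads = [32, 64, 128, 256], [1, 2, 4, 8]
    elif size == "b":
        chs, heads = [78, 156, 312, 624], [2, 4, 8, 16]
    else:
        raise ValueError(size)
    window, ratio = 7, 4
    stem, first_conv = _hr_stem(in_ch, rng)
    stage1 = Sequential(Bottleneck(64, 64, rng), Bottleneck(256, 64, rng))

    def make_blocks(c):
        h = heads[chs.index(c)]
        return Sequential(
            HRFormerBlock(c, h, window, ratio, rng),
            HRFormerBlock(c, h, window, ratio, rng),
        )

    stage2 = HRStage([256], chs[:2], 1, make_blocks, "sep", rng)
    stage3 = HRStage(chs[:2], chs[:3], 4, make_blocks, "sep", rng)
    stage4 = HRStage(chs[:3], chs, 2, make_blocks, "sep", rng,
                     final_multi_scale=False)
    head = BranchZeroHead(chs[0], num_keypoints, rng)
    return StagePartitionedBackbone(
        name=f"hrformer_{size}", stem=stem,
        stages=[stage1, stage2, stage3, stage4], head=head,
        first_conv=first_conv, input_size=input_size, heatmap_stride=4,
    )


def build_vit(size, in_ch, num_keypoints, input_size, rng) -> StagePartitionedBackbone:
    if size == "s":
        embed, heads = 384, 6
    elif size == "b":
        embed, heads = 768, 12
    else:
        raise ValueError(size)
    depth, patch = 12, 16
    pe = PatchEmbed(in_ch, embed, patch, input_size, rng)
    blocks = [ViTBlock(embed, heads, rng) for _ in range(depth)]
    q = depth // 4
    stage1 = Sequential(pe, *blocks[:q])
    stage2 = Sequential(*blocks[q : 2 * q])
    stage3 = Sequential(*blocks[2 * q : 3 * q])
    stage4 = Sequential(*blocks[3 * q :], LayerNorm(embed))
    head = Sequential(
        TokensToMap(pe.grid),
        ConvTranspose2d(embed, 256, rng=rng), BatchNorm2d(256), ReLU(),
        ConvTranspose2d(256, 256, rng=rng), BatchNorm2d(256), ReLU(),
        Conv2d(256, num_keypoints, 1, rng=rng),
    )
    return StagePartitionedBackbone(
        name=f"vit_{size}", stem=Identity(),
        stages=[stage1, stage2, stage3, stage4], head=head,
        first_conv=pe.proj, input_size=input_size, heatmap_stride=4,
    )


def build_tiny(in_ch, num_keypoints, input_size, rng, width=24) -> StagePartitionedBackbone:
    """Reduced norm-free convolutional backbone with full backward support."""
    first_conv = Conv2d(in_ch, width // 2, 3, stride=2, rng=rng)
    stem = Sequential(first_conv, ReLU(),
                      Conv2d(width // 2, width, 3, stride=2, rng=rng), ReLU())
    stages = [Sequential(PlainResBlock(width, rng)) for _ in range(4)]
    head = BranchZeroHead(width, num_keypoints, rng)
    return StagePartitionedBackbone(
        name="tiny", stem=stem, stages=stages, head=head,
        first_conv=first_conv, input_size=input_size, heatmap_stride=4,
        trainable=True,
    )


#: registry: name -> (builder kwargs, default input size (H, W))
BACKBONES = {
    "hrnet_w32": (lambda in_ch, k, sz, rng: build_hrnet(32, in_ch, k, sz, rng), (256, 256)),
    "hrnet_w48": (lambda in_ch, k, sz, rng: build_hrnet(48, in_ch, k, sz, rng), (384, 384)),
    "hrformer_s": (lambda in_ch, k, sz, rng: build_hrformer("s", in_ch, k, sz, rng), (384, 384)),
    "hrformer_b": (lambda in_ch, k, sz, rng: build_hrformer("b", in_ch, k, sz, rng), (384, 384)),
    "vit_s": (lambda in_ch, k, sz, rng: build_vit("s", in_ch, k, sz, rng), (256, 192)),
    "vit_b": (lambda in_ch, k, sz, rng: build_vit("b", in_ch, k, sz, rng), (256, 192)),
    "tiny": (lambda in_ch, k, sz, rng: build_tiny(in_ch, k, sz, rng), (64, 64)),
}


def build_backbone(name: str, in_channels: int, num_keypoints: int = 4,
                   input_size: Optional[Tuple[int, int]] = None,
                   seed: int = 0) -> StagePartitionedBackbone:
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; choose from {sorted(BACKBONES)}")
    builder, default_size = BACKBONES[name]
    rng = np.random.default_rng([seed, zlib.crc32(name.encode())])
    return builder(in_channels, num_keypoints, input_size or default_size, rng)
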