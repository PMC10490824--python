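"""Building blocks of the detector.

* ``CBS``     — conv + batch-norm + SiLU, the basic unit.
* ``MP``      — parallel max-pool / strided-conv downsampling block.
* ``ELAN`` / ``ELANW`` — efficient layer-aggregation blocks (backbone / neck).
* ``CoTBlock`` — contextual-transformer operator: a static 3x3 group-conv
  context branch (K1) fused (elementwise sum) with a dynamic branch (K2) that
  re-weights each 3x3 neighborhood of the value map with learned per-head
  attention.
* ``CoTLAN``  — ELAN with its final 3x3 convolution replaced by a CoTBlock.
* ``CoordAtt`` — coordinate attention: height- and width-pooled descriptors
  produce two sigmoid gates multiplied back onto the input.
* ``SPPCSP``  — CSP-wrapped spatial pyramid pooling (5/9/13 max-pool set).
* ``RepC``    — re-parameterizable conv (3x3 + 1x1 + identity branches at
  train time, fusable into a single 3x3 conv for deployment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, Module


@dataclass
class CoTConfig:
    """Hyperparameters of the contextual-transformer block.

    ``heads`` weight maps are shared across groups of ``channels/heads``
    value channels; the attention map at each location is 3x3 per head.
    """

    channels: int
    heads: int | None = None  # default: max(channels // 64, 1)
    groups: int = 4           # group count of the static 3x3 context conv
    reduction: int = 4        # bottleneck factor of the attention embed

    def __post_init__(self):
        if self.heads is None:
            self.heads = max(self.channels // 64, 1)
        if self.channels % self.heads:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by heads ({self.heads})"
            )


@dataclass
class CoordAttConfig:
    channels: int
    reduction: int = 32
    min_mid_channels: int = 8

    @property
    def mid_channels(self) -> int:
        return max(self.channels // self.reduction, self.min_mid_channels)


class CBS(Module):
    """Conv-BN-SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, groups: int = 1):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("CBS kernel must be odd (same-padding)")
        if s not in (1, 2):
            raise ValueError("CBS stride must be 1 or 2")
        self.conv = Conv2d(c1, c2, k, stride=s, groups=groups)
        self.bn = BatchNorm2d(c2)

    def forward(self, x: Tensor) -> Tensor:
        return ag.silu(self.bn(self.conv(x)))


class MP(Module):
    """Downsampling block: max-pool path and strided-conv path, concatenated.

    Each path carries ``c2 // 2`` channels; spatial dims are halved (inputs
    must have even height/width).
    """

    def __init__(self, c1: int, c2: int | None = None):
        super().__init__()
        c2 = c1 if c2 is None else c2
        if c2 % 2:
            raise ValueError("MP output channels must be even")
        self.cv_pool = CBS(c1, c2 // 2, 1, 1)
        self.cv_pre = CBS(c1, c2 // 2, 1, 1)
        self.cv_down = CBS(c2 // 2, c2 // 2, 3, 2)
        self.out_channels = c2

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"MP requires even spatial dims, got {x.shape[2:]}")
        p1 = self.cv_pool(ag.maxpool2d(x, 2, 2))
        p2 = self.cv_down(self.cv_pre(x))
        return ag.cat([p2, p1], axis=1)


class _ElanBase(Module):
    """Shared topology of ELAN/CoTLAN: two 1x1 entry branches, a chain of
    four 3x3 stages tapped after stages 2 and 4, concat, 1x1 merge."""

    def __init__(self, c1: int, c_hidden: int, c2: int, final_stage: Module | None = None):
        super().__init__()
        self.cv1 = CBS(c1, c_hidden, 1, 1)
        self.cv2 = CBS(c1, c_hidden, 1, 1)
        self.chain = [
            CBS(c_hidden, c_hidden, 3, 1),
            CBS(c_hidden, c_hidden, 3, 1),
            CBS(c_hidden, c_hidden, 3, 1),
            final_stage if final_stage is not None else CBS(c_hidden, c_hidden, 3, 1),
        ]
        self.merge = CBS(4 * c_hidden, c2, 1, 1)
        self.in_channels, self.out_channels = c1, c2

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.cv1(x)
        y2 = self.cv2(x)
        t = self.chain[1](self.chain[0](y2))
        t2 = self.chain[3](self.chain[2](t))
        return self.merge(ag.cat([t2, t, y2, y1], axis=1))


class ELAN(_ElanBase):
    """Baseline efficient layer-aggregation block (backbone flavor)."""


class CoTBlock(Module):
    """Contextual-transformer block (shape-preserving).

    K1 = BN+SiLU(GroupConv3x3(K)) is the static local context; the attention
    map A = Conv1x1(act(BN(Conv1x1([K1, Q])))) produces, per head, nine
    weights per location that aggregate the 3x3 neighborhood of the value
    embedding V into the dynamic context K2.  Output = K1 + K2.
    """

    def __init__(self, cfg: CoTConfig):
        super().__init__()
        c, heads = cfg.channels, cfg.heads
        self.cfg = cfg
        groups = cfg.groups
        while c % groups:
            groups //= 2  # degrade gracefully for tiny channel counts
        self.key_embed = Conv2d(c, c, 3, groups=groups)
        self.key_bn = BatchNorm2d(c)
        self.value = Conv2d(c, c, 1)
        self.value_bn = BatchNorm2d(c)
        mid = max(2 * c // cfg.reduction, 1)
        self.attn1 = Conv2d(2 * c, mid, 1)
        self.attn_bn = BatchNorm2d(mid)
        self.attn2 = Conv2d(mid, 9 * heads, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        c, heads = self.cfg.channels, self.cfg.heads
        if x.shape[1] != c:
            raise ValueError(f"CoTBlock expects {c} channels, got {x.shape[1]}")
        n, _, h, w = x.shape
        k1 = ag.silu(self.key_bn(self.key_embed(x)))
        v = self.value_bn(self.value(x))
        att = self.attn2(ag.silu(self.attn_bn(self.attn1(ag.cat([k1, x], axis=1)))))
        att = att.reshape(n, heads, 1, 9, h, w)
        v_neigh = ag.unfold3x3(v).reshape(n, heads, c // heads, 9, h, w)
        k2 = (v_neigh * att).sum(axis=3).reshape(n, c, h, w)
        return k1 + k2


class CoTLAN(_ElanBase):
    """ELAN with the last 3x3 conv of the chain replaced by a CoTBlock."""

    def __init__(self, c1: int, c_hidden: int, c2: int,
                 cot_groups: int = 4, cot_reduction: int = 4):
        super().__init__(
            c1, c_hidden, c2,
            final_stage=CoTBlock(
                CoTConfig(c_hidden, groups=cot_groups, reduction=cot_reduction)
            ),
        )


class CoordAtt(Module):
    """Coordinate attention.

    The input is average-pooled along width (z^h, one value per row) and
    along height (z^w, one per column); the concatenated descriptor passes a
    shared 1x1 bottleneck, is split back, and two 1x1 convs + sigmoid give the
    row gate g^h and column gate g^w.  Output: y_c(i,j) = x_c(i,j) g^h_c(i)
    g^w_c(j).
    """

    def __init__(self, cfg: CoordAttConfig):
        super().__init__()
        self.cfg = cfg
        c, mid = cfg.channels, cfg.mid_channels
        self.conv1 = Conv2d(c, mid, 1)
        self.bn1 = BatchNorm2d(mid)
        self.conv_h = Conv2d(mid, c, 1, bias=True)
        self.conv_w = Conv2d(mid, c, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"CoordAtt expects {self.cfg.channels} channels, got {x.shape[1]}"
            )
        n, c, h, w = x.shape
        z_h = x.mean(axis=3, keepdims=True)                    # (N,C,H,1)
        z_w = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (N,C,W,1)
        f = ag.hardswish(self.bn1(self.conv1(ag.cat([z_h, z_w], axis=2))))
        f_h = f[:, :, :h, :]
        f_w = f[:, :, h:, :].transpose(0, 1, 3, 2)
        g_h = ag.sigmoid(self.conv_h(f_h))   # (N,C,H,1)
        g_w = ag.sigmoid(self.conv_w(f_w))   # (N,C,1,W)
        return x * g_h * g_w


class SPPCSP(Module):
    """CSP spatial-pyramid-pooling block; reduces channels c1 -> c2.

    Pyramid kernels {5, 9, 13} are realized as three cascaded stride-1 5x5
    max-pools (window composition: 5, 9, 13).
    """

    def __init__(self, c1: int, c2: int):
        super().__init__()
        self.cv1 = CBS(c1, c2, 1, 1)
        self.cv3 = CBS(c2, c2, 3, 1)
        self.cv4 = CBS(c2, c2, 1, 1)
        self.cv5 = CBS(4 * c2, c2, 1, 1)
        self.cv6 = CBS(c2, c2, 3, 1)
        self.cv2 = CBS(c1, c2, 1, 1)
        self.cv7 = CBS(2 * c2, c2, 1, 1)
        self.in_channels, self.out_channels = c1, c2

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"SPPCSP expects {self.in_channels} channels, got {x.shape[1]}"
            )
        y = self.cv4(self.cv3(self.cv1(x)))
        p5 = ag.maxpool2d(y, 5, 1, 2)
        p9 = ag.maxpool2d(p5, 5, 1, 2)
        p13 = ag.maxpool2d(p9, 5, 1, 2)
        y = self.cv6(self.cv5(ag.cat([y, p5, p9, p13], axis=1)))
        return self.cv7(ag.cat([y, self.cv2(x)], axis=1))


class RepC(Module):
    """Re-parameterizable 3x3 conv (RepVGG-style) with SiLU activation.

    Training topology: 3x3 conv + BN, 1x1 conv + BN, and (iff the channel
    count is preserved) a BN identity branch, summed.  :meth:`fuse` collapses
    the branches into a single biased 3x3 convolution computing the identical
    function.
    """

    def __init__(self, c1: int, c2: int, stride: int = 1, deploy: bool = False):
        super().__init__()
        self.c1, self.c2, self.stride = c1, c2, stride
        self.deploy = deploy
        if deploy:
            self.fused = Conv2d(c1, c2, 3, stride=stride, bias=True)
        else:
            self.dense = Conv2d(c1, c2, 3, stride=stride)
            self.dense_bn = BatchNorm2d(c2)
            self.one = Conv2d(c1, c2, 1, stride=stride)
            self.one_bn = BatchNorm2d(c2)
            self.id_bn = BatchNorm2d(c2) if (c1 == c2 and stride == 1) else None

    def forward(self, x: Tensor) -> Tensor:
        if self.deploy:
            return ag.silu(self.fused(x))
        y = self.dense_bn(self.dense(x)) + self.one_bn(self.one(x))
        if self.id_bn is not None:
            y = y + self.id_bn(x)
        return ag.silu(y)

    @staticmethod
    def _fuse_conv_bn(w: np.ndarray, bn: BatchNorm2d) -> tuple[np.ndarray, np.ndarray]:
        std = np.sqrt(bn.running_var.data + bn.eps)
        scale = bn.gamma.data / std
        return w * scale[:, None, None, None], bn.beta.data - bn.running_mean.data * scale

    def fuse(self) -> "RepC":
        """Collapse branches into one 3x3 conv; uses BN running statistics."""
        if self.deploy:
            raise RuntimeError("RepC is already fused")
        bns = [self.dense_bn, self.one_bn] + ([self.id_bn] if self.id_bn else [])
        if all(bn.num_batches.data[0] == 0 for bn in bns):
            raise RuntimeError(
                "RepC fusion requested before batch-norm statistics exist "
                "(no training batch has been seen)"
            )
        w3, b3 = self._fuse_conv_bn(self.dense.weight.data, self.dense_bn)
        w1, b1 = self._fuse_conv_bn(self.one.weight.data, self.one_bn)
        w1_padded = np.zeros_like(w3)
        w1_padded[:, :, 1:2, 1:2] = w1
        w, b = w3 + w1_padded, b3 + b1
        if self.id_bn is not None:
            ident = np.zeros_like(w3)
            for i in range(self.c2):
                ident[i, i, 1, 1] = 1.0
            wi, bi = self._fuse_conv_bn(ident, self.id_bn)
            w, b = w + wi, b + bi
        self.fused = Conv2d(self.c1, self.c2, 3, stride=self.stride, bias=True)
        self.fused.weight.data = w.astype(np.float32)
        self.fused.bias.data = b.astype(np.float32)
        for attr in ("dense", "dense_bn", "one", "one_bn", "id_bn"):
            if hasattr(self, attr):
                delattr(self, attr)
        self.deploy = True
        return self


# -- functional wrappers matching the operation-level interface ---------------
def cbs_forward(x: Tensor, block: CBS) -> Tensor:
    return block(x)


def cot_block_forward(x: Tensor, block: CoTBlock) -> Tensor:
    return block(x)


def coordatt_forward(x: Tensor, block: CoordAtt) -> Tensor:
    return block(x)
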