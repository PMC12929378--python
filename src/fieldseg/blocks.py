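"""Building blocks of the improved segmentation network.

* :func:`channel_shuffle` — deterministic group-interleaving permutation.
* :class:`RepConv` — train-time multi-branch (3×3 + 1×1 + identity, each
  batch-normalized) convolution that fuses into a single 3×3 kernel + bias
  for inference (structural reparameterization).
* :class:`RCSOSA` — stacked reparameterized-convolution channel-shuffle
  (RCS) units with one-shot aggregation of intermediate outputs.
* :class:`SEAM` — spatially enhanced attention: depthwise/pointwise residual
  path re-weighted by exponential channel attention from a two-layer fully
  connected map on globally pooled features.
* :class:`IRMB` — inverted residual mobile block: 1×1 expansion, windowed
  multi-head self-attention, 3×3 depthwise convolution, 1×1 projection.
* :class:`ADown` — dual-branch adaptive downsampling (average-pool front end,
  channel split, conv branch + max-pool/1×1 branch).
* :func:`downsample_cost` — analytic parameter/MAC accounting showing the
  3.6× cost advantage of ADown over a plain stride-2 3×3 convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvBnAct,
    Linear,
    Module,
    Tensor,
    concat,
    conv2d,
    matmul,
    maxpool2d,
)

__all__ = [
    "BlockConfig",
    "CostReport",
    "channel_shuffle",
    "shuffle_permutation",
    "RepConv",
    "RCSOSA",
    "SEAM",
    "IRMB",
    "ADown",
    "downsample_cost",
]


@dataclass
class BlockConfig:
    """Plumbing configuration shared by the blocks."""

    in_channels: int
    out_channels: int
    n_repeats: int = 1
    expansion: float = 2.0
    heads: int = 4
    shuffle_groups: int = 2
    window: int = 7
    stride: int = 1


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channel groups: reshape to (g, C/g), transpose, flatten.

    Values are untouched; only the channel order changes.  ``groups`` must
    divide the channel count.
    """
    B, C, H, W = x.shape
    if C % groups:
        raise ValueError(f"channels ({C}) not divisible by groups ({groups})")
    if groups == 1:
        return x
    return (
        x.reshape(B, groups, C // groups, H, W)
        .transpose(0, 2, 1, 3, 4)
        .reshape(B, C, H, W)
    )


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Index map p with shuffled[:, i] = x[:, p[i]]."""
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


class RepConv(Module):
    """Reparameterizable convolution.

    Training mode sums three normalized branches: a 3×3 convolution, a 1×1
    convolution (receptive field zero-padded to 3×3 on fusion) and — when the
    channel counts match and stride is 1 — a batch-normalized identity.
    :meth:`fuse` folds the normalization statistics into a single 3×3
    kernel + bias; in inference (eval) mode the fused forward reproduces the
    branched forward to well below 1e-4.  No activation is applied here; the
    consuming block decides.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.conv3 = Conv2d(in_ch, out_ch, 3, stride, 1, bias=False, rng=rng, dtype=dtype)
        self.bn3 = BatchNorm2d(out_ch, dtype=dtype)
        self.conv1 = Conv2d(in_ch, out_ch, 1, stride, 0, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_ch, dtype=dtype)
        self.has_identity = in_ch == out_ch and stride == 1
        if self.has_identity:
            self.bnid = BatchNorm2d(out_ch, dtype=dtype)
        self.fused_weight: np.ndarray | None = None
        self.fused_bias: np.ndarray | None = None
        self.deploy = False

    # -- fusion ------------------------------------------------------------
    @staticmethod
    def _fold_bn(weight: np.ndarray, bn: BatchNorm2d) -> tuple[np.ndarray, np.ndarray]:
        scale = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
        w = weight * scale[:, None, None, None]
        b = bn.beta.data - bn.running_mean * scale
        return w, b

    def fuse(self) -> "RepConv":
        """Collapse the branches into a single 3×3 kernel + bias (idempotent)."""
        dtype = self.conv3.weight.data.dtype
        w3, b3 = self._fold_bn(self.conv3.weight.data, self.bn3)
        w1, b1 = self._fold_bn(self.conv1.weight.data, self.bn1)
        w1_33 = np.zeros_like(w3)
        w1_33[:, :, 1:2, 1:2] = w1
        w = w3 + w1_33
        b = b3 + b1
        if self.has_identity:
            ident = np.zeros_like(w3)
            for c in range(self.out_ch):
                ident[c, c, 1, 1] = 1.0
            wi, bi = self._fold_bn(ident, self.bnid)
            w = w + wi
            b = b + bi
        self.fused_weight = w.astype(dtype)
        self.fused_bias = b.astype(dtype)
        self.deploy = True
        return self

    def unfuse(self) -> "RepConv":
        self.deploy = False
        return self

    def forward(self, x: Tensor) -> Tensor:
        if self.deploy:
            if self.fused_weight is None:
                raise RuntimeError("deploy mode requested before fuse()")
            return conv2d(x, Tensor(self.fused_weight), Tensor(self.fused_bias),
                          self.stride, 1)
        y = self.bn3(self.conv3(x)) + self.bn1(self.conv1(x))
        if self.has_identity:
            y = y + self.bnid(x)
        return y


class _RCSUnit(Module):
    """Split channels in half, transform one half by RepConv+SiLU,
    concatenate, shuffle."""

    def __init__(self, ch: int, shuffle_groups: int, rng, dtype):
        super().__init__()
        if ch % 2:
            raise ValueError(f"RCS unit needs an even channel count, got {ch}")
        self.ch = ch
        self.groups = shuffle_groups
        self.rep = RepConv(ch // 2, ch // 2, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        half = self.ch // 2
        x1, x2 = x[:, :half], x[:, half:]
        y = concat([x1, self.rep(x2).silu()], axis=1)
        return channel_shuffle(y, self.groups)


class RCSOSA(Module):
    """Stack of RCS units with one-shot aggregation.

    The ``n_repeats`` unit outputs are concatenated once and projected to
    ``out_channels`` by a 1×1 convolution; spatial size is preserved.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        n_repeats: int = 1,
        shuffle_groups: int = 2,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if in_ch % 2:
            raise ValueError(f"RCSOSA requires an even in_channels, got {in_ch}")
        self.units = [
            _RCSUnit(in_ch, shuffle_groups, rng, dtype) for _ in range(n_repeats)
        ]
        for i, u in enumerate(self.units):
            setattr(self, f"unit{i}", u)
        self.proj = ConvBnAct(in_ch * n_repeats, out_ch, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        outs = []
        h = x
        for u in self.units:
            h = u(h)
            outs.append(h)
        agg = outs[0] if len(outs) == 1 else concat(outs, axis=1)
        return self.proj(agg)


class SEAM(Module):
    """Spatially enhanced attention module.

    A depthwise 3×3 + pointwise 1×1 residual path captures local spatial
    structure; global average pooling of that path feeds a two-layer fully
    connected map whose exponential output re-weights the channels.  Output
    shape equals input shape and the channel weights are strictly positive.
    """

    def __init__(
        self,
        ch: int,
        reduction: int = 4,
        gate: str = "exp",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if gate not in ("exp", "sigmoid"):
            raise ValueError(f"unknown gate {gate!r}")
        self.gate = gate
        self.dw = ConvBnAct(ch, ch, 3, groups=ch, rng=rng, dtype=dtype)
        self.pw = ConvBnAct(ch, ch, 1, act=False, rng=rng, dtype=dtype)
        hidden = max(ch // reduction, 4)
        self.fc1 = Linear(ch, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, ch, rng=rng, dtype=dtype)
        # start at a unit gate; the exponential is clipped to keep the
        # re-weighting bounded (exp is otherwise a runaway feedback loop)
        self.fc2.weight.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        y = self.pw(self.dw(x)) + x  # residual path
        pooled = y.mean(axis=(2, 3))  # (B, C)
        z = self.fc2(self.fc1(pooled).relu()).clip(-4.0, 4.0)
        w = z.exp() if self.gate == "exp" else z.sigmoid()
        B, C = w.shape
        return y * w.reshape(B, C, 1, 1)


class _WindowAttention(Module):
    """Multi-head self-attention over non-overlapping spatial windows."""

    def __init__(self, ch: int, heads: int, window: int, rng, dtype):
        super().__init__()
        if ch % heads:
            raise ValueError(f"channels ({ch}) not divisible by heads ({heads})")
        self.ch, self.heads, self.window = ch, heads, window
        self.qkv = Conv2d(ch, 3 * ch, 1, bias=True, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        win = min(self.window, H, W)
        ph = (-H) % win
        pw = (-W) % win
        xp = x
        if ph:  # pad bottom/right, crop afterwards
            xp = concat([xp, Tensor(np.zeros((B, C, ph, W), dtype=x.data.dtype))], axis=2)
        if pw:
            xp = concat([xp, Tensor(np.zeros((B, C, H + ph, pw), dtype=x.data.dtype))], axis=3)
        Hp, Wp = H + ph, W + pw
        qkv = self.qkv(xp)  # (B, 3C, Hp, Wp)
        nh, nw = Hp // win, Wp // win
        d = C // self.heads
        t = (
            qkv.reshape(B, 3, self.heads, d, nh, win, nw, win)
            .transpose(1, 0, 4, 6, 2, 5, 7, 3)  # (3, B, nh, nw, heads, win, win, d)
            .reshape(3, B * nh * nw, self.heads, win * win, d)
        )
        q, k, v = t[0], t[1], t[2]
        att = matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        att = att.softmax(axis=-1)
        out = matmul(att, v)  # (B*nh*nw, heads, T, d)
        out = (
            out.reshape(B, nh, nw, self.heads, win, win, d)
            .transpose(0, 3, 6, 1, 4, 2, 5)  # (B, heads, d, nh, win, nw, win)
            .reshape(B, C, Hp, Wp)
        )
        if ph or pw:
            out = out[:, :, :H, :W]
        return out


class IRMB(Module):
    """Inverted residual mobile block with windowed self-attention.

    1×1 expansion → windowed multi-head self-attention over spatial tokens →
    3×3 depthwise convolution (carries the stride) → 1×1 projection.  A
    residual connection is added when stride is 1 and the channel counts
    match.  Spatial dims not divisible by the window are padded and cropped.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        expansion: float = 2.0,
        heads: int = 4,
        window: int = 7,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = int(round(in_ch * expansion))
        hidden = max(heads, (hidden // heads) * heads)  # divisible by heads
        self.expand = ConvBnAct(in_ch, hidden, 1, rng=rng, dtype=dtype)
        self.attn = _WindowAttention(hidden, heads, window, rng, dtype)
        self.dw = ConvBnAct(hidden, hidden, 3, stride=stride, groups=hidden, rng=rng, dtype=dtype)
        self.proj = ConvBnAct(hidden, out_ch, 1, act=False, rng=rng, dtype=dtype)
        self.residual = stride == 1 and in_ch == out_ch

    def forward(self, x: Tensor) -> Tensor:
        h = self.expand(x)
        h = h + self.attn(h)
        h = self.dw(h)
        h = self.proj(h)
        if self.residual:
            h = h + x
        return h


def _avgpool2x2_s1(x: Tensor) -> Tensor:
    """2×2 average pooling, stride 1, no padding (H, W shrink by one)."""
    return (
        x[:, :, :-1, :-1] + x[:, :, 1:, :-1] + x[:, :, :-1, 1:] + x[:, :, 1:, 1:]
    ) * 0.25


class ADown(Module):
    """Dual-branch adaptive downsampling.

    A 2×2 stride-1 average pool smooths the map, the channels are split into
    halves; one half passes through a 3×3 stride-2 convolution, the other
    through a 3×3 stride-2 pad-1 max pool followed by a 1×1 convolution.  The
    two halves concatenate to ``out_channels`` at half spatial resolution.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if in_ch % 2 or out_ch % 2:
            raise ValueError(f"ADown needs even channel counts, got {in_ch}->{out_ch}")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.cv_conv = ConvBnAct(in_ch // 2, out_ch // 2, 3, stride=2, padding=1, rng=rng, dtype=dtype)
        self.cv_pool = ConvBnAct(in_ch // 2, out_ch // 2, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H < 2 or W < 2:
            raise ValueError("ADown needs spatial dims >= 2")
        x = _avgpool2x2_s1(x)
        half = C // 2
        x1, x2 = x[:, :half], x[:, half:]
        a = self.cv_conv(x1)
        b = self.cv_pool(maxpool2d(x2, 3, 2, 1))
        return concat([a, b], axis=1)


@dataclass
class CostReport:
    """Analytic cost of stride-2 downsampling: plain 3×3 conv vs. ADown.

    Parameters in absolute weight counts, complexity in multiply-accumulates
    (pooling and activations excluded).  For a c→c contract the conv costs
    9c² parameters and (9/4)c²hw MACs; ADown costs (5/2)c² and (5/8)c²hw,
    a 18/5 = 3.6× saving in both.
    """

    channels: int
    height: int
    width: int
    params_conv: float
    params_adown: float
    flops_conv: float
    flops_adown: float
    ratio_params: float = field(init=False)
    ratio_flops: float = field(init=False)

    def __post_init__(self) -> None:
        self.ratio_params = self.params_conv / self.params_adown
        self.ratio_flops = self.flops_conv / self.flops_adown


def downsample_cost(c: int, h: int, w: int) -> CostReport:
    """Cost report for a c→c stride-2 downsample on an h×w map.

    Plain path: one 3×3 stride-2 convolution, c→c: 9c² weights, each output
    pixel (h/2 · w/2 of them) costing 9c² MACs per... i.e. (9/4)c²hw total.
    ADown path: 3×3 conv on half the channels to half the outputs
    (9c²/4 weights, (9/16)c²hw MACs) plus a 1×1 conv on the other half
    (c²/4 weights, (1/16)c²hw MACs); pooling is MAC-free.
    """
    if c % 2:
        raise ValueError("channel count must be even")
    if h <= 0 or w <= 0:
        raise ValueError("spatial dims must be positive")
    params_conv = 9.0 * c * c
    params_adown = 9.0 * (c / 2) ** 2 + (c / 2) ** 2
    flops_conv = 9.0 * c * c * (h / 2) * (w / 2)
    flops_adown = 9.0 * (c / 2) ** 2 * (h / 2) * (w / 2) + (c / 2) ** 2 * (h / 2) * (w / 2)
    return CostReport(c, h, w, params_conv, params_adown, flops_conv, flops_adown)
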