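"""Assembly of the improved YOLO-style segmentation network.

The topology follows the YOLO11-seg layout — a CSP backbone ending in SPPF
and a post-SPPF attention block (C2PSA), a PAN-style neck, and a decoupled
anchor-free segmentation head with a mask-prototype branch — with four
switchable replacements:

* ``use_rcsosa`` — every C3k2 position (backbone and neck) holds an
  :class:`~fieldseg.blocks.RCSOSA` block instead.
* ``use_seam``   — a :class:`~fieldseg.blocks.SEAM` unit is inserted in the
  attention branch of the C2PSA block.
* ``use_irmb``   — one :class:`~fieldseg.blocks.IRMB` precedes the
  mask-prototype branch.
* ``use_adown``  — the backbone stage-transition downsamples (P2→P3, P3→P4,
  P4→P5) and the two neck top-down-return downsamples are
  :class:`~fieldseg.blocks.ADown` instead of strided 3×3 convolutions.

Scales ``n`` and ``s`` follow the published YOLO11 width/depth multipliers
(0.25/0.50 and 0.50/0.50).  Layer widths were calibrated once so the
all-modules s-scale network lands near 8.3 M parameters / 25 GFLOPs at
480×480 while staying a YOLO11-seg-shaped graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .blocks import ADown, IRMB, RCSOSA, RepConv, SEAM, _WindowAttention
from .nn import (
    ConvBnAct,
    Conv2d,
    Module,
    Tensor,
    concat,
    flop_counter,
    maxpool2d,
    upsample_nearest,
)

__all__ = ["ModelConfig", "ModelOutputs", "SegModel", "build_model",
           "count_parameters", "count_flops", "ablation_variant"]

_SCALES = {
    # (depth_mult, width_mult, max_channels)
    "n": (0.50, 0.25, 1024),
    "s": (0.50, 0.50, 768),
}


@dataclass
class ModelConfig:
    scale: str = "s"
    num_classes: int = 1
    input_size: int = 480
    use_rcsosa: bool = True
    use_seam: bool = True
    use_irmb: bool = True
    use_adown: bool = True
    reg_max: int = 16
    n_protos: int = 32
    shuffle_groups: int = 2
    irmb_expansion: float = 2.0
    irmb_heads: int = 4
    irmb_window: int = 7
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; choose from {sorted(_SCALES)}")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    @property
    def toggles(self) -> tuple[bool, bool, bool, bool]:
        return (self.use_rcsosa, self.use_seam, self.use_irmb, self.use_adown)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type


def ablation_variant(toggles, scale: str = "s", **kw) -> ModelConfig:
    """Config for one row of the four-module ablation grid.

    ``toggles`` is (use_rcsosa, use_seam, use_irmb, use_adown); all off is
    the structural baseline, all on is the full model.
    """
    r, s, i, a = (bool(t) for t in toggles)
    return ModelConfig(scale=scale, use_rcsosa=r, use_seam=s, use_irmb=i, use_adown=a, **kw)


def _make_divisible(v: float, d: int = 8) -> int:
    return max(d, int(round(v / d) * d))


@dataclass
class ModelOutputs:
    """Raw multi-scale head outputs.

    ``box``/``cls``/``coef`` are per-level lists at strides 8/16/32; ``box``
    carries 4·reg_max distribution-focal logits, ``cls`` class logits and
    ``coef`` mask-prototype coefficients.  ``protos`` is the shared prototype
    bank at stride 4.
    """

    box: list
    cls: list
    coef: list
    protos: Tensor
    strides: tuple = (8, 16, 32)


class _Bottleneck(Module):
    def __init__(self, ch: int, shortcut: bool, rng, dtype, e: float = 0.5):
        super().__init__()
        hidden = max(4, int(ch * e))
        self.cv1 = ConvBnAct(ch, hidden, 3, rng=rng, dtype=dtype)
        self.cv2 = ConvBnAct(hidden, ch, 3, rng=rng, dtype=dtype)
        self.add = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k2(Module):
    """CSP block with two partial stages (the YOLO11 C3k2 baseline)."""

    def __init__(self, in_ch: int, out_ch: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c = max(4, int(out_ch * e))
        self.cv1 = ConvBnAct(in_ch, 2 * self.c, 1, rng=rng, dtype=dtype)
        blocks = []
        for _ in range(n):
            if c3k:
                blocks.append((_Bottleneck(self.c, True, rng, dtype),
                               _Bottleneck(self.c, True, rng, dtype)))
            else:
                blocks.append((_Bottleneck(self.c, True, rng, dtype),))
        self.blocks = blocks
        for i, pair in enumerate(blocks):
            for j, b in enumerate(pair):
                setattr(self, f"b{i}_{j}", b)
        self.cv2 = ConvBnAct((2 + n) * self.c, out_ch, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, : self.c], y[:, self.c :]
        outs = [a, b]
        h = b
        for pair in self.blocks:
            for blk in pair:
                h = blk(h)
            outs.append(h)
        return self.cv2(concat(outs, axis=1))


class SPPF(Module):
    def __init__(self, ch: int, k: int = 5, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.cv1 = ConvBnAct(ch, ch // 2, 1, rng=rng, dtype=dtype)
        self.cv2 = ConvBnAct(2 * ch, ch, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        y = self.cv1(x)
        p1 = maxpool2d(y, self.k, 1, self.k // 2)
        p2 = maxpool2d(p1, self.k, 1, self.k // 2)
        p3 = maxpool2d(p2, self.k, 1, self.k // 2)
        return self.cv2(concat([y, p1, p2, p3], axis=1))


class _PSABlock(Module):
    """Attention + FFN residual unit; hosts SEAM when enabled."""

    def __init__(self, ch: int, use_seam: bool, cfg: ModelConfig, rng, dtype):
        super().__init__()
        heads = max(1, ch // 64)
        self.attn = _WindowAttention(ch, heads, cfg.irmb_window, rng, dtype)
        self.use_seam = use_seam
        if use_seam:
            self.seam = SEAM(ch, rng=rng, dtype=dtype)
        self.ffn1 = ConvBnAct(ch, 2 * ch, 1, rng=rng, dtype=dtype)
        self.ffn2 = ConvBnAct(2 * ch, ch, 1, act=False, rng=rng, dtype=dtype)

    def forward(self, x):
        a = self.attn(x)
        if self.use_seam:
            a = self.seam(a)
        x = x + a
        return x + self.ffn2(self.ffn1(x))


class C2PSA(Module):
    def __init__(self, ch: int, use_seam: bool, cfg: ModelConfig, rng, dtype):
        super().__init__()
        self.c = ch // 2
        self.cv1 = ConvBnAct(ch, 2 * self.c, 1, rng=rng, dtype=dtype)
        self.psa = _PSABlock(self.c, use_seam, cfg, rng, dtype)
        self.cv2 = ConvBnAct(2 * self.c, ch, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, : self.c], y[:, self.c :]
        b = self.psa(b)
        return self.cv2(concat([a, b], axis=1))


class Proto(Module):
    """Mask prototype branch at stride 4."""

    def __init__(self, in_ch: int, mid_ch: int, k: int, rng, dtype):
        super().__init__()
        self.cv1 = ConvBnAct(in_ch, mid_ch, 3, rng=rng, dtype=dtype)
        self.cv2 = ConvBnAct(mid_ch, mid_ch, 3, rng=rng, dtype=dtype)
        self.cv3 = Conv2d(mid_ch, k, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        y = upsample_nearest(self.cv1(x), 2)
        return self.cv3(self.cv2(y))


class _HeadBranch(Module):
    def __init__(self, in_ch: int, hidden: int, out_ch: int, rng, dtype,
                 bias_init: float = 0.0):
        super().__init__()
        self.cv1 = ConvBnAct(in_ch, hidden, 3, rng=rng, dtype=dtype)
        self.cv2 = ConvBnAct(hidden, hidden, 3, rng=rng, dtype=dtype)
        self.out = Conv2d(hidden, out_ch, 1, rng=rng, dtype=dtype)
        self.out.bias.data[...] = bias_init

    def forward(self, x):
        return self.out(self.cv2(self.cv1(x)))


class SegModel(Module):
    """The assembled backbone + neck + segmentation head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dtype = cfg.np_dtype
        depth, width, max_ch = _SCALES[cfg.scale]

        def ch(c: int) -> int:
            return _make_divisible(min(c, max_ch) * width, 8)

        def reps(n: int) -> int:
            return max(1, int(round(n * depth)))

        c1, c2, c3, c4, c5 = ch(64), ch(128), ch(256), ch(512), ch(1024)
        self.channels = (c1, c2, c3, c4, c5)
        n = reps(2)

        def stage_block(cin, cout, c3k):
            if cfg.use_rcsosa:
                return RCSOSA(cin, cout, n_repeats=n,
                              shuffle_groups=cfg.shuffle_groups, rng=rng, dtype=dtype)
            return C3k2(cin, cout, n=n, c3k=c3k,
                        e=0.25 if not c3k else 0.5, rng=rng, dtype=dtype)

        def down(cin, cout):
            if cfg.use_adown:
                return ADown(cin, cout, rng=rng, dtype=dtype)
            return ConvBnAct(cin, cout, 3, stride=2, rng=rng, dtype=dtype)

        # backbone
        self.stem1 = ConvBnAct(3, c1, 3, stride=2, rng=rng, dtype=dtype)   # P1
        self.stem2 = ConvBnAct(c1, c2, 3, stride=2, rng=rng, dtype=dtype)  # P2
        self.b2 = stage_block(c2, c3, False)
        self.down3 = down(c3, c3)                                          # P3
        self.b3 = stage_block(c3, c4, False)
        self.down4 = down(c4, c4)                                          # P4
        self.b4 = stage_block(c4, c4, True)
        self.down5 = down(c4, c5)                                          # P5
        self.b5 = stage_block(c5, c5, True)
        self.sppf = SPPF(c5, 5, rng=rng, dtype=dtype)
        self.c2psa = C2PSA(c5, cfg.use_seam, cfg, rng, dtype)

        # neck (PAN)
        self.n1 = stage_block(c5 + c4, c4, False)   # after upsample to P4
        self.n2 = stage_block(c4 + c4, c3, False)   # after upsample to P3
        self.nd3 = down(c3, c3)
        self.n3 = stage_block(c3 + c4, c4, False)   # P4 out
        self.nd4 = down(c4, c4)
        self.n4 = stage_block(c4 + c5, c5, True)    # P5 out

        # segmentation head
        nc, k, rm = cfg.num_classes, cfg.n_protos, cfg.reg_max
        box_h = max(16, c3 // 4, rm)
        coef_h = max(c3 // 4, k)
        self.heads_box = []
        self.heads_cls = []
        self.heads_coef = []
        for i, ci in enumerate((c3, c4, c5)):
            hb = _HeadBranch(ci, box_h, 4 * rm, rng, dtype)
            hc = _HeadBranch(ci, c3, nc, rng, dtype, bias_init=-4.0)
            hm = _HeadBranch(ci, coef_h, k, rng, dtype)
            setattr(self, f"box{i}", hb)
            setattr(self, f"cls{i}", hc)
            setattr(self, f"coef{i}", hm)
            self.heads_box.append(hb)
            self.heads_cls.append(hc)
            self.heads_coef.append(hm)
        self.use_irmb = cfg.use_irmb
        if cfg.use_irmb:
            self.irmb = IRMB(c3, c3, expansion=cfg.irmb_expansion,
                             heads=cfg.irmb_heads, window=cfg.irmb_window,
                             rng=rng, dtype=dtype)
        self.proto = Proto(c3, max(k, c3), k, rng, dtype)

    # -- passes ------------------------------------------------------------
    def forward(self, x: Tensor) -> ModelOutputs:
        x = self.stem2(self.stem1(x))
        p3_in = self.b2(x)
        p3 = self.b3(self.down3(p3_in))          # stride 8 features
        p4 = self.b4(self.down4(p3))             # stride 16
        p5 = self.c2psa(self.sppf(self.b5(self.down5(p4))))  # stride 32

        u4 = concat([upsample_nearest(p5, 2), p4], axis=1)
        f4 = self.n1(u4)
        u3 = concat([upsample_nearest(f4, 2), p3], axis=1)
        f3 = self.n2(u3)                         # P3 out
        f4o = self.n3(concat([self.nd3(f3), f4], axis=1))
        f5o = self.n4(concat([self.nd4(f4o), p5], axis=1))

        feats = (f3, f4o, f5o)
        box = [h(f) for h, f in zip(self.heads_box, feats)]
        cls = [h(f) for h, f in zip(self.heads_cls, feats)]
        coef = [h(f) for h, f in zip(self.heads_coef, feats)]
        pin = self.irmb(f3) if self.use_irmb else f3
        protos = self.proto(pin)
        return ModelOutputs(box=box, cls=cls, coef=coef, protos=protos)

    def fuse(self) -> "SegModel":
        """Fuse every reparameterizable convolution for inference."""
        for m in self.modules():
            if isinstance(m, RepConv):
                m.fuse()
        return self

    def unfuse(self) -> "SegModel":
        for m in self.modules():
            if isinstance(m, RepConv):
                m.unfuse()
        return self

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def load(self, path) -> "SegModel":
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})
        return self


def build_model(cfg: ModelConfig) -> SegModel:
    return SegModel(cfg)


def count_parameters(model: SegModel) -> int:
    """Exact count of trainable scalars."""
    return model.num_parameters()


def count_flops(model: SegModel, input_size: int | None = None) -> int:
    """FLOPs of one forward pass at ``input_size`` (MACs × 2, conv/matmul
    only; pooling, normalization and activations excluded)."""
    size = input_size or model.cfg.input_size
    x = Tensor(np.zeros((1, 3, size, size), dtype=model.cfg.np_dtype))
    was_training = model.training
    model.eval()
    with flop_counter() as fc:
        model(x)
    flops = fc.flops
    if was_training:
        model.train()
    return flops
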