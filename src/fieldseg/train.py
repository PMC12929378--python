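"""Smoke-scale training and inference for the segmentation network.

The loss is the standard YOLO-seg composite: IoU box loss on boxes decoded
from distribution-focal (DFL) bins, binary cross-entropy on the class map,
DFL cross-entropy on the box-side distributions, and prototype-mask binary
cross-entropy cropped to the ground-truth box.  Target assignment is
center-based and anchor-free: each ground-truth instance claims the anchor
points of its size-matched pyramid level whose centres fall inside the box
and near its centre; conflicts resolve to the nearest instance.

``smoke_train`` is a deliberately small overfit harness: a few labelled
tiles, a few hundred SGD iterations, fixed seeds — enough to demonstrate
that the assembled architecture trains and can segment its own training
tiles, not a reproduction of full field-scale training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import GroundTruthInstance, InstancePrediction, evaluate_dataset
from .model import ModelOutputs, SegModel
from .nn import SGD, Tensor, matmul

__all__ = ["TrainProtocol", "smoke_train", "predict", "tiles_to_ground_truth"]

_STRIDES = (8, 16, 32)


def _np_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class TrainProtocol:
    """Optimisation protocol; defaults follow the YOLO convention of SGD
    with momentum at initial learning rate 0.01 (full-scale runs use batch
    16 for 300 epochs; the smoke harness caps iterations instead)."""

    iterations: int = 200
    batch_size: int = 4
    lr: float = 0.01
    momentum: float = 0.9
    warmup_iters: int = 20
    seed: int = 0
    w_box: float = 7.5
    w_cls: float = 0.5
    w_dfl: float = 1.5
    w_mask: float = 2.5


@dataclass
class TrainHistory:
    losses: list = field(default_factory=list)

    @property
    def first(self) -> float:
        return self.losses[0]

    @property
    def last(self) -> float:
        return self.losses[-1]


def _instances_from_label_map(label_map: np.ndarray):
    """(box, mask) per instance id present in a tile label map."""
    out = []
    for iid in np.unique(label_map):
        if iid == 0:
            continue
        mask = label_map == iid
        ys, xs = np.nonzero(mask)
        box = (float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))
        out.append((box, mask))
    return out


def tiles_to_ground_truth(tiles) -> list[list[GroundTruthInstance]]:
    """Per-tile GroundTruthInstance lists for the evaluator."""
    gts = []
    for t in tiles:
        gts.append([
            GroundTruthInstance(box=box, class_id=0, mask=mask)
            for box, mask in _instances_from_label_map(t.label_map)
        ])
    return gts


def _level_of(box, size: int) -> int:
    m = max(box[2] - box[0], box[3] - box[1])
    if m < size / 4:
        return 0
    if m < size / 2:
        return 1
    return 2


def _assign_targets(instances, size: int):
    """Positive anchors per instance: (level, i, j) triples."""
    grids = [size // s for s in _STRIDES]
    claims: dict[tuple, tuple] = {}  # (lvl,i,j) -> (dist, gt_idx)
    for gi, (box, _mask) in enumerate(instances):
        lvl = _level_of(box, size)
        s = _STRIDES[lvl]
        g = grids[lvl]
        cx, cy = (box[0] + box[2]) / 2, (box[1] + box[3]) / 2
        j0 = int(np.clip(np.floor(box[0] / s), 0, g - 1))
        j1 = int(np.clip(np.ceil(box[2] / s), 1, g))
        i0 = int(np.clip(np.floor(box[1] / s), 0, g - 1))
        i1 = int(np.clip(np.ceil(box[3] / s), 1, g))
        found = False
        for i in range(i0, i1):
            for j in range(j0, j1):
                ax, ay = (j + 0.5) * s, (i + 0.5) * s
                inside = box[0] <= ax <= box[2] and box[1] <= ay <= box[3]
                near = abs(ax - cx) <= 2.5 * s and abs(ay - cy) <= 2.5 * s
                if inside and near:
                    d = (ax - cx) ** 2 + (ay - cy) ** 2
                    key = (lvl, i, j)
                    if key not in claims or d < claims[key][0]:
                        claims[key] = (d, gi)
                        found = True
        if not found:  # sub-stride instance: closest anchor wins unconditionally
            j = int(np.clip(cx / s, 0, g - 1))
            i = int(np.clip(cy / s, 0, g - 1))
            claims[(lvl, i, j)] = (0.0, gi)
    return claims


def _bce_logits(z: Tensor, y) -> Tensor:
    """Numerically stable elementwise BCE-with-logits."""
    absz = z.relu() + (-z).relu()
    return z.relu() - z * y + (1.0 + (-absz).exp()).log()


def _emin(a: Tensor, b: Tensor) -> Tensor:
    return a - (a - b).relu()


def _emax(a: Tensor, b: Tensor) -> Tensor:
    return a + (b - a).relu()


def compute_loss(outputs: ModelOutputs, batch_instances, size: int,
                 protocol: TrainProtocol):
    """Composite detection+segmentation loss over one batch."""
    B = outputs.cls[0].shape[0]
    rm = outputs.box[0].shape[1] // 4
    proto_stride = size // outputs.protos.shape[-1]

    cls_loss = Tensor(np.zeros(()))
    n_pos_total = 0
    pos_by_level: dict[int, list] = {0: [], 1: [], 2: []}
    for b in range(B):
        claims = _assign_targets(batch_instances[b], size)
        for (lvl, i, j), (_d, gi) in claims.items():
            pos_by_level[lvl].append((b, i, j, gi))
            n_pos_total += 1
    n_pos = max(n_pos_total, 1)

    # classification: BCE over every anchor of every level
    for lvl in range(3):
        z = outputs.cls[lvl]  # (B, 1, g, g)
        y = np.zeros(z.shape, dtype=z.data.dtype)
        for b, i, j, _gi in pos_by_level[lvl]:
            y[b, 0, i, j] = 1.0
        cls_loss = cls_loss + _bce_logits(z, Tensor(y)).sum()
    cls_loss = cls_loss * (1.0 / n_pos)

    iou_loss = Tensor(np.zeros(()))
    dfl_loss = Tensor(np.zeros(()))
    mask_loss = Tensor(np.zeros(()))
    bins = np.arange(rm, dtype=np.float64)
    for lvl in range(3):
        pos = pos_by_level[lvl]
        if not pos:
            continue
        s = _STRIDES[lvl]
        bs = np.array([p[0] for p in pos])
        is_ = np.array([p[1] for p in pos])
        js = np.array([p[2] for p in pos])
        boxes = np.array([batch_instances[b][gi][0] for b, _i, _j, gi in
                          ((p[0], p[1], p[2], p[3]) for p in pos)])
        ax = (js + 0.5) * s
        ay = (is_ + 0.5) * s
        # target side distances in stride units, clipped to the DFL support
        t = np.stack([
            (ax - boxes[:, 0]) / s, (ay - boxes[:, 1]) / s,
            (boxes[:, 2] - ax) / s, (boxes[:, 3] - ay) / s,
        ], axis=1)
        t = np.clip(t, 0.0, rm - 1 - 1e-3)

        zb = outputs.box[lvl][bs, :, is_, js].reshape(len(pos), 4, rm)
        logits = zb.softmax(axis=-1)
        d = (logits * Tensor(bins.astype(zb.data.dtype))).sum(axis=-1)  # (N,4)
        # decoded box vs target box IoU
        px1 = Tensor(ax) - d[:, 0] * s
        py1 = Tensor(ay) - d[:, 1] * s
        px2 = Tensor(ax) + d[:, 2] * s
        py2 = Tensor(ay) + d[:, 3] * s
        gx1, gy1, gx2, gy2 = (Tensor(boxes[:, k]) for k in range(4))
        iw = (_emin(px2, gx2) - _emax(px1, gx1)).relu()
        ih = (_emin(py2, gy2) - _emax(py1, gy1)).relu()
        inter = iw * ih
        area_p = (px2 - px1).relu() * (py2 - py1).relu()
        area_g = (gx2 - gx1) * (gy2 - gy1)
        iou = inter / (area_p + area_g - inter + 1e-7)
        iou_loss = iou_loss + (1.0 - iou).sum()

        # distribution focal loss on the two neighbouring bins
        lo = np.floor(t).astype(int)
        hi = lo + 1
        frac = t - lo
        logp = zb - Tensor(zb.max_const(axis=-1)) \
            - ((zb - Tensor(zb.max_const(axis=-1))).exp().sum(axis=-1, keepdims=True)).log()
        oh_lo = np.eye(rm, dtype=zb.data.dtype)[lo]
        oh_hi = np.eye(rm, dtype=zb.data.dtype)[np.minimum(hi, rm - 1)]
        dfl = -((logp * Tensor(oh_lo)).sum(axis=-1) * Tensor((1 - frac).astype(zb.data.dtype))
                + (logp * Tensor(oh_hi)).sum(axis=-1) * Tensor(frac.astype(zb.data.dtype)))
        dfl_loss = dfl_loss + dfl.sum()

        # prototype mask loss, cropped to the (slightly padded) gt box
        ph = outputs.protos.shape[-2]
        pw = outputs.protos.shape[-1]
        k = outputs.protos.shape[1]
        for b in np.unique(bs):
            sel = np.nonzero(bs == b)[0]
            coefs = outputs.coef[lvl][np.full(len(sel), b), :, is_[sel], js[sel]]  # (n, k)
            protos_b = outputs.protos[int(b)].reshape(k, ph * pw)
            mlogits = matmul(coefs, protos_b)  # (n, ph*pw)
            targets = np.zeros((len(sel), ph * pw), dtype=mlogits.data.dtype)
            weights = np.zeros_like(targets)
            for row, pi in enumerate(sel):
                _b, _i, _j, gi = pos[pi]
                box, mask = batch_instances[b][gi]
                small = mask.reshape(ph, proto_stride, pw, proto_stride).mean(axis=(1, 3))
                targets[row] = small.ravel()
                x0 = int(np.clip(box[0] / proto_stride - 1, 0, pw))
                x1 = int(np.clip(np.ceil(box[2] / proto_stride) + 1, 0, pw))
                y0 = int(np.clip(box[1] / proto_stride - 1, 0, ph))
                y1 = int(np.clip(np.ceil(box[3] / proto_stride) + 1, 0, ph))
                wmask = np.zeros((ph, pw))
                wmask[y0:y1, x0:x1] = 1.0 / max((y1 - y0) * (x1 - x0), 1)
                weights[row] = wmask.ravel()
            mask_loss = mask_loss + (_bce_logits(mlogits, Tensor(targets)) * Tensor(weights)).sum()

    iou_loss = iou_loss * (1.0 / n_pos)
    dfl_loss = dfl_loss * (1.0 / (4 * n_pos))
    mask_loss = mask_loss * (1.0 / n_pos)
    total = (protocol.w_box * iou_loss + protocol.w_cls * cls_loss
             + protocol.w_dfl * dfl_loss + protocol.w_mask * mask_loss)
    parts = {
        "box": float(iou_loss.data), "cls": float(cls_loss.data),
        "dfl": float(dfl_loss.data), "mask": float(mask_loss.data),
    }
    return total, parts


def _prepare_image(img: np.ndarray, dtype) -> np.ndarray:
    return (img.astype(dtype) / 255.0).transpose(2, 0, 1)


def smoke_train(model: SegModel, tiles, protocol: TrainProtocol | None = None) -> TrainHistory:
    """Overfit the model to a handful of labelled tiles.

    Requires at least 4 tiles, each with at least one weed instance;
    background-only datasets are rejected.  Aborts on non-finite loss.
    """
    protocol = protocol or TrainProtocol()
    if len(tiles) < 4:
        raise ValueError("smoke training needs at least 4 labelled tiles")
    data = []
    size = None
    for t in tiles:
        inst = _instances_from_label_map(t.label_map)
        if not inst:
            raise ValueError("smoke training requires weed instances in every tile; "
                             "filter negative tiles first")
        if size is None:
            size = t.label_map.shape[0]
        data.append((_prepare_image(t.image, model.cfg.np_dtype), inst))
    rng = np.random.default_rng(protocol.seed)
    opt = SGD(model.parameters(), lr=protocol.lr, momentum=protocol.momentum)
    model.train()
    history = TrainHistory()
    for it in range(protocol.iterations):
        opt.lr = protocol.lr * min(1.0, (it + 1) / max(protocol.warmup_iters, 1))
        idx = rng.choice(len(data), size=min(protocol.batch_size, len(data)), replace=False)
        imgs = np.stack([data[i][0] for i in idx])
        insts = [data[i][1] for i in idx]
        out = model(Tensor(imgs))
        loss, parts = compute_loss(out, insts, size, protocol)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"training diverged at iteration {it}: {parts}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.losses.append(float(loss.data))
    model.eval()
    return history


def _nms(boxes: np.ndarray, scores: np.ndarray, thr: float) -> list[int]:
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        xx1 = np.maximum(boxes[i, 0], boxes[rest, 0])
        yy1 = np.maximum(boxes[i, 1], boxes[rest, 1])
        xx2 = np.minimum(boxes[i, 2], boxes[rest, 2])
        yy2 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.maximum(xx2 - xx1, 0) * np.maximum(yy2 - yy1, 0)
        a = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        b = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        iou = inter / np.maximum(a + b - inter, 1e-9)
        order = rest[iou <= thr]
    return keep


def predict(model: SegModel, images, conf: float = 0.25, nms_iou: float = 0.6,
            max_det: int = 300, mask_thr: float = 0.5) -> list[list[InstancePrediction]]:
    """Run inference on HWC uint8 images; returns per-image instance lists."""
    model.eval()
    results = []
    rm = model.cfg.reg_max
    for img in images:
        size = img.shape[0]
        x = Tensor(_prepare_image(img, model.cfg.np_dtype)[None])
        out = model(x)
        proto_stride = size // out.protos.shape[-1]
        boxes, scores, coefs = [], [], []
        for lvl, s in enumerate(_STRIDES):
            g = out.cls[lvl].shape[-1]
            z = out.cls[lvl].data[0, 0]
            sc = _np_sigmoid(z)
            ii, jj = np.nonzero(sc >= conf)
            if len(ii) == 0:
                continue
            zb = out.box[lvl].data[0][:, ii, jj].reshape(4, rm, -1)
            zb = zb - zb.max(axis=1, keepdims=True)
            p = np.exp(zb)
            p /= p.sum(axis=1, keepdims=True)
            d = (p * np.arange(rm)[None, :, None]).sum(axis=1)  # (4, n)
            ax, ay = (jj + 0.5) * s, (ii + 0.5) * s
            bx = np.stack([ax - d[0] * s, ay - d[1] * s, ax + d[2] * s, ay + d[3] * s], axis=1)
            boxes.append(bx)
            scores.append(sc[ii, jj])
            coefs.append(out.coef[lvl].data[0][:, ii, jj].T)
        preds = []
        if boxes:
            boxes = np.concatenate(boxes)
            scores = np.concatenate(scores)
            coefs = np.concatenate(coefs)
            keep = _nms(boxes, scores, nms_iou)[:max_det]
            protos = out.protos.data[0].reshape(model.cfg.n_protos, -1)
            ph = pw = out.protos.shape[-1]
            for i in keep:
                b = np.clip(boxes[i], 0, size)
                if b[2] - b[0] < 1 or b[3] - b[1] < 1:
                    continue
                mlog = coefs[i] @ protos
                m = _np_sigmoid(mlog).reshape(ph, pw)
                m = m.repeat(proto_stride, 0).repeat(proto_stride, 1)
                mask = m >= mask_thr
                crop = np.zeros_like(mask)
                x0, y0, x1, y1 = (int(b[0]), int(b[1]),
                                  int(np.ceil(b[2])), int(np.ceil(b[3])))
                crop[y0:y1, x0:x1] = mask[y0:y1, x0:x1]
                if not crop.any():
                    continue
                preds.append(InstancePrediction(
                    box=tuple(b.tolist()), score=float(scores[i]),
                    class_id=0, mask=crop,
                ))
        results.append(preds)
    return results


def evaluate_on_tiles(model: SegModel, tiles, conf: float = 0.25) -> dict:
    """Box and mask P/R/mAP@0.5 of the model on a tile list."""
    preds = predict(model, [t.image for t in tiles], conf=conf)
    gts = tiles_to_ground_truth(tiles)
    return {
        "box": evaluate_dataset(preds, gts, kind="box"),
        "mask": evaluate_dataset(preds, gts, kind="mask"),
    }
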