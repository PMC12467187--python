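"""Desk-scale single-stage detector around the dual-perception head.

The scaffold is intentionally small: a strided-conv backbone, a top-down
sum feature pyramid (strides 8/16/32 by default) and a head — either the
dual-perception head or a plain two-conv baseline of equal channel width
for ablations. Anchor-free: each pyramid location predicts per-class
logits and distances to the four box sides (decoded as
``stride * exp(r)``).

Target assignment is deterministic: a ground truth belongs to the level
whose scale range covers its longer side (ranges end at ``8 * stride``,
the last is unbounded); every location inside the box on that level is
positive; a location claimed by several boxes goes to the smallest area
(ties to the lower box index); a box left without a location is given its
nearest free location on its level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .head import HeadOutputs, IDPHead, PlainHead
from .nn import AdamW, Conv2d, Module
from .synthdata import AnnotatedScene
from .types import ConfigError, Detection, GroundTruth, ShapeError

__all__ = [
    "DetectorConfig",
    "TrainSchedule",
    "Detector",
    "build_detector",
    "level_points",
    "assign_targets",
    "detection_loss",
    "LossBreakdown",
    "decode_and_nms",
    "nms",
    "train",
    "save_detector",
    "load_detector",
]


@dataclass
class DetectorConfig:
    num_classes: int = 4
    strides: tuple[int, ...] = (8, 16, 32)
    neck_channels: int = 24
    anchors_per_loc: int = 1
    backbone_widths: tuple[int, ...] = (8, 16, 24, 32, 48)
    in_channels: int = 1
    head_type: str = "idp"           # "idp" | "plain"
    kernel_size: int = 11
    dilation: int = 2
    activation: str = "sigmoid"
    heads: int = 4
    gn_groups: int | None = None
    score_threshold: float = 0.05
    nms_iou_threshold: float = 0.6
    max_detections: int = 100

    def __post_init__(self):
        s = self.strides = tuple(self.strides)
        if any(b >= a for a, b in zip(s[1:], s)):
            raise ConfigError("strides must be strictly increasing")
        for a, b in zip(s, s[1:]):
            if b != 2 * a:
                raise ConfigError("consecutive strides must double (pyramid uses 2x upsampling)")
        if s[0] & (s[0] - 1) or s[0] < 2:
            raise ConfigError("strides must be powers of two")
        n_down = int(np.log2(s[-1]))
        if len(self.backbone_widths) != n_down:
            raise ConfigError(
                f"backbone_widths needs {n_down} entries (one stride-2 stage per "
                f"factor of {s[-1]}), got {len(self.backbone_widths)}")
        if self.anchors_per_loc < 1:
            raise ConfigError("anchors_per_loc must be >= 1")
        if self.head_type not in ("idp", "plain"):
            raise ConfigError(f"unknown head_type {self.head_type!r}")
        if self.dilation != 2:
            raise ConfigError("dilation rate is fixed at 2")
        for name in ("score_threshold", "nms_iou_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["strides"] = list(self.strides)
        d["backbone_widths"] = list(self.backbone_widths)
        return d


class _Backbone(Module):
    def __init__(self, cfg: DetectorConfig, rng, dtype=np.float32):
        widths = cfg.backbone_widths
        self.convs = []
        cin = cfg.in_channels
        for wd in widths:
            self.convs.append(Conv2d(cin, wd, 3, stride=2, rng=rng, dtype=dtype))
            cin = wd
        self.out_stages = [int(np.log2(s)) - 1 for s in cfg.strides]

    def __call__(self, x: Tensor) -> list[Tensor]:
        feats = []
        for i, conv in enumerate(self.convs):
            x = ad.silu(conv(x))
            if i in self.out_stages:
                feats.append(x)
        return feats

    def macs(self, h: int, w: int) -> int:
        total = 0
        for conv in self.convs:
            m, h, w = conv.macs(h, w)
            total += m
        return total


class _Neck(Module):
    """1x1 laterals to a common width, top-down 2x sum, 3x3 smoothing."""

    def __init__(self, in_widths: Sequence[int], c: int, rng, dtype=np.float32):
        self.laterals = [Conv2d(wd, c, 1, rng=rng, dtype=dtype) for wd in in_widths]
        self.smooth = [Conv2d(c, c, 3, rng=rng, dtype=dtype) for _ in in_widths]

    def __call__(self, feats: list[Tensor]) -> list[Tensor]:
        lats = [lat(f) for lat, f in zip(self.laterals, feats)]
        out = [None] * len(lats)
        out[-1] = lats[-1]
        for i in range(len(lats) - 2, -1, -1):
            out[i] = ad.add(lats[i], ad.upsample2(out[i + 1]))
        return [ad.silu(sm(o)) for sm, o in zip(self.smooth, out)]

    def macs(self, level_hw: Sequence[tuple[int, int]]) -> int:
        total = 0
        for lat, sm, (h, w) in zip(self.laterals, self.smooth, level_hw):
            total += lat.macs(h, w)[0] + sm.macs(h, w)[0]
        return total


class Detector(Module):
    def __init__(self, cfg: DetectorConfig, rng, dtype=np.float32):
        self.cfg = cfg
        self.backbone = _Backbone(cfg, rng, dtype=dtype)
        stage_widths = [cfg.backbone_widths[i] for i in self.backbone.out_stages]
        self.neck = _Neck(stage_widths, cfg.neck_channels, rng, dtype=dtype)
        if cfg.head_type == "idp":
            self.head = IDPHead(cfg.neck_channels, cfg.num_classes,
                                anchors=cfg.anchors_per_loc,
                                kernel_size=cfg.kernel_size,
                                activation=cfg.activation, heads=cfg.heads,
                                gn_groups=cfg.gn_groups, rng=rng, dtype=dtype)
        else:
            self.head = PlainHead(cfg.neck_channels, cfg.num_classes,
                                  anchors=cfg.anchors_per_loc, rng=rng, dtype=dtype)

    def __call__(self, images: Tensor) -> list[tuple[Tensor, Tensor]]:
        b, c, h, w = images.shape
        s = self.cfg.strides[-1]
        if h % s or w % s:
            raise ShapeError(f"input size {h}x{w} must be divisible by stride {s}")
        return self.head(self.neck(self.backbone(images)))

    def forward_np(self, images: np.ndarray) -> list[HeadOutputs]:
        outs = self(Tensor(np.asarray(images, dtype=np.float32)))
        return [HeadOutputs(cls=c.data, reg=r.data) for c, r in outs]

    def macs(self, input_hw: tuple[int, int]) -> int:
        h, w = input_hw
        level_hw = [(h // s, w // s) for s in self.cfg.strides]
        return (self.backbone.macs(h, w) + self.neck.macs(level_hw)
                + self.head.macs(level_hw))


def build_detector(cfg: DetectorConfig, seed: int) -> Detector:
    """Initialise a detector; parameters are a pure function of ``seed``."""
    return Detector(cfg, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------


def level_points(cfg: DetectorConfig, input_hw: tuple[int, int]):
    """Per level: ((N, 2) array of (x, y) location centres, stride)."""
    h, w = input_hw
    out = []
    for s in cfg.strides:
        hs, ws = h // s, w // s
        xs = (np.arange(ws) + 0.5) * s
        ys = (np.arange(hs) + 0.5) * s
        gx, gy = np.meshgrid(xs, ys)
        out.append((np.stack([gx.ravel(), gy.ravel()], axis=1), s))
    return out


def _scale_ranges(strides: Sequence[int]) -> list[tuple[float, float]]:
    his = [8.0 * s for s in strides[:-1]] + [float("inf")]
    los = [0.0] + his[:-1]
    return list(zip(los, his))


def assign_targets(points, gts: Sequence[GroundTruth]):
    """Assign ground truths to pyramid locations (see module docstring).

    ``points`` is the output of :func:`level_points`. Returns per level
    ``(labels, boxes)`` where ``labels`` is -1 for background else the
    class id and ``boxes`` holds the matched gt box rows.
    """
    strides = [s for _, s in points]
    ranges = _scale_ranges(strides)
    labels = [np.full(p.shape[0], -1, dtype=np.int64) for p, _ in points]
    boxes = [np.zeros((p.shape[0], 4), dtype=np.float64) for p, _ in points]
    owner = [np.full(p.shape[0], -1, dtype=np.int64) for p, _ in points]

    def gt_level(gt):
        size = max(gt.box[2] - gt.box[0], gt.box[3] - gt.box[1])
        for li, (lo, hi) in enumerate(ranges):
            if lo <= size < hi:
                return li
        return len(ranges) - 1

    order = sorted(range(len(gts)),
                   key=lambda i: ((gts[i].box[2] - gts[i].box[0])
                                  * (gts[i].box[3] - gts[i].box[1]), i))
    assigned = [False] * len(gts)
    for gi in order:  # ascending area: small boxes claim first and keep
        gt = gts[gi]
        li = gt_level(gt)
        p, _ = points[li]
        x1, y1, x2, y2 = gt.box
        inside = ((p[:, 0] >= x1) & (p[:, 0] < x2)
                  & (p[:, 1] >= y1) & (p[:, 1] < y2))
        free = inside & (owner[li] == -1)
        if free.any():
            idx = np.nonzero(free)[0]
            owner[li][idx] = gi
            labels[li][idx] = gt.label
            boxes[li][idx] = gt.box
            assigned[gi] = True
    for gi in order:
        if assigned[gi]:
            continue
        gt = gts[gi]
        li = gt_level(gt)
        p, _ = points[li]
        cx, cy = (gt.box[0] + gt.box[2]) / 2, (gt.box[1] + gt.box[3]) / 2
        d2 = (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2
        d2[owner[li] >= 0] = np.inf
        j = int(np.argmin(d2))
        if not np.isfinite(d2[j]):
            raise RuntimeError("no free location left for a ground-truth box")
        owner[li][j] = gi
        labels[li][j] = gt.label
        boxes[li][j] = gt.box
    return [(l, b) for l, b in zip(labels, boxes)]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


@dataclass
class LossBreakdown:
    total: Tensor
    cls_term: float
    box_term: float
    n_pos: int


_REG_CLIP = 6.0  # keeps exp(reg) and its gradient in a sane range


def detection_loss(outputs: Sequence[tuple], targets: Sequence[Sequence[tuple]],
                   points, num_classes: int) -> LossBreakdown:
    """BCE on class maps plus (1 - IoU) on positives.

    ``outputs`` are per-level (cls, reg) Tensors for a batch of B images;
    ``targets`` is a length-B list of per-level (labels, boxes) from
    :func:`assign_targets`. Both terms are normalised by the positive
    count (floored at one): ``loss = sum(BCE)/max(1,P) + sum(1-IoU)/max(1,P)``.
    """
    b = outputs[0][0].shape[0]
    if outputs[0][0].shape[1] != num_classes:
        raise ShapeError("loss assumes one anchor per location "
                         f"(cls channels {outputs[0][0].shape[1]} != {num_classes})")
    if len(targets) != b:
        raise ShapeError(f"batch size mismatch: outputs {b}, targets {len(targets)}")
    n_pos = 0
    for per_img in targets:
        for labels, _ in per_img:
            n_pos += int((labels >= 0).sum())
    denom = max(1, n_pos)

    cls_sum = None
    box_sum = None
    for li, (cls_t, reg_t) in enumerate(outputs):
        for arr, name in ((cls_t.data, "classification"), (reg_t.data, "regression")):
            if np.isnan(arr).any():
                raise ValueError(f"NaN in {name} output at level {li}")
        _, c, hh, ww = cls_t.shape
        npts = hh * ww
        onehot = np.zeros((b, npts, num_classes), dtype=cls_t.dtype)
        tboxes = np.tile(np.array([0.0, 0.0, 1.0, 1.0]), (b, npts, 1))
        posmask = np.zeros((b, npts), dtype=cls_t.dtype)
        for bi, per_img in enumerate(targets):
            labels, tb = per_img[li]
            pos = labels >= 0
            onehot[bi, pos, labels[pos]] = 1.0
            tboxes[bi, pos] = tb[pos]
            posmask[bi, pos] = 1.0

        cls_flat = ad.transpose(ad.reshape(cls_t, (b, num_classes, npts)), (0, 2, 1))
        bce = ad.tsum(ad.bce_with_logits(cls_flat, Tensor(onehot)))
        cls_sum = bce if cls_sum is None else ad.add(cls_sum, bce)

        p, stride = points[li]
        reg_flat = ad.transpose(ad.reshape(reg_t, (b, 4, npts)), (0, 2, 1))
        dist = ad.mul(ad.exp(ad.clip(reg_flat, -_REG_CLIP, _REG_CLIP)), float(stride))
        px = Tensor(np.broadcast_to(p[:, 0], (b, npts)).copy())
        py = Tensor(np.broadcast_to(p[:, 1], (b, npts)).copy())
        d_l = ad.reshape(dist, (b, npts, 4))
        x1 = ad.sub(px, _col(d_l, 0))
        y1 = ad.sub(py, _col(d_l, 1))
        x2 = ad.add(px, _col(d_l, 2))
        y2 = ad.add(py, _col(d_l, 3))
        tx1, ty1 = Tensor(tboxes[:, :, 0]), Tensor(tboxes[:, :, 1])
        tx2, ty2 = Tensor(tboxes[:, :, 2]), Tensor(tboxes[:, :, 3])
        iw = ad.clip(ad.sub(ad.minimum(x2, tx2), ad.maximum(x1, tx1)), lo=0.0)
        ih = ad.clip(ad.sub(ad.minimum(y2, ty2), ad.maximum(y1, ty1)), lo=0.0)
        inter = ad.mul(iw, ih)
        area_p = ad.mul(ad.sub(x2, x1), ad.sub(y2, y1))
        area_t = ad.mul(ad.sub(tx2, tx1), ad.sub(ty2, ty1))
        union = ad.add(ad.sub(ad.add(area_p, area_t), inter), 1e-9)
        iou_v = ad.div(inter, union)
        lvl_box = ad.tsum(ad.mul(ad.sub(1.0, iou_v), Tensor(posmask)))
        box_sum = lvl_box if box_sum is None else ad.add(box_sum, lvl_box)

    total = ad.mul(ad.add(cls_sum, box_sum), 1.0 / denom)
    return LossBreakdown(total=total,
                         cls_term=float(cls_sum.data) / denom,
                         box_term=float(box_sum.data) / denom,
                         n_pos=n_pos)


def _col(t: Tensor, i: int) -> Tensor:
    """Select column i of a (..., 4) tensor via a constant projection."""
    e = np.zeros((4, 1), dtype=t.dtype)
    e[i, 0] = 1.0
    return ad.reshape(ad.matmul(t, Tensor(e)), t.shape[:-1])


# ---------------------------------------------------------------------------
# decoding / NMS
# ---------------------------------------------------------------------------


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    """Greedy suppression; equal scores break toward the lower input index."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    keep: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        bx = boxes[i]
        for j in order:
            if suppressed[j] or j == i:
                continue
            iw = min(bx[2], boxes[j][2]) - max(bx[0], boxes[j][0])
            ih = min(bx[3], boxes[j][3]) - max(bx[1], boxes[j][1])
            if iw <= 0 or ih <= 0:
                continue
            inter = iw * ih
            union = ((bx[2] - bx[0]) * (bx[3] - bx[1])
                     + (boxes[j][2] - boxes[j][0]) * (boxes[j][3] - boxes[j][1]) - inter)
            if inter / union > iou_thr:
                suppressed[j] = True
    return keep


def decode_and_nms(outputs: Sequence[HeadOutputs], cfg: DetectorConfig,
                   input_hw: tuple[int, int], batch_index: int = 0) -> list[Detection]:
    """Decode one image's head outputs into final detections."""
    if cfg.anchors_per_loc != 1:
        raise ConfigError("decoding is implemented for anchors_per_loc == 1")
    h, w = input_hw
    pts = level_points(cfg, input_hw)
    all_boxes, all_scores, all_labels = [], [], []
    for (out, (p, stride)) in zip(outputs, pts):
        cls = out.cls[batch_index]
        reg = out.reg[batch_index]
        c = cfg.num_classes
        npts = cls.shape[1] * cls.shape[2]
        logits = cls.reshape(c, npts).T
        e = np.exp(-np.abs(logits))
        scores = np.where(logits >= 0, 1.0 / (1.0 + e), e / (1.0 + e))  # (npts, C)
        dist = np.exp(np.clip(reg.reshape(4, npts).T, -_REG_CLIP, _REG_CLIP)) * stride
        x1 = np.clip(p[:, 0] - dist[:, 0], 0, w)
        y1 = np.clip(p[:, 1] - dist[:, 1], 0, h)
        x2 = np.clip(p[:, 0] + dist[:, 2], 0, w)
        y2 = np.clip(p[:, 1] + dist[:, 3], 0, h)
        boxes = np.stack([x1, y1, x2, y2], axis=1)
        valid = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
        for ci in range(c):
            sel = valid & (scores[:, ci] >= cfg.score_threshold)
            if sel.any():
                all_boxes.append(boxes[sel])
                all_scores.append(scores[sel, ci])
                all_labels.append(np.full(int(sel.sum()), ci))
    if not all_boxes:
        return []
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    dets: list[Detection] = []
    for ci in np.unique(labels):
        idx = np.nonzero(labels == ci)[0]
        keep = nms(boxes[idx], scores[idx], cfg.nms_iou_threshold)
        for k in keep:
            i = idx[k]
            dets.append(Detection(box=tuple(float(v) for v in boxes[i]),
                                  label=int(ci), score=float(scores[i])))
    dets.sort(key=lambda d: -d.score)
    return dets[: cfg.max_detections]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainSchedule:
    epochs: int = 6
    lr: float = 2e-3
    batch_size: int = 8
    seed: int = 0
    weight_decay: float = 1e-4


def train(det: Detector, dataset: Sequence[AnnotatedScene],
          schedule: TrainSchedule) -> list[dict]:
    """Train in place; returns one history entry per epoch.

    The learning rate follows a cosine decay to 10% of its initial value.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = det.cfg
    h, w = dataset[0].image.shape
    pts = level_points(cfg, (h, w))
    per_scene_targets = [assign_targets(pts, scene.boxes) for scene in dataset]
    images = np.stack([s.image for s in dataset]).astype(np.float32)[:, None]

    rng = np.random.default_rng(schedule.seed)
    opt = AdamW(det.parameters(), lr=schedule.lr, weight_decay=schedule.weight_decay)
    n = len(dataset)
    steps_per_epoch = max(1, int(np.ceil(n / schedule.batch_size)))
    total_steps = schedule.epochs * steps_per_epoch
    history: list[dict] = []
    step = 0
    for epoch in range(schedule.epochs):
        order = rng.permutation(n)
        losses, cls_terms, box_terms = [], [], []
        for bstart in range(0, n, schedule.batch_size):
            idx = order[bstart: bstart + schedule.batch_size]
            batch = Tensor(images[idx])
            outputs = det(batch)
            targets = [per_scene_targets[i] for i in idx]
            loss = detection_loss(outputs, targets, pts, cfg.num_classes)
            det.zero_grad()
            loss.total.backward()
            frac = step / max(1, total_steps)
            opt.lr = float(schedule.lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac))))
            opt.step()
            step += 1
            losses.append(float(loss.total.data))
            cls_terms.append(loss.cls_term)
            box_terms.append(loss.box_term)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "cls": float(np.mean(cls_terms)),
                        "box": float(np.mean(box_terms))})
    return history


def save_detector(det: Detector, path) -> Path:
    """Serialise config + weights to a single ``.npz``; round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = det.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(det.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path


def load_detector(path) -> Detector:
    with np.load(Path(path)) as data:
        cfg = DetectorConfig(**json.loads(bytes(data["__config__"]).decode()))
        det = Detector(cfg, rng=np.random.default_rng(0))
        det.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return det
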