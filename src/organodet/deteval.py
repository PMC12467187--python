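"""From-scratch COCO-style detection evaluation.

Implements IoU, precision/recall, greedy score-ordered matching, 101-point
interpolated average precision, mAP over IoU thresholds 0.50:0.05:0.95,
size-stratified AP (small < 32^2 px, medium 32^2..96^2, large > 96^2), a
normalized confusion matrix with an explicit background row/column, and
model-complexity counters (trainable parameters, MACs*2 FLOPs).

Boxes are half-open ``[x1, x2) x [y1, y2)`` pixel rectangles. Matching is
greedy in descending score: each detection takes the highest-IoU still
unmatched ground truth at or above the threshold (COCO convention). Classes
with no ground truth are excluded from class means and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .nn import Module
from .types import Detection, GroundTruth, ShapeError, box_area

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
AREA_RANGES = {
    "small": (0.0, 32.0 ** 2),
    "medium": (32.0 ** 2, 96.0 ** 2),
    "large": (96.0 ** 2, float("inf")),
}

__all__ = [
    "iou",
    "precision_recall",
    "match_detections",
    "average_precision",
    "pr_curve",
    "evaluate",
    "confusion_matrix",
    "count_params",
    "count_flops",
    "PRCurve",
    "EvalReport",
    "ConfusionMatrix",
    "IOU_THRESHOLDS",
]


def iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection-over-union of two positive-area boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ValueError(f"degenerate box: {a if ax2 <= ax1 or ay2 <= ay1 else b}")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float, bool]:
    """(precision, recall, degenerate); zero denominators yield 0 and a flag."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall, degenerate


def match_detections(dets: Sequence[Detection], gts: Sequence[GroundTruth],
                     iou_thr: float) -> list[int]:
    """Greedy single-image, single-class matching.

    Returns, for each detection in descending-score order of the input
    list's indices, the matched ground-truth index or -1 (FP). Unreturned
    ground truths are FN.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    taken = [False] * len(gts)
    match = [-1] * len(dets)
    for i in order:
        best, best_iou = -1, iou_thr
        for j, gt in enumerate(gts):
            if taken[j]:
                continue
            v = iou(dets[i].box, gt.box)
            if v >= best_iou and (best == -1 or v > best_iou):
                best, best_iou = j, v
        if best >= 0:
            taken[best] = True
            match[i] = best
    return match


@dataclass
class PRCurve:
    """Raw precision/recall sweep plus score thresholds (descending)."""

    recall: np.ndarray
    precision: np.ndarray
    scores: np.ndarray


def _collect(dets_by_img, gts_by_img, iou_thr, area_range=None):
    """Global score-ordered sweep; returns (tp flags, fp flags, scores, npos).

    With an ``area_range``, ground truths outside the range are *ignored*:
    matching one neither scores nor penalises, and unmatched detections
    whose own area falls outside the range are ignored too (COCO rule).
    """
    records = []  # (score, img, det_idx)
    for img, dets in dets_by_img.items():
        for idx, d in enumerate(dets):
            records.append((d.score, img, idx))
    records.sort(key=lambda r: (-r[0], r[1], r[2]))

    ignore = {}
    npos = 0
    for img, gts in gts_by_img.items():
        flags = []
        for gt in gts:
            a = box_area(gt.box)
            ign = area_range is not None and not (area_range[0] <= a < area_range[1])
            flags.append(ign)
            npos += not ign
        ignore[img] = flags
    taken = {img: [False] * len(gts) for img, gts in gts_by_img.items()}

    tp, fp, scores = [], [], []
    for score, img, idx in records:
        det = dets_by_img[img][idx]
        gts = gts_by_img.get(img, [])
        best, best_iou, best_ign = -1, -1.0, False
        for j, gt in enumerate(gts):
            if taken[img][j]:
                continue
            v = iou(det.box, gt.box)
            if v < iou_thr:
                continue
            ign = ignore[img][j]
            # prefer any real gt over an ignored one, then higher IoU
            if best == -1 or (best_ign and not ign) or (ign == best_ign and v > best_iou):
                best, best_iou, best_ign = j, v, ign
        if best >= 0:
            taken[img][best] = True
            if best_ign:
                continue  # matched an out-of-stratum gt: drop silently
            tp.append(1)
            fp.append(0)
        else:
            if area_range is not None:
                a = box_area(det.box)
                if not (area_range[0] <= a < area_range[1]):
                    continue  # unmatched det outside the stratum: ignore
            tp.append(0)
            fp.append(1)
        scores.append(score)
    return np.array(tp), np.array(fp), np.array(scores), npos


def pr_curve(dets_by_img, gts_by_img, iou_thr, area_range=None) -> PRCurve:
    tp, fp, scores, npos = _collect(dets_by_img, gts_by_img, iou_thr, area_range)
    if npos == 0:
        return PRCurve(np.array([]), np.array([]), np.array([]))
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    recall = ctp / npos
    precision = ctp / np.maximum(ctp + cfp, 1)
    return PRCurve(recall=recall, precision=precision, scores=scores)


def _ap_from_curve(curve: PRCurve, npos: int, grid_points: int = 101,
                   method: str = "interp101") -> float:
    if npos == 0:
        return float("nan")
    if curve.recall.size == 0:
        return 0.0
    r, p = curve.recall, curve.precision
    if method == "trapezoid":
        rr = np.concatenate([[0.0], r])
        pp = np.concatenate([[p[0] if p.size else 0.0], p])
        return float(np.trapezoid(pp, rr))
    # right-max interpolation on an evenly spaced recall grid
    grid = np.linspace(0.0, 1.0, grid_points)
    p_interp = np.zeros_like(grid)
    # precision envelope: running max from the right
    env = np.maximum.accumulate(p[::-1])[::-1]
    idx = np.searchsorted(r, grid, side="left")
    valid = idx < len(r)
    p_interp[valid] = env[idx[valid]]
    return float(p_interp.mean())


def average_precision(dets_by_img: Mapping[object, Sequence[Detection]],
                      gts_by_img: Mapping[object, Sequence[GroundTruth]],
                      iou_thr: float, area_range=None,
                      method: str = "interp101") -> float:
    """101-point interpolated AP for one class (inputs already class-filtered).

    Returns NaN when the class has no ground truth (and no detections make
    that meaningful) — callers exclude such classes from means.
    """
    tp, fp, scores, npos = _collect(dets_by_img, gts_by_img, iou_thr, area_range)
    if npos == 0:
        return float("nan")
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    recall = ctp / npos
    precision = ctp / np.maximum(ctp + cfp, 1)
    return _ap_from_curve(PRCurve(recall, precision, scores), npos, method=method)


@dataclass
class EvalReport:
    """Aggregate metrics; all values are fractions in [0, 1] (or NaN)."""

    per_class_ap: dict[str, float]
    map: float
    map50: float
    map75: float
    map_small: float
    map_medium: float
    map_large: float
    counts: dict[str, dict[str, int]]
    skipped_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class_ap": self.per_class_ap,
            "mAP": self.map, "mAP50": self.map50, "mAP75": self.map75,
            "mAP_S": self.map_small, "mAP_M": self.map_medium, "mAP_L": self.map_large,
            "counts": self.counts,
            "skipped_classes": self.skipped_classes,
        }


def _split_by_class(items, n_classes, label=lambda x: x.label):
    out = [dict() for _ in range(n_classes)]
    for img, lst in items.items():
        for x in lst:
            if not 0 <= label(x) < n_classes:
                raise ValueError(f"unknown class id {label(x)}")
            out[label(x)].setdefault(img, []).append(x)
    return out


def evaluate(dets: Mapping[object, Sequence[Detection]],
             gts: Mapping[object, Sequence[GroundTruth]],
             classes: Sequence[str], method: str = "interp101") -> EvalReport:
    """Full report over all images; ``dets``/``gts`` map image id -> lists."""
    n = len(classes)
    dets_c = _split_by_class(dets, n)
    gts_c = _split_by_class(gts, n)
    imgs = set(dets) | set(gts)

    def _class_maps(c):
        return ({img: dets_c[c].get(img, []) for img in imgs},
                {img: gts_c[c].get(img, []) for img in imgs})

    ap = np.full((n, len(IOU_THRESHOLDS)), np.nan)
    strata = {k: np.full((n, len(IOU_THRESHOLDS)), np.nan) for k in AREA_RANGES}
    counts: dict[str, dict[str, int]] = {}
    skipped = []
    for c, name in enumerate(classes):
        dmap, gmap = _class_maps(c)
        has_gt = any(gmap.values())
        if not has_gt:
            skipped.append(name)
        for t, thr in enumerate(IOU_THRESHOLDS):
            if has_gt:
                ap[c, t] = average_precision(dmap, gmap, thr, method=method)
            for key, rng in AREA_RANGES.items():
                strata[key][c, t] = average_precision(dmap, gmap, thr, rng, method=method)
        # TP/FP/FN at IoU 0.5 for the count summary
        tp_tot = fp_tot = fn_tot = 0
        for img in imgs:
            m = match_detections(dmap.get(img, []), gmap.get(img, []), 0.5)
            tp_i = sum(1 for v in m if v >= 0)
            tp_tot += tp_i
            fp_tot += len(m) - tp_i
            fn_tot += len(gmap.get(img, [])) - tp_i
        counts[name] = {"tp": tp_tot, "fp": fp_tot, "fn": fn_tot}

    def _mean(a):
        return float(np.nanmean(a)) if not np.all(np.isnan(a)) else float("nan")

    i50 = IOU_THRESHOLDS.index(0.5)
    i75 = IOU_THRESHOLDS.index(0.75)
    per_class = {name: _mean(ap[c]) for c, name in enumerate(classes)}
    return EvalReport(
        per_class_ap=per_class,
        map=_mean(ap), map50=_mean(ap[:, i50]), map75=_mean(ap[:, i75]),
        map_small=_mean(strata["small"]), map_medium=_mean(strata["medium"]),
        map_large=_mean(strata["large"]),
        counts=counts, skipped_classes=skipped)


@dataclass
class ConfusionMatrix:
    """(C+1)x(C+1) counts; last row/column is background; rows normalised."""

    counts: np.ndarray
    normalized: np.ndarray
    empty_rows: list[int]


def confusion_matrix(dets: Mapping[object, Sequence[Detection]],
                     gts: Mapping[object, Sequence[GroundTruth]],
                     n_classes: int, iou_thr: float = 0.5,
                     score_thr: float = 0.3) -> ConfusionMatrix:
    """Class-agnostic greedy matching; mismatched pairs populate off-diagonals."""
    if not 0.0 <= score_thr <= 1.0:
        raise ValueError("score_thr must lie in [0, 1]")
    m = np.zeros((n_classes + 1, n_classes + 1), dtype=np.int64)
    bg = n_classes
    for img in set(dets) | set(gts):
        ds = [d for d in dets.get(img, []) if d.score >= score_thr]
        gs = list(gts.get(img, []))
        order = sorted(range(len(ds)), key=lambda i: (-ds[i].score, i))
        taken = [False] * len(gs)
        for i in order:
            best, best_iou = -1, iou_thr
            for j, gt in enumerate(gs):
                if taken[j]:
                    continue
                v = iou(ds[i].box, gt.box)
                if v >= best_iou and (best == -1 or v > best_iou):
                    best, best_iou = j, v
            if best >= 0:
                taken[best] = True
                m[gs[best].label, ds[i].label] += 1
            else:
                m[bg, ds[i].label] += 1
        for j, t in enumerate(taken):
            if not t:
                m[gs[j].label, bg] += 1
    sums = m.sum(axis=1, keepdims=True)
    norm = np.divide(m, np.maximum(sums, 1), dtype=float)
    empty = [i for i in range(n_classes + 1) if sums[i, 0] == 0]
    return ConfusionMatrix(counts=m, normalized=norm, empty_rows=empty)


def count_params(model: Module) -> int:
    """Exact trainable-scalar count."""
    return model.num_params()


def count_flops(model, input_hw: tuple[int, int]) -> float:
    """FLOPs (multiply-accumulates x 2) of one forward pass at the given size.

    Counts convolution, projection and attention MACs; cheap elementwise
    gating is included where the layer reports it.
    """
    return 2.0 * model.macs(input_hw)
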