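"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — explicit
loops, full-convolution kernel composition, exhaustive rule application —
so it shares no code path with the library implementation it checks.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# kernel composition / direct correlation (spatial-branch oracle)
# ---------------------------------------------------------------------------


def dilate_kernel(k: np.ndarray, rate: int) -> np.ndarray:
    """Insert rate-1 zeros between taps along both axes."""
    kh, kw = k.shape
    out = np.zeros(((kh - 1) * rate + 1, (kw - 1) * rate + 1), dtype=k.dtype)
    out[::rate, ::rate] = k
    return out


def full_convolve2d(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Plain 'full' 2-D convolution by explicit accumulation."""
    ah, aw = a.shape
    bh, bw = b.shape
    out = np.zeros((ah + bh - 1, aw + bw - 1), dtype=np.result_type(a, b))
    for i in range(ah):
        for j in range(aw):
            out[i: i + bh, j: j + bw] += a[i, j] * b
    return out


def compose_stage_kernels(kh1: np.ndarray, kv1: np.ndarray,
                          kh2: np.ndarray, kv2: np.ndarray,
                          rate: int) -> np.ndarray:
    """Equivalent single 2-D kernel of the four-stage chain.

    Successive cross-correlations compose by full *convolution* of the
    kernels (no flips needed when every stage is a cross-correlation).
    Stage-2 kernels are dilation-expanded with inserted zeros first.
    """
    k = full_convolve2d(kh1[None, :], kv1[:, None])
    k = full_convolve2d(k, dilate_kernel(kh2[None, :], rate))
    k = full_convolve2d(k, dilate_kernel(kv2[:, None], rate))
    return k


def direct_correlate2d_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Brute-force sliding-window 'same' cross-correlation (odd kernel)."""
    kh, kw = k.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((ph, ph), (pw, pw)))
    out = np.zeros_like(x)
    h, w = x.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = (xp[i: i + kh, j: j + kw] * k).sum()
    return out


# ---------------------------------------------------------------------------
# channel-branch oracle: scalar 2x2 attention arithmetic
# ---------------------------------------------------------------------------


def scalar_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray):
    """softmax(q k^T / sqrt(d)) v with explicit scalar loops."""
    h, d = q.shape
    logits = [[sum(q[i][t] * k[j][t] for t in range(d)) / d ** 0.5
               for j in range(h)] for i in range(h)]
    att = []
    for row in logits:
        m = max(row)
        e = [np.exp(x - m) for x in row]
        s = sum(e)
        att.append([x / s for x in e])
    out = [[sum(att[i][j] * v[j][t] for j in range(h)) for t in range(d)]
           for i in range(h)]
    return np.array(att), np.array(out)


# ---------------------------------------------------------------------------
# detection-evaluation oracles
# ---------------------------------------------------------------------------


def pixel_iou(a, b, scale: int = 1) -> float:
    """IoU by rasterising both boxes onto a pixel grid and counting."""
    x1 = int(min(a[0], b[0]) * scale)
    y1 = int(min(a[1], b[1]) * scale)
    x2 = int(np.ceil(max(a[2], b[2]) * scale)) + 1
    y2 = int(np.ceil(max(a[3], b[3]) * scale)) + 1
    w, h = x2 - x1, y2 - y1
    ga = np.zeros((h, w), dtype=bool)
    gb = np.zeros((h, w), dtype=bool)
    ga[int(a[1] * scale) - y1: int(a[3] * scale) - y1,
       int(a[0] * scale) - x1: int(a[2] * scale) - x1] = True
    gb[int(b[1] * scale) - y1: int(b[3] * scale) - y1,
       int(b[0] * scale) - x1: int(b[2] * scale) - x1] = True
    inter = (ga & gb).sum()
    union = (ga | gb).sum()
    return inter / union


def _iou(a, b) -> float:
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    i = iw * ih
    return i / ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - i)


def greedy_match_counts(dets, gts, thr):
    """(tp, fp, fn) by literal application of the greedy matching rule.

    ``dets`` = [(box, score)], ``gts`` = [box]; single image, single class.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][1], i))
    used = [False] * len(gts)
    tp = fp = 0
    for i in order:
        cands = [(j, _iou(dets[i][0], g)) for j, g in enumerate(gts) if not used[j]]
        cands = [(j, v) for j, v in cands if v >= thr]
        if cands:
            best = max(cands, key=lambda t: (t[1], -t[0]))
            used[best[0]] = True
            tp += 1
        else:
            fp += 1
    return tp, fp, len(gts) - tp


def reference_ap(records, npos, grid=101):
    """AP from (score, is_tp) records by direct threshold sweep.

    Interpolated precision at recall r is the max precision among sweep
    points with recall >= r, evaluated on an even grid of ``grid`` points.
    """
    if npos == 0:
        return float("nan")
    records = sorted(records, key=lambda r: -r[0])
    pr = []
    tp = fp = 0
    for score, is_tp in records:
        tp += is_tp
        fp += not is_tp
        pr.append((tp / npos, tp / (tp + fp)))
    total = 0.0
    for r in np.linspace(0.0, 1.0, grid):  # the COCO-defined recall grid
        ps = [p for (rec, p) in pr if rec >= r]
        total += max(ps) if ps else 0.0
    return total / grid


def reference_evaluate(dets_by_img, gts_by_img, n_classes, thresholds,
                       area_range=None):
    """Per-class AP dict by exhaustive greedy matching at each threshold.

    ``dets_by_img[img]`` = [(box, label, score)], ``gts_by_img[img]`` =
    [(box, label)]. Implements the COCO ignore rule for ``area_range``:
    out-of-range gts never count; a detection matching one (or unmatched
    with out-of-range area) is dropped from the sweep.
    """
    out = {}
    for c in range(n_classes):
        per_thr = []
        for thr in thresholds:
            records = []
            npos = 0
            for img in sorted(set(dets_by_img) | set(gts_by_img), key=str):
                gts = [g for g in gts_by_img.get(img, []) if g[1] == c]
                ignore = []
                for box, _ in gts:
                    a = (box[2] - box[0]) * (box[3] - box[1])
                    ign = area_range is not None and not (
                        area_range[0] <= a < area_range[1])
                    ignore.append(ign)
                    npos += not ign
                dets = [d for d in dets_by_img.get(img, []) if d[1] == c]
                order = sorted(range(len(dets)), key=lambda i: (-dets[i][2], i))
                used = [False] * len(gts)
                for i in order:
                    box, _, score = dets[i]
                    cands = [(j, _iou(box, gts[j][0])) for j in range(len(gts))
                             if not used[j]]
                    cands = [(j, v) for j, v in cands if v >= thr]
                    real = [t for t in cands if not ignore[t[0]]]
                    if real:
                        j = max(real, key=lambda t: (t[1], -t[0]))[0]
                        used[j] = True
                        records.append((score, True))
                    elif cands:
                        j = max(cands, key=lambda t: (t[1], -t[0]))[0]
                        used[j] = True  # matched an ignored gt: drop
                    else:
                        if area_range is not None:
                            a = (box[2] - box[0]) * (box[3] - box[1])
                            if not (area_range[0] <= a < area_range[1]):
                                continue
                        records.append((score, False))
            per_thr.append(reference_ap(records, npos))
        out[c] = per_thr
    return out


# ---------------------------------------------------------------------------
# NMS / assignment oracles
# ---------------------------------------------------------------------------


def brute_nms(boxes, scores, thr):
    """O(n^2) suppression: keep a box iff no higher-priority kept box
    overlaps it above thr; priority = (score desc, index asc)."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    kept = []
    for i in order:
        if all(_iou(boxes[i], boxes[j]) <= thr for j in kept):
            kept.append(i)
    return kept


def brute_assign(points, gts, strides):
    """Exhaustive application of the documented assignment rule.

    ``points`` = per level (N,2) arrays; returns per level owner index
    arrays (-1 = background).
    """
    his = [8.0 * s for s in strides[:-1]] + [float("inf")]
    los = [0.0] + his[:-1]

    def level_of(box):
        size = max(box[2] - box[0], box[3] - box[1])
        for li, (lo, hi) in enumerate(zip(los, his)):
            if lo <= size < hi:
                return li
        return len(strides) - 1

    owners = [np.full(len(p), -1, dtype=int) for p in points]
    area = [(g.box[2] - g.box[0]) * (g.box[3] - g.box[1]) for g in gts]
    order = sorted(range(len(gts)), key=lambda i: (area[i], i))
    got = [False] * len(gts)
    for gi in order:
        li = level_of(gts[gi].box)
        x1, y1, x2, y2 = gts[gi].box
        for pi, (px, py) in enumerate(points[li]):
            if owners[li][pi] == -1 and x1 <= px < x2 and y1 <= py < y2:
                owners[li][pi] = gi
                got[gi] = True
    for gi in order:
        if got[gi]:
            continue
        li = level_of(gts[gi].box)
        cx = (gts[gi].box[0] + gts[gi].box[2]) / 2
        cy = (gts[gi].box[1] + gts[gi].box[3]) / 2
        best, bestd = -1, np.inf
        for pi, (px, py) in enumerate(points[li]):
            if owners[li][pi] != -1:
                continue
            d = (px - cx) ** 2 + (py - cy) ** 2
            if d < bestd:
                best, bestd = pi, d
        owners[li][best] = gi
    return owners
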