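"""Synthetic bright-field organoid scenes with COCO annotations.

Emulates the data regime of intestinal-organoid bright-field imaging: blobby
translucent bodies with a darker rim and brighter lumen, optional budding
protrusions (crypts), large scale variation (log-uniform radii), blurred
boundaries (Gaussian optics blur), partial overlap and a skewed class
balance. Four developmental classes are drawn:

* ``cyst`` — vesicular body, no buds, thin rim, bright lumen;
* ``early_organoid`` — 1–2 buds;
* ``late_organoid`` — >= 3 buds (the rarest class by default);
* ``spheroid`` — smooth near-circular body with a dense, darker interior.

Every stochastic draw consumes, in a fixed order, from one
``numpy.random.default_rng`` (PCG64) seeded by ``SceneSpec.seed``, so scenes
are bitwise reproducible. The generator is a declared stand-in for real
microscopy — it exercises a detector, it does not model optics faithfully.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .head import CLASS_NAMES
from .types import GroundTruth, PlacementError

__all__ = [
    "SceneSpec",
    "OrganoidInstance",
    "AnnotatedScene",
    "render_scene",
    "instance_mask",
    "write_coco",
    "read_coco",
    "split_dataset",
    "CLASS_NAMES",
]

# per-class appearance: (lumen intensity, rim intensity, rim thickness px)
_APPEARANCE = {
    0: (0.88, 0.32, 1),   # cyst: bright lumen, thin dark rim
    1: (0.82, 0.34, 2),   # early organoid
    2: (0.78, 0.34, 2),   # late organoid
    3: (0.52, 0.30, 3),   # spheroid: dense darker body
}


@dataclass
class SceneSpec:
    """Generation parameters for one scene; fully determines it via ``seed``."""

    image_size: tuple[int, int] = (256, 256)
    n_instances: tuple[int, int] = (3, 8)
    instances_per_class: Mapping[str, tuple[int, int]] | None = None
    radius_range: tuple[float, float] = (8.0, 48.0)
    bud_radius_fraction: float = 0.4
    blur_sigma: float = 1.5
    noise_std: float = 0.03
    max_overlap_iou: float = 0.3
    class_weights: Mapping[str, float] = field(default_factory=lambda: {
        "cyst": 0.35, "early_organoid": 0.30, "late_organoid": 0.10,
        "spheroid": 0.25})
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        lo, hi = self.radius_range
        if not (0 < lo <= hi < min(h, w) / 2):
            raise ValueError(f"radius_range {self.radius_range} must lie in "
                             f"(0, {min(h, w) / 2})")
        if not 0.0 <= self.max_overlap_iou < 1.0:
            raise ValueError("max_overlap_iou must lie in [0, 1)")
        missing = set(self.class_weights) - set(CLASS_NAMES)
        if missing:
            raise ValueError(f"unknown class names in class_weights: {missing}")


@dataclass(frozen=True)
class OrganoidInstance:
    """Geometry of one rendered organoid."""

    class_id: int
    center: tuple[float, float]   # (x, y) px
    body_radius: float            # semi-major axis, px
    bud_count: int
    bud_angles: tuple[float, ...]
    eccentricity: float           # semi-minor = radius * (1 - eccentricity)


@dataclass
class AnnotatedScene:
    """One image with its tight ground-truth boxes and instance metadata."""

    image: np.ndarray
    boxes: list[GroundTruth]
    instance_meta: list[OrganoidInstance]


def instance_mask(inst: OrganoidInstance, image_size: tuple[int, int],
                  bud_radius_fraction: float) -> np.ndarray:
    """Binary mask of the instance (body ellipse plus bud disks), clipped."""
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = inst.center
    a = inst.body_radius
    b = inst.body_radius * (1.0 - inst.eccentricity)
    m = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    rb = bud_radius_fraction * inst.body_radius
    for theta in inst.bud_angles:
        bx = cx + a * np.cos(theta)
        by = cy + b * np.sin(theta)
        m |= (xx - bx) ** 2 + (yy - by) ** 2 <= rb ** 2
    return m


def _mask_box(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _box_iou(a, b) -> float:
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)


def _draw_bud_counts(class_id: int, rng: np.random.Generator) -> int:
    if class_id == 1:
        return int(rng.integers(1, 3))      # early: 1-2 crypts
    if class_id == 2:
        return int(rng.integers(3, 7))      # late: >= 3 buds
    return 0                                 # cyst / spheroid: smooth


def render_scene(spec: SceneSpec) -> AnnotatedScene:
    """Render one annotated scene, fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size

    # textured background around bright-field grey
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=min(h, w) / 16)
    tex_std = tex.std()
    if tex_std > 0:
        tex /= tex_std
    img = 0.72 + 0.025 * tex

    # which classes to draw
    if spec.instances_per_class is not None:
        class_ids: list[int] = []
        for ci, name in enumerate(CLASS_NAMES):
            lo, hi = spec.instances_per_class.get(name, (0, 0))
            class_ids.extend([ci] * int(rng.integers(lo, hi + 1)))
    else:
        n = int(rng.integers(spec.n_instances[0], spec.n_instances[1] + 1))
        names = list(spec.class_weights)
        weights = np.array([spec.class_weights[k] for k in names], dtype=float)
        weights /= weights.sum()
        idx = rng.choice(len(names), size=n, p=weights)
        class_ids = [CLASS_NAMES.index(names[i]) for i in idx]

    instances: list[OrganoidInstance] = []
    boxes: list[tuple[int, int, int, int]] = []
    log_lo, log_hi = np.log(spec.radius_range[0]), np.log(spec.radius_range[1])
    for ci in class_ids:
        placed = False
        for _ in range(1000):
            r = float(np.exp(rng.uniform(log_lo, log_hi)))
            ecc = float(rng.uniform(0.0, 0.08 if ci == 3 else 0.35))
            margin = 0.3 * r
            cx = float(rng.uniform(margin, w - margin))
            cy = float(rng.uniform(margin, h - margin))
            bud_count = _draw_bud_counts(ci, rng)
            bud_angles = tuple(np.sort(rng.uniform(0.0, 2 * np.pi, bud_count)))
            inst = OrganoidInstance(class_id=ci, center=(cx, cy), body_radius=r,
                                    bud_count=bud_count, bud_angles=bud_angles,
                                    eccentricity=ecc)
            mask = instance_mask(inst, spec.image_size, spec.bud_radius_fraction)
            box = _mask_box(mask)
            if box is None:
                continue
            if all(_box_iou(box, other) <= spec.max_overlap_iou for other in boxes):
                instances.append(inst)
                boxes.append(box)
                lumen, rim_val, rim_px = _APPEARANCE[ci]
                interior = ndimage.binary_erosion(mask, iterations=rim_px) \
                    if rim_px > 0 else mask
                rim = mask & ~interior
                img[interior] = lumen
                img[rim] = rim_val
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a {CLASS_NAMES[ci]} instance within 1000 tries")

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma)
    img = img + rng.normal(0.0, spec.noise_std, (h, w))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    gts = [GroundTruth(box=(float(b[0]), float(b[1]), float(b[2]), float(b[3])),
                       label=inst.class_id)
           for b, inst in zip(boxes, instances)]
    return AnnotatedScene(image=img, boxes=gts, instance_meta=instances)


# ---------------------------------------------------------------------------
# COCO I/O (plain JSON; [x, y, w, h] boxes at the file boundary only)
# ---------------------------------------------------------------------------


def write_coco(scenes: Sequence[AnnotatedScene], path,
               category_names: Sequence[str] = CLASS_NAMES,
               file_names: Sequence[str] | None = None) -> Path:
    """Write standard COCO annotations for a list of scenes."""
    if not scenes:
        raise ValueError("write_coco requires a non-empty scene list")
    path = Path(path)
    images, annotations = [], []
    ann_id = 1
    for i, scene in enumerate(scenes):
        h, w = scene.image.shape
        name = file_names[i] if file_names else f"scene_{i:05d}.png"
        images.append({"id": i + 1, "file_name": name, "width": w, "height": h})
        for gt in scene.boxes:
            x1, y1, x2, y2 = gt.box
            annotations.append({
                "id": ann_id, "image_id": i + 1,
                "category_id": gt.label + 1,
                "bbox": [x1, y1, x2 - x1, y2 - y1],
                "area": (x2 - x1) * (y2 - y1),
                "iscrowd": 0,
            })
            ann_id += 1
    doc = {
        "info": {"generator": "organodet.synthdata", "rng": "numpy PCG64"},
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i + 1, "name": n} for i, n in enumerate(category_names)],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def read_coco(path):
    """Read COCO annotations.

    Returns ``(images, gts_by_image, categories)`` where ``gts_by_image``
    maps image id to :class:`GroundTruth` lists in half-open pixel coords
    and ``categories`` maps category id to name.
    """
    with open(path) as fh:
        doc = json.load(fh)
    categories = {c["id"]: c["name"] for c in doc["categories"]}
    cat_to_label = {cid: i for i, cid in enumerate(sorted(categories))}
    gts: dict[int, list[GroundTruth]] = {img["id"]: [] for img in doc["images"]}
    for ann in doc["annotations"]:
        x, y, bw, bh = ann["bbox"]
        gts[ann["image_id"]].append(
            GroundTruth(box=(x, y, x + bw, y + bh),
                        label=cat_to_label[ann["category_id"]]))
    return doc["images"], gts, categories


def split_dataset(n_items: int, ratio: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> tuple[list[int], list[int], list[int]]:
    """Random disjoint train/val/test index lists.

    Val and test sizes are ``floor(n * r / sum(ratio))``; the remainder goes
    to train. Deterministic per seed.
    """
    if n_items < 10:
        raise ValueError(f"need at least 10 items to split, got {n_items}")
    total = sum(ratio)
    n_val = int(n_items * ratio[1] // total)
    n_test = int(n_items * ratio[2] // total)
    perm = np.random.default_rng(seed).permutation(n_items)
    n_train = n_items - n_val - n_test
    return (perm[:n_train].tolist(),
            perm[n_train:n_train + n_val].tolist(),
            perm[n_train + n_val:].tolist())
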