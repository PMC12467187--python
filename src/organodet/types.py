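"""Shared domain types and exceptions.

Boxes are 0-based pixel coordinates, half-open ``[x1, x2) x [y1, y2)``.
COCO's ``[x, y, w, h]`` convention appears only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass


class ShapeError(ValueError):
    """Array shapes inconsistent with the operation's contract."""


class ParameterError(ValueError):
    """Invalid hyperparameter (even kernel, non-dividing head count, ...)."""


class ConfigError(ValueError):
    """Invalid run configuration."""


class PlacementError(RuntimeError):
    """Rejection sampling could not place a requested instance."""


Box = tuple[float, float, float, float]


@dataclass(frozen=True)
class Detection:
    """One predicted box with class label and confidence."""

    box: Box
    label: int
    score: float


@dataclass(frozen=True)
class GroundTruth:
    """One annotated box."""

    box: Box
    label: int


def box_area(b: Box) -> float:
    return max(0.0, b[2] - b[0]) * max(0.0, b[3] - b[1])
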