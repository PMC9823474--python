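"""Annotation geometry and the six-class frame-labeling rules.

A pupillometer frame is judged by where the pupil center sits inside the
square field of view seen through the stimulation lens, and by how much of
the pupil the eyelids cover.  The square is partitioned by its two diagonals
into four cardinal triangles (*up*, *right*, *down*, *left*); a small circle
around the optical axis is the *central region* within which the eye is
considered aligned.  A frame is labeled

* ``correct`` -- pupil center inside the central region and more than 90 %
  of the pupil area visible;
* ``closed``  -- pupil not detectable, or center inside the central region
  with more than 10 % of the pupil covered, or center outside it with more
  than 85 % covered;
* ``up`` / ``right`` / ``down`` / ``left`` -- center outside the central
  region, at least 15 % visible; the label is the triangle the center falls
  into.

Coordinates are continuous image coordinates: origin at the top-left corner
of the square, x rightward, y downward; the pixel at (row i, col j) has its
center at (j + 0.5, i + 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Tuple

__all__ = [
    "EyeLabel",
    "AnnotationGeometry",
    "PupilObservation",
    "region_of",
    "assign_label",
    "scale_geometry",
]

#: default cropped-square side in pixels
DEFAULT_SIDE = 520
#: default central-region radius at side 520, in pixels
DEFAULT_CENTRAL_RADIUS = 69.0


class EyeLabel(str, Enum):
    """The six admissible frame labels."""

    CORRECT = "correct"
    CLOSED = "closed"
    RIGHT = "right"
    DOWN = "down"
    LEFT = "left"
    UP = "up"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: label order used for confusion matrices and reports
LABEL_ORDER = [
    EyeLabel.CORRECT,
    EyeLabel.CLOSED,
    EyeLabel.RIGHT,
    EyeLabel.DOWN,
    EyeLabel.LEFT,
    EyeLabel.UP,
]

#: directional labels in tie-break priority order
_DIRECTION_PRIORITY = (EyeLabel.UP, EyeLabel.RIGHT, EyeLabel.DOWN, EyeLabel.LEFT)


@dataclass(frozen=True)
class AnnotationGeometry:
    """Square field-of-view geometry used for labeling.

    Parameters
    ----------
    side
        Edge of the cropped square, pixels.
    center
        Geometry center (optical axis) in continuous coordinates; defaults
        to the square center ``(side/2, side/2)``.
    central_radius
        Radius of the central (aligned) region, pixels.  The default 69 px
        is defined at side 520 and scales linearly with the side.
    """

    side: float = DEFAULT_SIDE
    center: Optional[Tuple[float, float]] = None
    central_radius: float = DEFAULT_CENTRAL_RADIUS

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError(f"side must be positive, got {self.side}")
        if self.center is None:
            object.__setattr__(self, "center", (self.side / 2.0, self.side / 2.0))
        cx, cy = self.center
        if not (0 < cx < self.side and 0 < cy < self.side):
            raise ValueError(f"center {self.center} not strictly inside the square")
        if not (0 < self.central_radius < self.side / 2.0):
            raise ValueError(
                f"central_radius must lie in (0, side/2), got {self.central_radius}"
            )


@dataclass(frozen=True)
class PupilObservation:
    """A (possibly absent) pupil center plus its visible area fraction.

    ``center is None`` means the pupil could not be detected at all, which
    forces the *closed* label regardless of ``visible_fraction``.
    """

    center: Optional[Tuple[float, float]]
    visible_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.visible_fraction <= 1.0):
            raise ValueError(
                f"visible_fraction must be in [0, 1], got {self.visible_fraction}"
            )


def region_of(point: Tuple[float, float], geometry: AnnotationGeometry) -> str:
    """Region of a point: ``central`` or one of the four diagonal triangles.

    The central region includes its edge (distance equal to the radius).
    Points exactly on a diagonal are resolved with the fixed priority
    up > right > down > left so the partition is deterministic.

    Raises
    ------
    ValueError
        If the point lies outside the ``side`` x ``side`` square.
    """
    x, y = point
    if not (0.0 <= x <= geometry.side and 0.0 <= y <= geometry.side):
        raise ValueError(f"point {point} outside the {geometry.side}-px square")
    cx, cy = geometry.center
    dx, dy = x - cx, y - cy
    if math.hypot(dx, dy) <= geometry.central_radius:
        return "central"
    # strict triangle membership first, then the diagonal tie-break
    if dy < -abs(dx):
        return EyeLabel.UP.value
    if dx > abs(dy):
        return EyeLabel.RIGHT.value
    if dy > abs(dx):
        return EyeLabel.DOWN.value
    if dx < -abs(dy):
        return EyeLabel.LEFT.value
    # on a diagonal: |dx| == |dy|; pick the highest-priority adjacent region
    for label in _DIRECTION_PRIORITY:
        if label is EyeLabel.UP and dy <= -abs(dx):
            return label.value
        if label is EyeLabel.RIGHT and dx >= abs(dy):
            return label.value
        if label is EyeLabel.DOWN and dy >= abs(dx):
            return label.value
        if label is EyeLabel.LEFT and dx <= -abs(dy):
            return label.value
    raise AssertionError("unreachable: the four closed triangles cover the square")


def assign_label(obs: PupilObservation, geometry: AnnotationGeometry) -> EyeLabel:
    """Map a pupil observation to one of the six frame labels.

    Rule order (first match wins):

    1. absent center -> ``closed``;
    2. center in the central region: ``correct`` if more than 90 % visible,
       else ``closed`` (exactly 90 % visible counts as closed);
    3. center outside: ``closed`` if less than 15 % visible (exactly 15 %
       counts as directional), else the directional label of the triangle.
    """
    if obs.center is None:
        return EyeLabel.CLOSED
    region = region_of(obs.center, geometry)
    if region == "central":
        return EyeLabel.CORRECT if obs.visible_fraction > 0.90 else EyeLabel.CLOSED
    if obs.visible_fraction < 0.15:
        return EyeLabel.CLOSED
    return EyeLabel(region)


def scale_geometry(geometry: AnnotationGeometry, new_side: float) -> AnnotationGeometry:
    """Rescale all pixel-denominated fields to a new square side."""
    if new_side <= 0:
        raise ValueError(f"new_side must be positive, got {new_side}")
    s = new_side / geometry.side
    cx, cy = geometry.center
    return replace(
        geometry,
        side=new_side,
        center=(cx * s, cy * s),
        central_radius=geometry.central_radius * s,
    )
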