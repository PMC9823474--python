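"""Rule-based (expert-system) pupil detector and frame classifier.

The pipeline encodes a priori knowledge of the instrument's imagery in an
eight-stage sequence: fixed square crop, suppression of the dark background
below a fixed threshold, anisotropic Gaussian smoothing (wider horizontally,
to smear eyelashes across the dark pupil), percentile-capped re-stretching
that pushes everything but the darkest structures to white, extraction of
locally dark pixels, removal of the lens outer ring, morphological opening
and closing with a circular element, and finally contour scoring: each
remaining connected region is convex-hulled and judged by roundness,
darkness, and size; the best-scoring candidate is taken as the pupil.

The frame label follows from the detection: no surviving candidate means the
eye is closed; a vertically squashed bounding box (height/width below a
threshold) means the lid is over the pupil, also closed; otherwise the label
is the region of the detected center under the annotation geometry.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import convex_hull_image

from .geometry import (
    AnnotationGeometry,
    DEFAULT_CENTRAL_RADIUS,
    DEFAULT_SIDE,
    EyeLabel,
    PupilObservation,
    assign_label,
)

__all__ = [
    "ESParams",
    "PupilDetection",
    "preprocess",
    "find_pupil_candidates",
    "select_pupil",
    "classify_frame",
    "scale_params",
]


@dataclass(frozen=True)
class ESParams:
    """Tunable constants of the rule pipeline, defined at a 520-px square.

    Pixel-denominated fields scale with the working resolution (see
    :func:`scale_params`); intensity thresholds do not.
    """

    base_side: int = 520
    mask_threshold: int = 80
    gaussian_kernel: Tuple[int, int] = (21, 9)  # (width, height), odd
    second_threshold_floor: int = 70
    second_threshold_percentile: float = 5.0
    adaptive_block: int = 9
    adaptive_offset: float = 5.0
    adaptive_dark_floor: float = 128.0
    ring_radius: float = 245.0
    morph_kernel: int = 21
    inscribed_radius_range: Tuple[float, float] = (20.0, 150.0)
    darkness_min: float = 50.0
    aspect_ratio_closed: float = 0.55

    def __post_init__(self) -> None:
        for k in (*self.gaussian_kernel, self.adaptive_block, self.morph_kernel):
            if k < 3 or k % 2 == 0:
                raise ValueError(f"kernel/block sizes must be odd and >= 3, got {k}")
        lo, hi = self.inscribed_radius_range
        if not (0 < lo < hi):
            raise ValueError(f"bad inscribed radius range {self.inscribed_radius_range}")
        if not (0 < self.ring_radius < self.base_side):
            raise ValueError(f"ring_radius {self.ring_radius} out of range")


@dataclass
class PupilDetection:
    """One pupil candidate: hull geometry plus its score components."""

    center: Tuple[float, float]
    bounding_box: Tuple[int, int, int, int]  # (x0, y0, width, height)
    hull: np.ndarray  # (N, 2) hull vertices, (x, y)
    circularity: float
    darkness: float  # inverted mean brightness inside the hull, in [0, 1]
    area: float  # hull area, px^2
    score: float = 0.0

    @property
    def aspect_ratio(self) -> float:
        """Bounding-box height over width."""
        _, _, w, h = self.bounding_box
        return h / w


def _stretch(img: np.ndarray) -> np.ndarray:
    """Min-max contrast stretch to [0, 255]; a constant image maps to 0."""
    lo = float(img.min())
    hi = float(img.max())
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def _gaussian_sigma(ksize: int) -> float:
    # sigma matched to the kernel size the way OpenCV derives it
    return 0.3 * ((ksize - 1) * 0.5 - 1.0) + 0.8


def _disk_erosion(mask: np.ndarray, radius: float) -> np.ndarray:
    if not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(mask) > radius


def _disk_dilation(mask: np.ndarray, radius: float) -> np.ndarray:
    if mask.all():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= radius


def _crop_square(frame: np.ndarray) -> np.ndarray:
    h, w = frame.shape
    side = min(h, w)
    x0 = (w - side) // 2
    y0 = (h - side) // 2
    return frame[y0:y0 + side, x0:x0 + side]


def preprocess(frame: np.ndarray, params: ESParams) -> Tuple[np.ndarray, np.ndarray]:
    """Stages 1-7: native frame to binary pupil-candidate mask.

    Returns ``(mask, reference)`` where ``reference`` is the percentile-
    capped, re-stretched grayscale used for darkness scoring.

    The locally-dark extraction combines the block-mean test (pixel darker
    than its 9x9 neighborhood mean by more than the offset) with an absolute
    dark floor on the reference: after the double stretch the image is close
    to bimodal, and the block-mean test alone only marks the boundary band
    of a dark region wider than the block, which the subsequent opening
    would erase.  A degenerate (contentless) reference yields an empty mask.
    """
    if frame.ndim != 2 or frame.dtype != np.uint8:
        raise ValueError("expected a 2-D uint8 grayscale frame")
    sq = _crop_square(frame)
    if sq.shape[0] != params.base_side:
        raise ValueError(
            f"frame square side {sq.shape[0]} does not match params side "
            f"{params.base_side}; rescale the frame or the params"
        )

    # 2: suppress background below the fixed threshold, then stretch
    f = sq.astype(np.float64)
    f[f < params.mask_threshold] = 0.0
    f = _stretch(f)

    # 3: anisotropic blur, wider horizontally
    kw, kh = params.gaussian_kernel
    f = ndi.gaussian_filter(f, sigma=(_gaussian_sigma(kh), _gaussian_sigma(kw)))

    # 4: cap at max(floor, 5th percentile of nonzero) and stretch again
    nz = f[f > 0]
    cap = params.second_threshold_floor if nz.size == 0 else max(
        params.second_threshold_floor,
        float(np.percentile(nz, params.second_threshold_percentile)),
    )
    reference = _stretch(np.minimum(f, cap))

    if reference.max() <= 0:
        return np.zeros_like(reference, dtype=bool), reference

    # 5: locally / absolutely dark pixels -> foreground
    local_mean = ndi.uniform_filter(reference, size=params.adaptive_block)
    mask = (reference < local_mean - params.adaptive_offset) | (
        reference <= params.adaptive_dark_floor
    )

    # 6: drop everything beyond the lens ring
    side = params.base_side
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    r2 = (xx + 0.5 - side / 2.0) ** 2 + (yy + 0.5 - side / 2.0) ** 2
    mask &= r2 <= params.ring_radius ** 2

    # 7: circular opening then closing; the closing can dilate back past the
    # ring cut, so the device's hard geometric limit is re-imposed at the end
    radius = (params.morph_kernel - 1) / 2.0
    mask = _disk_dilation(_disk_erosion(mask, radius), radius)
    mask = _disk_erosion(_disk_dilation(mask, radius), radius)
    mask &= r2 <= params.ring_radius ** 2
    return mask, reference


def find_pupil_candidates(
    mask: np.ndarray, reference: np.ndarray, params: ESParams
) -> List[PupilDetection]:
    """Hull and score every connected region that passes the size/darkness rules."""
    labeled, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    lo, hi = params.inscribed_radius_range
    out: List[PupilDetection] = []
    for sl, idx in zip(ndi.find_objects(labeled), range(1, n + 1)):
        if sl is None:
            continue
        region = labeled[sl] == idx
        y0, x0 = sl[0].start, sl[1].start
        h, w = region.shape
        inscribed = min(w, h) / 2.0
        if not (lo <= inscribed <= hi):
            continue
        ys, xs = np.nonzero(region)
        pts = np.column_stack([xs + x0 + 0.5, ys + y0 + 0.5]).astype(np.float64)
        try:
            hull = ConvexHull(pts)
        except QhullError:
            continue  # degenerate (collinear) region
        hull_pts = pts[hull.vertices]
        # rasterize the hull to score average brightness inside it
        hull_mask = _fill_hull(region, ys, xs)
        mean_ref = float(reference[sl][hull_mask].mean())
        darkness_raw = 255.0 - mean_ref
        if darkness_raw <= params.darkness_min:
            continue
        area = float(hull_mask.sum())
        perimeter = float(hull.area)  # 2-D ConvexHull.area is the perimeter
        circularity = min(1.0, 4.0 * math.pi * float(hull.volume) / perimeter ** 2)
        cy, cx = ndi.center_of_mass(hull_mask)
        out.append(
            PupilDetection(
                center=(cx + x0 + 0.5, cy + y0 + 0.5),
                bounding_box=(x0, y0, w, h),
                hull=hull_pts,
                circularity=circularity,
                darkness=darkness_raw / 255.0,
                area=area,
            )
        )
    return out


def _fill_hull(region: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Convex fill of a component inside its bounding box."""
    if region.sum() < 3:
        return region
    return convex_hull_image(region)


def select_pupil(candidates: List[PupilDetection]) -> Optional[PupilDetection]:
    """Pick the most circular, darkest, biggest candidate.

    Each criterion is min-max normalized across the candidate set (a single
    candidate, or a criterion with no spread, normalizes to 1) and the three
    terms are summed with equal weight.  Ties go to the larger area, then to
    the leftmost-topmost center.
    """
    if not candidates:
        return None

    def norm(values: List[float]) -> List[float]:
        lo, hi = min(values), max(values)
        if hi <= lo:
            return [1.0] * len(values)
        return [(v - lo) / (hi - lo) for v in values]

    nc = norm([c.circularity for c in candidates])
    nd = norm([c.darkness for c in candidates])
    na = norm([c.area for c in candidates])
    for c, a, b, d in zip(candidates, nc, nd, na):
        c.score = a + b + d
    best = max(
        candidates,
        key=lambda c: (c.score, c.area, -c.center[0], -c.center[1]),
    )
    return best


def classify_frame(
    frame: np.ndarray,
    params: Optional[ESParams] = None,
    geometry: Optional[AnnotationGeometry] = None,
) -> Tuple[EyeLabel, Optional[PupilDetection]]:
    """Full pipeline: frame in, (label, detection-or-None) out.

    Total over all 8-bit inputs: a frame with no surviving pupil candidate,
    or a candidate squashed below the closed aspect-ratio threshold, is
    labeled closed; otherwise the detected center is mapped through the
    annotation rules with the pupil treated as fully visible.
    """
    if params is None:
        params = ESParams()
    if geometry is None:
        geometry = AnnotationGeometry(
            side=params.base_side,
            central_radius=DEFAULT_CENTRAL_RADIUS * params.base_side / DEFAULT_SIDE,
        )
    mask, reference = preprocess(frame, params)
    best = select_pupil(find_pupil_candidates(mask, reference, params))
    if best is None:
        return EyeLabel.CLOSED, None
    if best.aspect_ratio < params.aspect_ratio_closed:
        return EyeLabel.CLOSED, best
    label = assign_label(PupilObservation(best.center, 1.0), geometry)
    return label, best


def _nearest_odd(x: float) -> int:
    return max(3, 2 * int(math.floor((x - 1.0) / 2.0 + 0.5)) + 1)


def scale_params(params: ESParams, new_side: int) -> ESParams:
    """Rescale pixel-denominated parameters to a new working square side.

    Kernel and block sizes are rounded to the nearest odd integer (floor 3);
    intensity thresholds are resolution-independent and stay unchanged.
    """
    if new_side <= 0:
        raise ValueError(f"new_side must be positive, got {new_side}")
    s = new_side / params.base_side
    kw, kh = params.gaussian_kernel
    lo, hi = params.inscribed_radius_range
    return dataclasses.replace(
        params,
        base_side=new_side,
        gaussian_kernel=(_nearest_odd(kw * s), _nearest_odd(kh * s)),
        adaptive_block=_nearest_odd(params.adaptive_block * s),
        morph_kernel=_nearest_odd(params.morph_kernel * s),
        ring_radius=params.ring_radius * s,
        inscribed_radius_range=(lo * s, hi * s),
    )
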