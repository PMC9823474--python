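"""Synthetic eye-frame generator with exact ground truth.

Emulates the imagery produced by an infrared, Maxwellian-view pupillometer:
an illuminated lens disc on a black background, a bright sclera, an iris
disc, a dark elliptical pupil, a ring of specular LED glints near the
pupil, eyelids with dark lash margins, smooth iris/sclera texture, an
illumination ramp, and additive sensor noise.  Every rendered frame
carries exact ground truth (pupil center, visible area fraction, six-class
label), so the generator doubles as its own annotator and replaces the
instrument's real recordings for testing.

The renderer is deterministic: a (scene, seed) pair always produces the
same 8-bit frame, and dataset generation fans a single master seed out to
per-frame seeds in a fixed order.
"""

from __future__ import annotations

import dataclasses
import functools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

from .geometry import (
    DEFAULT_CENTRAL_RADIUS,
    DEFAULT_SIDE,
    AnnotationGeometry,
    EyeLabel,
    LABEL_ORDER,
    PupilObservation,
    assign_label,
)

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "DatasetProfile",
    "GenerationError",
    "render_frame",
    "ground_truth",
    "sample_scene",
    "iter_frames",
    "generate_frames",
    "generate_dataset",
    "easy_suite",
    "crop_square",
]

#: supersampling factor for area integration of the visible pupil fraction
_SUPERSAMPLE = 4
#: eyelid modeled as a circular-arc occluder of this radius (pixels)
_LID_RADIUS = 500.0
#: Gaussian radius of a glint spot (pixels)
_GLINT_SIGMA = 1.5


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot realize a requested class."""


@dataclass(frozen=True)
class SceneSpec:
    """Full parametric description of one synthetic eye frame.

    All coordinates are native-frame continuous coordinates (x rightward,
    y downward, pixel (i, j) centered at (j+0.5, i+0.5)).  ``pupil_axes``
    are semi-axes; ``eyelid_coverage`` is the fraction of the pupil ellipse
    area hidden by the eyelid arc descending from the top of the frame.
    """

    frame_width: int = 772
    frame_height: int = 520
    lens_center: Tuple[float, float] = (386.0, 260.0)
    lens_radius: float = 250.0
    pupil_center: Tuple[float, float] = (386.0, 260.0)
    pupil_axes: Tuple[float, float] = (95.0, 95.0)  # dark-adapted (~5.8 mm) pupil
    pupil_intensity: int = 30
    iris_intensity: int = 125
    iris_radius: Optional[float] = None  # default 1.9x the larger pupil semi-axis
    sclera_intensity: int = 215
    skin_intensity: int = 180
    texture_amp: float = 15.0  # smooth iris/sclera texture amplitude, gray levels
    illumination_gradient: float = 0.06  # relative ramp across the lens, 0 at center
    glint_count: int = 8
    glint_ring_radius: Optional[float] = None
    eyelid_coverage: float = 0.0
    upper_lid_gap: Optional[float] = None  # lid apex above pupil top (px) when coverage 0
    lower_lid_gap: Optional[float] = None  # lower lid apex below pupil bottom (px)
    lid_line_intensity: int = 60  # dark lash margin along each lid edge
    lid_line_width: float = 4.0
    noise_sigma: float = 4.0
    lashes: bool = False

    def __post_init__(self) -> None:
        for name in (
            "pupil_intensity",
            "iris_intensity",
            "sclera_intensity",
            "skin_intensity",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must be an 8-bit level, got {v}")
        if self.pupil_intensity >= self.iris_intensity:
            raise ValueError("pupil must be darker than the iris")
        if not (0.0 <= self.eyelid_coverage <= 1.0):
            raise ValueError(f"eyelid_coverage must be in [0,1], got {self.eyelid_coverage}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for name in ("upper_lid_gap", "lower_lid_gap"):
            g = getattr(self, name)
            if g is not None and g <= 1.0:
                raise ValueError(f"{name} must exceed 1 px so the lid clears the pupil")
        a, b = self.pupil_axes
        if a <= 0 or b <= 0:
            raise ValueError("pupil semi-axes must be positive")
        dx = self.pupil_center[0] - self.lens_center[0]
        dy = self.pupil_center[1] - self.lens_center[1]
        # the ellipse itself may be clipped by the lens edge at extreme gaze
        if math.hypot(dx, dy) > self.lens_radius:
            raise ValueError("pupil center must lie within the lens disc")

    @property
    def glint_radius(self) -> float:
        """Glint-ring radius; defaults to 1.6x the larger pupil semi-axis."""
        if self.glint_ring_radius is not None:
            return self.glint_ring_radius
        return 1.6 * max(self.pupil_axes)

    @property
    def iris_disc_radius(self) -> float:
        """Iris radius; defaults to 1.9x the larger pupil semi-axis."""
        if self.iris_radius is not None:
            return self.iris_radius
        return 1.9 * max(self.pupil_axes)

    @property
    def crop_origin(self) -> Tuple[int, int]:
        """Top-left (x0, y0) of the centered square crop."""
        side = min(self.frame_width, self.frame_height)
        return (self.frame_width - side) // 2, (self.frame_height - side) // 2

    @property
    def crop_side(self) -> int:
        return min(self.frame_width, self.frame_height)

    def crop_geometry(self) -> AnnotationGeometry:
        """Labeling geometry matched to this frame's square crop."""
        side = self.crop_side
        return AnnotationGeometry(
            side=side, central_radius=DEFAULT_CENTRAL_RADIUS * side / DEFAULT_SIDE
        )

    def pupil_center_cropped(self) -> Tuple[float, float]:
        x0, y0 = self.crop_origin
        return self.pupil_center[0] - x0, self.pupil_center[1] - y0


@dataclass(frozen=True)
class GroundTruth:
    """Exact annotation of a synthetic frame (cropped coordinates)."""

    pupil_center: Tuple[float, float]
    visible_fraction: float
    label: EyeLabel


@dataclass(frozen=True)
class DatasetProfile:
    """Per-class frame counts for the train and test partitions."""

    train: Dict[EyeLabel, int] = field(default_factory=dict)
    test: Dict[EyeLabel, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for part in (self.train, self.test):
            for lab, n in part.items():
                if n < 0:
                    raise ValueError(f"negative count for {lab}: {n}")

    @classmethod
    def paper_like(cls, scale: float = 1.0) -> "DatasetProfile":
        """The instrument study's imbalanced train / balanced test split.

        ``scale`` < 1 shrinks every count proportionally (rounded, min 2
        for nonzero classes) for desk-scale experiments.
        """
        train_full = {
            EyeLabel.CORRECT: 7410,
            EyeLabel.CLOSED: 1040,
            EyeLabel.RIGHT: 586,
            EyeLabel.LEFT: 546,
            EyeLabel.UP: 629,
            EyeLabel.DOWN: 265,
        }
        train = {k: max(2, round(v * scale)) for k, v in train_full.items()}
        test = {k: max(2, round(750 * scale)) for k in LABEL_ORDER}
        if scale == 1.0:
            train = train_full
            test = {k: 750 for k in LABEL_ORDER}
        return cls(train=train, test=test)


# ---------------------------------------------------------------------------
# eyelid placement
# ---------------------------------------------------------------------------

def _lid_occluded(points_x: np.ndarray, points_y: np.ndarray, edge_y: float,
                  lid_cx: float) -> np.ndarray:
    """Mask of points hidden by the upper-lid arc whose apex is at edge_y."""
    cy = edge_y - _LID_RADIUS
    return (points_x - lid_cx) ** 2 + (points_y - cy) ** 2 <= _LID_RADIUS ** 2


def _lower_lid_region(points_x: np.ndarray, points_y: np.ndarray, edge_y: float,
                      lid_cx: float) -> np.ndarray:
    """Mask of points below the lower-lid arc whose apex is at edge_y."""
    cy = edge_y + _LID_RADIUS
    return (points_x - lid_cx) ** 2 + (points_y - cy) ** 2 <= _LID_RADIUS ** 2


def _upper_lid_edge(spec: SceneSpec) -> Optional[float]:
    """Apex of the upper occluder's lower boundary, or None if no upper lid.

    With nonzero coverage the apex is solved by bisection so the occluder
    (skin plus lash margin) hides exactly the requested pupil fraction; with
    zero coverage the lid rests ``upper_lid_gap`` above the pupil top.
    """
    if spec.eyelid_coverage > 0.0:
        return _solve_lid_edge(spec)
    if spec.upper_lid_gap is not None:
        return spec.pupil_center[1] - spec.pupil_axes[1] - spec.upper_lid_gap
    return None


@functools.lru_cache(maxsize=4)
def _pixel_grid(h: int, w: int) -> Tuple[np.ndarray, np.ndarray]:
    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)
    X += 0.5
    Y += 0.5
    X.setflags(write=False)
    Y.setflags(write=False)
    return X, Y


def _pupil_sample_points(
    spec: SceneSpec, n: int = _SUPERSAMPLE
) -> Tuple[np.ndarray, np.ndarray]:
    """Supersampled points inside the pupil ellipse (native coordinates)."""
    pcx, pcy = spec.pupil_center
    a, b = spec.pupil_axes
    xs = np.arange(math.floor(pcx - a), math.ceil(pcx + a))
    ys = np.arange(math.floor(pcy - b), math.ceil(pcy + b))
    sub = (np.arange(n) + 0.5) / n
    gx = (xs[:, None] + sub[None, :]).ravel()
    gy = (ys[:, None] + sub[None, :]).ravel()
    X, Y = np.meshgrid(gx, gy)
    inside = ((X - pcx) / a) ** 2 + ((Y - pcy) / b) ** 2 <= 1.0
    return X[inside], Y[inside]


@functools.lru_cache(maxsize=8192)
def _solve_lid_edge(spec: SceneSpec) -> float:
    """Apex height of the eyelid arc realizing the requested coverage."""
    px, py = _pupil_sample_points(spec, n=1)
    target = spec.eyelid_coverage
    lid_cx = spec.pupil_center[0]
    lo = float(py.min()) - 2.0
    hi = float(py.max()) + _LID_RADIUS - math.sqrt(
        max(_LID_RADIUS ** 2 - (np.abs(px - lid_cx).max()) ** 2, 0.0)
    ) + 2.0
    for _ in range(22):
        mid = 0.5 * (lo + hi)
        frac = float(_lid_occluded(px, py, mid, lid_cx).mean())
        if frac < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_frame(spec: SceneSpec, seed: int = 0) -> np.ndarray:
    """Render a scene to an 8-bit grayscale frame.

    Deterministic for a fixed (spec, seed).  With ``noise_sigma == 0`` all
    pixels outside the lens disc are exactly 0, and (for a pupil at the lens
    center, where the illumination ramp vanishes) the pupil interior sits
    exactly at ``pupil_intensity``.

    The eye seen through the lens is a bright sclera, a darker iris disc
    concentric with the pupil, and the near-black pupil ellipse; smooth
    random texture modulates iris and sclera, and a mild linear illumination
    ramp (zero at the lens center) varies the overall shading.
    """
    h, w = spec.frame_height, spec.frame_width
    X, Y = _pixel_grid(h, w)
    rng = np.random.default_rng(seed)

    lx, ly = spec.lens_center
    lens = (X - lx) ** 2 + (Y - ly) ** 2 <= spec.lens_radius ** 2

    img = np.zeros((h, w), dtype=np.float64)
    img[lens] = spec.sclera_intensity

    pcx, pcy = spec.pupil_center
    a, b = spec.pupil_axes
    iris = (X - pcx) ** 2 + (Y - pcy) ** 2 <= spec.iris_disc_radius ** 2
    img[iris & lens] = spec.iris_intensity

    # smooth blotchy texture on iris and sclera (crypts, furrows, vessels);
    # synthesized at quarter resolution since its correlation length is large
    if spec.texture_amp > 0:
        coarse = ndi.gaussian_filter(
            rng.normal(0.0, 1.0, size=(h // 4 + 2, w // 4 + 2)), sigma=3.0
        )
        blotch = ndi.zoom(coarse, 4.0, order=1)[:h, :w]
        blotch *= spec.texture_amp / max(blotch.std(), 1e-9)
        img[lens] += blotch[lens]

    pupil = ((X - pcx) / a) ** 2 + ((Y - pcy) / b) ** 2 <= 1.0
    img[pupil & lens] = spec.pupil_intensity

    # linear illumination ramp across the lens, vanishing at the lens center
    if spec.illumination_gradient > 0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        ramp = ((X - lx) * math.cos(theta) + (Y - ly) * math.sin(theta)) / spec.lens_radius
        img *= 1.0 + spec.illumination_gradient * ramp

    # specular glints on a ring around the pupil (corneal reflections)
    if spec.glint_count > 0:
        r = spec.glint_radius
        win = int(math.ceil(4.0 * _GLINT_SIGMA)) + 1
        for k in range(spec.glint_count):
            ang = 2.0 * math.pi * k / spec.glint_count - math.pi / 2.0
            gx = pcx + r * math.cos(ang)
            gy = pcy + r * math.sin(ang)
            i0, i1 = max(0, int(gy) - win), min(h, int(gy) + win + 1)
            j0, j1 = max(0, int(gx) - win), min(w, int(gx) + win + 1)
            if i0 >= i1 or j0 >= j1:
                continue
            d2 = (X[i0:i1, j0:j1] - gx) ** 2 + (Y[i0:i1, j0:j1] - gy) ** 2
            spot = d2 <= (4.0 * _GLINT_SIGMA) ** 2
            bump = 255.0 * np.exp(-d2 / (2.0 * _GLINT_SIGMA ** 2))
            bump[d2 <= 1.0] = 255.0
            patch = img[i0:i1, j0:j1]
            patch[spot] = np.maximum(patch[spot], bump[spot])

    # upper eyelid: skin descending from the top, dark lash margin at its edge
    edge_y = _upper_lid_edge(spec)
    if edge_y is not None:
        lid = _lid_occluded(X, Y, edge_y, pcx)
        skin = _lid_occluded(X, Y, edge_y - spec.lid_line_width, pcx)
        img[skin & lens] = spec.skin_intensity
        img[lid & ~skin & lens] = spec.lid_line_intensity
        if spec.lashes:
            rng_l = np.random.default_rng(seed + 1)
            for _ in range(6):
                xl = pcx + rng_l.uniform(-120, 120)
                streak = (np.abs(X - xl) <= 1.0) & (Y >= edge_y) & (Y <= edge_y + 35)
                img[streak & lens & ~lid] = 60.0

    # lower eyelid, kept clear of the pupil by construction
    if spec.lower_lid_gap is not None:
        low_edge = pcy + b + spec.lower_lid_gap
        low = _lower_lid_region(X, Y, low_edge, pcx)
        low_skin = _lower_lid_region(X, Y, low_edge + spec.lid_line_width, pcx)
        img[low_skin & lens] = spec.skin_intensity
        img[low & ~low_skin & lens] = spec.lid_line_intensity

    img[~lens] = 0.0

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def ground_truth(spec: SceneSpec) -> GroundTruth:
    """Exact annotation of a scene by area integration.

    The visible fraction is the share of the pupil ellipse area that is
    inside the lens disc and not under the eyelid, integrated by pixel
    counting on a 4x supersampled grid; the label follows the same rules a
    human annotator applies (see :mod:`eyeqc.geometry`).
    """
    px, py = _pupil_sample_points(spec)
    lx, ly = spec.lens_center
    visible = (px - lx) ** 2 + (py - ly) ** 2 <= spec.lens_radius ** 2
    edge_y = _upper_lid_edge(spec)
    if edge_y is not None:
        visible &= ~_lid_occluded(px, py, edge_y, spec.pupil_center[0])
    frac = float(visible.mean())
    center = spec.pupil_center_cropped()
    label = assign_label(PupilObservation(center, frac), spec.crop_geometry())
    return GroundTruth(pupil_center=center, visible_fraction=frac, label=label)


def crop_square(frame: np.ndarray) -> np.ndarray:
    """Centered square crop of a native frame (no-op if already square)."""
    h, w = frame.shape
    if w == h:
        return frame
    side = min(h, w)
    x0 = (w - side) // 2
    y0 = (h - side) // 2
    return frame[y0:y0 + side, x0:x0 + side]


# ---------------------------------------------------------------------------
# class-conditional scene sampling
# ---------------------------------------------------------------------------

#: central angle of each directional wedge (image coordinates, y down)
_WEDGE_ANGLE = {
    EyeLabel.RIGHT: 0.0,
    EyeLabel.DOWN: math.pi / 2.0,
    EyeLabel.LEFT: math.pi,
    EyeLabel.UP: -math.pi / 2.0,
}
#: keep sampled angles this far (radians) from the diagonals
_WEDGE_MARGIN = 0.12


def sample_scene(
    label: EyeLabel,
    rng: np.random.Generator,
    noise_sigma: float = 4.0,
    lashes: bool = False,
    boundary_margin: float = 0.05,
) -> SceneSpec:
    """Draw a random scene whose ground-truth label is ``label``.

    Coverage values are kept at least ``boundary_margin`` away from the
    visibility thresholds of the labeling rules, so rendered frames are
    unambiguous.  Uses rejection sampling against the exact ground truth;
    raises :class:`GenerationError` if a draw cannot be realized.
    """
    base = SceneSpec()
    gcx = base.lens_center[0]
    gcy = base.lens_center[1]
    for _ in range(200):
        # dark-adapted pupils are large: ~5.2-7 mm at ~32.5 px/mm
        a = rng.uniform(85.0, 115.0)
        b = a * rng.uniform(0.90, 1.05)
        appearance = dict(
            pupil_intensity=int(rng.integers(20, 46)),
            iris_intensity=int(rng.integers(105, 151)),
            sclera_intensity=int(rng.integers(195, 236)),
            skin_intensity=int(rng.integers(140, 221)),
            iris_radius=a * rng.uniform(1.7, 2.1),
            texture_amp=rng.uniform(6.0, 12.0),
            illumination_gradient=rng.uniform(0.0, 0.08),
            upper_lid_gap=rng.uniform(8.0, 45.0),
            # in a blink the upper lid closes down onto the lower lid, so the
            # lower lid hugs the covered pupil; in open-eye frames it sits lower
            lower_lid_gap=(
                rng.uniform(2.0, 12.0)
                if label is EyeLabel.CLOSED
                else rng.uniform(10.0, 60.0)
            ),
            lid_line_intensity=int(rng.integers(40, 76)),
            lid_line_width=rng.uniform(3.0, 6.0),
        )
        if label is EyeLabel.CORRECT:
            r = rng.uniform(0.0, 55.0)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            # visible > 0.90 required; stay boundary_margin clear of it
            coverage = rng.uniform(0.0, max(0.10 - boundary_margin, 0.01))
        elif label is EyeLabel.CLOSED:
            # blinks happen with the eye roughly on axis; strongly displaced
            # covered pupils are the rarer case
            if rng.random() < 0.7:
                r = rng.uniform(0.0, 55.0)
            else:
                r = rng.uniform(95.0, 120.0)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            coverage = rng.uniform(1.0 - 0.15 + boundary_margin + 0.02, 1.0)
        else:
            half = math.pi / 4.0 - _WEDGE_MARGIN
            ang = _WEDGE_ANGLE[label] + rng.uniform(-half, half)
            r = rng.uniform(110.0, 200.0)
            coverage = rng.uniform(0.0, 0.15 - boundary_margin - 0.02)
        pcx = gcx + r * math.cos(ang)
        pcy = gcy + r * math.sin(ang)
        if math.hypot(pcx - gcx, pcy - gcy) + max(a, b) > base.lens_radius - 2.0:
            continue
        spec = dataclasses.replace(
            base,
            pupil_center=(pcx, pcy),
            pupil_axes=(a, b),
            eyelid_coverage=coverage,
            noise_sigma=noise_sigma,
            lashes=lashes,
            **appearance,
        )
        if ground_truth(spec).label is label:
            return spec
    raise GenerationError(f"could not realize class {label.value!r} in 200 draws")


def iter_frames(
    counts: Dict[EyeLabel, int],
    seed: int,
    noise_sigma: float = 4.0,
    lashes: bool = False,
    boundary_margin: float = 0.05,
):
    """Lazily render a labeled frame set with the given class counts.

    Yields (frame, truth, spec, frame_seed) tuples, in class order then
    index order, all derived deterministically from the master seed.
    """
    rng = np.random.default_rng(seed)
    for label in LABEL_ORDER:
        for _ in range(counts.get(label, 0)):
            frame_seed = int(rng.integers(0, 2 ** 31))
            spec = sample_scene(
                label,
                rng,
                noise_sigma=noise_sigma,
                lashes=lashes,
                boundary_margin=boundary_margin,
            )
            frame = render_frame(spec, seed=frame_seed)
            yield frame, ground_truth(spec), spec, frame_seed


def generate_frames(
    counts: Dict[EyeLabel, int],
    seed: int,
    noise_sigma: float = 4.0,
    lashes: bool = False,
    boundary_margin: float = 0.05,
) -> List[Tuple[np.ndarray, GroundTruth, SceneSpec, int]]:
    """Eager list form of :func:`iter_frames`."""
    return list(
        iter_frames(
            counts,
            seed,
            noise_sigma=noise_sigma,
            lashes=lashes,
            boundary_margin=boundary_margin,
        )
    )


def easy_suite(
    n_per_class: int = 100, seed: int = 20221229, noise_sigma: float = 4.0
) -> List[Tuple[np.ndarray, GroundTruth, SceneSpec, int]]:
    """The fixed benchmark suite: n frames per class, no lashes, moderate noise,
    coverage kept well clear of the labeling-rule boundaries."""
    counts = {label: n_per_class for label in LABEL_ORDER}
    return generate_frames(counts, seed=seed, noise_sigma=noise_sigma, lashes=False)


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["path", "label", "cx", "cy", "visible_fraction", "seed"]


def generate_dataset(
    counts: Dict[EyeLabel, int],
    out_dir: Path,
    seed: int,
    partition: str = "test",
    noise_sigma: float = 4.0,
    lashes: bool = False,
) -> pd.DataFrame:
    """Write one PNG per frame plus a CSV manifest and a JSON sidecar.

    Fully reproducible from the master seed; the manifest records cropped
    pupil-center coordinates and the exact visible fraction per frame.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / partition
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (frame, truth, spec, fseed) in enumerate(
        iter_frames(counts, seed=seed, noise_sigma=noise_sigma, lashes=lashes)
    ):
        rel = f"{partition}/{truth.label.value}_{i:05d}.png"
        Image.fromarray(frame, mode="L").save(out_dir / rel)
        rows.append(
            {
                "path": rel,
                "label": truth.label.value,
                "cx": truth.pupil_center[0],
                "cy": truth.pupil_center[1],
                "visible_fraction": truth.visible_fraction,
                "seed": fseed,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / f"{partition}_manifest.csv", index=False)
    sidecar = {
        "partition": partition,
        "master_seed": seed,
        "noise_sigma": noise_sigma,
        "lashes": lashes,
        "counts": {k.value: int(v) for k, v in counts.items()},
    }
    (out_dir / f"{partition}_profile.json").write_text(json.dumps(sidecar, indent=2))
    return manifest
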