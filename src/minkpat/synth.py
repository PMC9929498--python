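"""Seeded generators for synthetic egg patterns and the painting manipulation.

Real eggs carry two marking morphologies: "scribbles" — long, thin,
curvilinear pigment lines — and "blotches" — compact, roughly convex spots.
This module draws both on a smooth egg-like background so that every
measurement stage of the package can be exercised with known ground truth:
marking masks, counts and areas are all available to the caller.

Scribbles are drawn by integrating a bounded-curvature random heading
(wrapped-normal angular increments) and dilating the resulting polyline to
the stroke width; blotches are rotated ellipses of bounded eccentricity.
``paint`` emulates the egg-manipulation experiment: compositing fresh
scribbles or blotches onto an existing egg image, with ``water`` as the
handling-only identity control.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from .preprocess import IntensityImage

__all__ = [
    "MarkingSpec",
    "generate_scribble",
    "generate_blotch",
    "match_area",
    "compose_egg",
    "paint",
    "egg_pair",
]


@dataclass
class MarkingSpec:
    """Parameters of a marking set.

    kind: ``scribble`` or ``blotch``; count: number of markings;
    stroke_width / radius in pixels; curvature_scale in radians per unit
    step (scribbles); intensity: the marking level in [0, 1].
    """

    kind: str = "scribble"
    count: int = 5
    stroke_width: int = 3
    radius: float = 8.0
    length: float = 120.0
    curvature_scale: float = 0.25
    max_eccentricity: float = 1.6
    intensity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("scribble", "blotch"):
            raise ValueError(f"unknown marking kind {self.kind!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.stroke_width < 1 or self.radius < 1:
            raise ValueError("stroke widths and radii must be >= 1 px")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_scribble(
    canvas: tuple[int, int],
    length: float = 120.0,
    stroke_width: int = 3,
    curvature_scale: float = 0.25,
    seed=0,
    margin: int = 6,
) -> np.ndarray:
    """Draw one smooth random stroke as a boolean mask.

    The pen integrates a heading whose increments are N(0, curvature_scale²)
    per half-pixel step, which bounds curvature and biases the stroke away
    from self-crossing; headings reflect off the canvas margin.  The path is
    then dilated to ``stroke_width`` with a disc structuring element, so the
    painted area is close to length x width.
    """
    h, w = canvas
    if min(h, w) <= 2 * margin + stroke_width:
        raise ValueError("canvas too small for the requested stroke")
    rng = _rng(seed)
    step = 0.5
    n_steps = max(2, int(round(length / step)))
    y = rng.uniform(margin + stroke_width, h - margin - stroke_width)
    x = rng.uniform(margin + stroke_width, w - margin - stroke_width)
    theta = rng.uniform(0, 2 * np.pi)
    mask = np.zeros(canvas, dtype=bool)
    for _ in range(n_steps):
        mask[int(round(y)) % h, int(round(x)) % w] = True
        theta += rng.normal(0.0, curvature_scale) * step
        dy, dx = np.sin(theta) * step, np.cos(theta) * step
        # reflect the heading off the margins to stay on canvas
        if not (margin < y + dy < h - margin):
            theta = -theta
            dy = -dy
        if not (margin < x + dx < w - margin):
            theta = np.pi - theta
            dx = -dx
        y += dy
        x += dx
    r = max(0, (stroke_width - 1) // 2)
    if r > 0:
        mask = binary_dilation(mask, structure=disk(r))
    return mask


def generate_blotch(
    canvas: tuple[int, int],
    radius: float = 8.0,
    max_eccentricity: float = 1.6,
    seed=0,
    margin: int = 6,
) -> np.ndarray:
    """Draw one compact elliptical blotch of equivalent-circle ``radius``.

    The ellipse axes are radius·s and radius/s with the axis ratio s drawn
    uniformly in [1, max_eccentricity] and a uniform orientation, so the
    area stays near π·radius² regardless of elongation.
    """
    h, w = canvas
    rng = _rng(seed)
    s = np.sqrt(rng.uniform(1.0, max_eccentricity))
    a, b = radius * s, radius / s
    pad = int(np.ceil(max(a, b))) + margin
    if h <= 2 * pad or w <= 2 * pad:
        raise ValueError("canvas too small for the requested blotch")
    cy = rng.uniform(pad, h - pad)
    cx = rng.uniform(pad, w - pad)
    rot = rng.uniform(0, np.pi)
    mask = np.zeros(canvas, dtype=bool)
    rr, cc = draw_ellipse(cy, cx, a, b, shape=canvas, rotation=rot)
    mask[rr, cc] = True
    return mask


def match_area(
    scribbles: Sequence[np.ndarray],
    count: int = 10,
    canvas: Optional[tuple[int, int]] = None,
    max_eccentricity: float = 1.6,
    seed=0,
    tol: float = 0.05,
    max_iter: int = 25,
) -> List[np.ndarray]:
    """Generate ``count`` blotches whose summed area matches the scribbles'.

    Starts from the closed-form radius sqrt(total/(count·π)) and iteratively
    corrects for digitisation until the blotch total is within ``tol``
    (relative) of the scribble total.  Returns an empty list for zero
    scribble area; raises if the tolerance is unreachable.
    """
    total = int(sum(int(np.asarray(m, dtype=bool).sum()) for m in scribbles))
    if total == 0 or count == 0:
        if total > 0:
            raise ValueError("cannot match positive area with zero blotches")
        return []
    if canvas is None:
        canvas = np.asarray(scribbles[0], dtype=bool).shape
    rng = _rng(seed)
    radius = float(np.sqrt(total / (count * np.pi)))
    if radius < 1:
        raise ValueError("target area too small for the requested blotch count")
    for _ in range(max_iter):
        sub = rng.spawn(1)[0]
        blotches = [
            generate_blotch(canvas, radius=radius, max_eccentricity=max_eccentricity, seed=sub)
            for _ in range(count)
        ]
        got = sum(int(b.sum()) for b in blotches)
        if abs(got - total) <= tol * total:
            return blotches
        radius *= float(np.sqrt(total / max(got, 1)))
    raise ValueError(
        f"could not match area {total} px with {count} blotches to within {tol:.0%}"
    )


def _elliptical_roi(shape: tuple[int, int], fill: float = 0.92) -> np.ndarray:
    """Egg-shaped (elliptical) region of interest filling most of the frame."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = fill * h / 2.0, fill * w / 2.0
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def compose_egg(
    canvas: tuple[int, int] = (120, 160),
    markings: Sequence[tuple[np.ndarray, float]] = (),
    background: float = 0.2,
    background_variation: float = 0.05,
    noise_sd: float = 0.02,
    seed=0,
    roi: bool = True,
) -> IntensityImage:
    """Assemble a synthetic egg image in the marking-intensity convention.

    A smooth low-frequency background (heavily blurred noise around the
    ``background`` level) is overlaid with each marking mask at its stated
    intensity (via max, so overlapping markings do not add), then Gaussian
    pixel noise is applied and the result clipped to [0, 1].  An elliptical
    ROI plays the role of the egg outline; its long axis runs along the
    larger canvas dimension with the "blunt pole" on the low-index side.
    """
    rng = _rng(seed)
    h, w = canvas
    field = np.full(canvas, background, dtype=float)
    if background_variation > 0:
        low = gaussian_filter(rng.normal(0.0, 1.0, canvas), sigma=min(h, w) / 6.0, mode="reflect")
        denom = max(float(np.abs(low).max()), 1e-12)
        field += background_variation * low / denom
    for mask, intensity in markings:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != canvas:
            raise ValueError(f"marking shape {mask.shape} != canvas {canvas}")
        field = np.where(mask, np.maximum(field, intensity), field)
    if noise_sd > 0:
        field = field + rng.normal(0.0, noise_sd, canvas)
    field = np.clip(field, 0.0, 1.0)
    mask = _elliptical_roi(canvas) if roi else None
    if mask is not None:
        field = np.where(mask, field, 0.0)
    long_axis = "horizontal" if w >= h else "vertical"
    meta = {
        "source": "synthetic",
        "inverted": True,  # already in marking-intensity convention
        "sigma": 0.0,
        "degenerate": False,
        "long_axis": long_axis,
        "blunt_pole": "low",
        "n_markings": len(markings),
        "marking_area": int(sum(np.asarray(m, bool).sum() for m, _ in markings)),
    }
    return IntensityImage(pixels=field, mask=mask, meta=meta)


def paint(
    img: IntensityImage,
    kind: str = "scribbles",
    count: Optional[int] = None,
    paint_intensity: float = 0.8,
    stroke_width: int = 3,
    length: float = 120.0,
    radius: float = 6.0,
    seed=0,
) -> IntensityImage:
    """Apply one of the three egg-manipulation treatments to an image.

    ``scribbles`` composites ``count`` (default 5) fresh scribbles at
    ``paint_intensity``; ``blotches`` composites ``count`` (default 10)
    blotches; ``water`` is the handling-only control and leaves the pixels
    untouched.  The treatment is recorded in the metadata.
    """
    if kind == "water":
        return img.with_pixels(img.pixels.copy(), treatment="water")
    if kind not in ("scribbles", "blotches"):
        raise ValueError(f"unknown treatment kind {kind!r}")
    if count is None:
        count = 5 if kind == "scribbles" else 10
    rng = _rng(seed)
    out = img.pixels.copy()
    painted = np.zeros(img.shape, dtype=bool)
    for _ in range(count):
        sub = rng.spawn(1)[0]
        if kind == "scribbles":
            m = generate_scribble(img.shape, length=length, stroke_width=stroke_width, seed=sub)
        else:
            m = generate_blotch(img.shape, radius=radius, seed=sub)
        painted |= m
    if img.mask is not None:
        painted &= img.mask
    out = np.where(painted, np.maximum(out, paint_intensity), out)
    return img.with_pixels(out, treatment=kind, painted_area=int(painted.sum()))


def egg_pair(
    seed=0,
    canvas: tuple[int, int] = (120, 160),
    n_scribbles: int = 5,
    n_blotches: int = 10,
    length: float = 120.0,
    stroke_width: int = 3,
    intensity: float = 0.8,
    noise_sd: float = 0.02,
) -> tuple[IntensityImage, IntensityImage]:
    """A matched (scribbled egg, blotched egg) pair of equal total marking area.

    The blotched member's markings are area-matched to the scribbled
    member's via :func:`match_area`, mirroring the experimental design of
    painting blotches "totalling approximately the same area" as the
    scribbles.
    """
    rng = _rng(seed)
    s_seed, b_seed, c1, c2 = rng.spawn(4)
    scribbles = [
        generate_scribble(canvas, length=length, stroke_width=stroke_width, seed=s)
        for s in s_seed.spawn(n_scribbles)
    ]
    blotches = match_area(scribbles, count=n_blotches, canvas=canvas, seed=b_seed)
    scribbled = compose_egg(canvas, [(m, intensity) for m in scribbles], noise_sd=noise_sd, seed=c1)
    blotched = compose_egg(canvas, [(m, intensity) for m in blotches], noise_sd=noise_sd, seed=c2)
    return scribbled, blotched
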