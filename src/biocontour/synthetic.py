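"""Deterministic synthetic stimuli with exact boundary ground truth.

These parametric fixtures stand in for natural-image benchmarks at desk
scale: oriented gratings (tuning probes), textured squares (a salient
region boundary embedded in disorderly oriented-bar texture), isoluminant
colour edges (chromatic boundary with zero luminance gradient), two-tone
luminance edges, and cluttered multi-shape scenes. Generation is a pure
function of the spec: same spec, bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.draw import line_aa

from .core import BoundaryGT, validate_rgb_image

#: luminance weights shared with the surround-statistics stage
LUMA = np.array([0.299, 0.587, 0.114])

DEFAULT_BAR_DENSITY = 0.08
DEFAULT_BAR_LENGTH = 7


@dataclass(frozen=True)
class StimulusSpec:
    """Recipe for one stimulus; generation is a pure function of this record."""

    kind: str
    size: tuple[int, int] = (64, 64)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _to_rgb(grey: np.ndarray) -> np.ndarray:
    return np.stack([grey, grey, grey], axis=-1)


def _empty_gt(shape: tuple[int, int]) -> BoundaryGT:
    return BoundaryGT(maps=[np.zeros(shape)])


def make_grating(spec: StimulusSpec) -> tuple[np.ndarray, BoundaryGT]:
    """Achromatic sinusoidal grating; pure texture, so the ground truth is empty.

    ``orientation`` is the stripe direction: the image is invariant under
    translation along it, and luminance varies along the perpendicular.
    Coordinates are centred so the central pixel sits on a zero crossing
    (maximal gradient), which makes it a convenient tuning-probe site.
    """
    h, w = spec.size
    p = spec.params
    orientation = float(p.get("orientation", 0.0))
    frequency = float(p.get("frequency", 0.1))
    contrast = float(p.get("contrast", 1.0))
    if not (0.0 < frequency < 0.5):
        raise ValueError(f"frequency must lie in (0, 0.5) cycles/pixel, got {frequency}")
    if not (0.0 <= orientation < np.pi):
        raise ValueError(f"orientation must lie in [0, π), got {orientation}")
    if not (0.0 <= contrast <= 1.0):
        raise ValueError("contrast must lie in [0, 1]")
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    x -= w // 2
    y -= h // 2
    # coordinate along the stripe normal (perpendicular to `orientation`)
    u = -x * np.sin(orientation) + y * np.cos(orientation)
    grey = 0.5 + 0.5 * contrast * np.sin(2.0 * np.pi * frequency * u)
    img = validate_rgb_image(_to_rgb(np.clip(grey, 0.0, 1.0)))
    return img, _empty_gt((h, w))


def _bar_texture(
    shape: tuple[int, int],
    angle: float,
    rng: np.random.Generator,
    density: float,
    bar_length: int,
    amplitude: float = 0.25,
    background: float = 0.5,
) -> np.ndarray:
    """Anti-aliased oriented bars on a mid-grey background.

    Bars sit on a jittered grid (one element per cell, uniform jitter),
    the standard construction for orientation-contrast texture stimuli:
    it keeps the element density spatially uniform, so first- and
    second-order luminance statistics match between regions that differ
    only in element orientation. ``density`` is the target fraction of
    pixels covered by bars.
    """
    h, w = shape
    canvas = np.full(shape, background, dtype=np.float64)
    n_target = max(1, density * h * w / bar_length)
    cell = max(1.0, np.sqrt(h * w / n_target))
    half = bar_length / 2.0
    dy, dx = np.sin(angle) * half, np.cos(angle) * half
    edges_y = np.arange(0, h, cell)
    edges_x = np.arange(0, w, cell)
    for ey in edges_y:
        for ex in edges_x:
            cy = ey + rng.uniform(0, cell)
            cx = ex + rng.uniform(0, cell)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            r0, c0 = int(round(cy - dy)), int(round(cx - dx))
            r1, c1 = int(round(cy + dy)), int(round(cx + dx))
            rr, cc, val = line_aa(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            canvas[rr[keep], cc[keep]] += sign * amplitude * val[keep]
    return np.clip(canvas, 0.0, 1.0)


def make_textured_square(spec: StimulusSpec) -> tuple[np.ndarray, BoundaryGT]:
    """Oriented-bar texture at θ_in inside a centred square, θ_out outside.

    The only true boundary is the orientation-defined square perimeter
    (one pixel wide, 4·side − 4 foreground pixels); the bars themselves
    are texture to be suppressed.
    """
    h, w = spec.size
    p = spec.params
    theta_in = float(p.get("theta_in", np.pi / 2))
    theta_out = float(p.get("theta_out", 0.0))
    side = int(p.get("side", min(h, w) // 2))
    density = float(p.get("density", DEFAULT_BAR_DENSITY))
    bar_length = int(p.get("bar_length", DEFAULT_BAR_LENGTH))
    if np.isclose((theta_in - theta_out) % np.pi, 0.0, atol=1e-9):
        raise ValueError("theta_in and theta_out must differ (mod π): no boundary exists")
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    if r0 < 8 or c0 < 8 or r0 + side > h - 8 or c0 + side > w - 8:
        raise ValueError("square must fit with an 8-pixel margin")
    rng = spec.rng()
    outside = _bar_texture((h, w), theta_out, rng, density, bar_length)
    inside = _bar_texture((h, w), theta_in, rng, density, bar_length)
    grey = outside.copy()
    grey[r0 : r0 + side, c0 : c0 + side] = inside[r0 : r0 + side, c0 : c0 + side]
    mask = np.zeros((h, w))
    mask[r0, c0 : c0 + side] = 1
    mask[r0 + side - 1, c0 : c0 + side] = 1
    mask[r0 : r0 + side, c0] = 1
    mask[r0 : r0 + side, c0 + side - 1] = 1
    return validate_rgb_image(_to_rgb(grey)), BoundaryGT(maps=[mask])


def _luminance(colour: np.ndarray) -> float:
    return float(np.dot(LUMA, colour))


def match_luminance(colour_a, colour_b) -> tuple[np.ndarray, np.ndarray]:
    """Rescale ``colour_b`` so both colours share the greyscale luminance of ``colour_a``.

    Raises if the match would leave the [0, 1] gamut.
    """
    a = np.asarray(colour_a, dtype=np.float64)
    b = np.asarray(colour_b, dtype=np.float64)
    ya, yb = _luminance(a), _luminance(b)
    if yb <= 0:
        raise ValueError("second colour has zero luminance; cannot match")
    b_matched = b * (ya / yb)
    if b_matched.max() > 1.0 or b_matched.min() < 0.0:
        raise ValueError("luminance match leaves the [0, 1] gamut")
    return a, b_matched


def make_isoluminant_edge(spec: StimulusSpec) -> tuple[np.ndarray, BoundaryGT]:
    """Left/right halves in two luminance-matched colours: a purely chromatic edge.

    The greyscale projection (0.299 R + 0.587 G + 0.114 B) is constant to
    1e−6, so any response along the midline is attributable to colour
    opponency alone. Ground truth is the first column of the right half
    (exactly H foreground pixels).
    """
    h, w = spec.size
    p = spec.params
    left = p.get("left_colour", (0.60, 0.25, 0.25))
    right = p.get("right_colour", (0.25, 0.45, 0.25))
    a, b = match_luminance(left, right)
    img = np.empty((h, w, 3), dtype=np.float64)
    mid = w // 2
    img[:, :mid] = a
    img[:, mid:] = b
    mask = np.zeros((h, w))
    mask[:, mid] = 1
    return validate_rgb_image(img), BoundaryGT(maps=[mask])


def make_two_tone_edge(spec: StimulusSpec) -> tuple[np.ndarray, BoundaryGT]:
    """Achromatic luminance step edge down the vertical midline."""
    h, w = spec.size
    p = spec.params
    dark = float(p.get("dark", 0.25))
    bright = float(p.get("bright", 0.75))
    grey = np.full((h, w), dark)
    mid = w // 2
    grey[:, mid:] = bright
    mask = np.zeros((h, w))
    mask[:, mid] = 1
    return validate_rgb_image(_to_rgb(grey)), BoundaryGT(maps=[mask])


def make_cluttered_scene(spec: StimulusSpec) -> tuple[np.ndarray, BoundaryGT]:
    """2–4 textured/coloured rectangles on a textured background.

    Ground truth is the union of rectangle perimeters; an end-to-end smoke
    stimulus rather than a calibrated probe.
    """
    h, w = spec.size
    p = spec.params
    n_shapes = int(p.get("n_shapes", 3))
    density = float(p.get("density", DEFAULT_BAR_DENSITY))
    bar_length = int(p.get("bar_length", DEFAULT_BAR_LENGTH))
    if not (2 <= n_shapes <= 4):
        raise ValueError("n_shapes must lie in [2, 4]")
    rng = spec.rng()
    base = _to_rgb(_bar_texture((h, w), 0.0, rng, density, bar_length))
    mask = np.zeros((h, w))
    angles = np.pi * np.array([0.25, 0.5, 0.75, 0.4])
    for i in range(n_shapes):
        sh = int(rng.integers(min(h, w) // 5, min(h, w) // 3))
        sw = int(rng.integers(min(h, w) // 5, min(h, w) // 3))
        r0 = int(rng.integers(2, h - sh - 2))
        c0 = int(rng.integers(2, w - sw - 2))
        if i % 2 == 0:
            patch = _to_rgb(
                _bar_texture((sh, sw), angles[i], rng, density, bar_length)
            )
        else:
            a, b = match_luminance((0.60, 0.25, 0.25), (0.25, 0.45, 0.25))
            patch = np.broadcast_to(b if i == 1 else a, (sh, sw, 3)).copy()
        base[r0 : r0 + sh, c0 : c0 + sw] = patch
        mask[r0, c0 : c0 + sw] = 1
        mask[r0 + sh - 1, c0 : c0 + sw] = 1
        mask[r0 : r0 + sh, c0] = 1
        mask[r0 : r0 + sh, c0 + sw - 1] = 1
    return validate_rgb_image(np.clip(base, 0.0, 1.0)), BoundaryGT(maps=[mask])


_GENERATORS: dict[str, Callable[[StimulusSpec], tuple[np.ndarray, BoundaryGT]]] = {
    "grating": make_grating,
    "textured_square": make_textured_square,
    "isoluminant_edge": make_isoluminant_edge,
    "two_tone_edge": make_two_tone_edge,
    "cluttered_scene": make_cluttered_scene,
}


def generate(spec: StimulusSpec) -> tuple[np.ndarray, BoundaryGT]:
    """Dispatch on ``spec.kind``."""
    try:
        gen = _GENERATORS[spec.kind]
    except KeyError:
        raise ValueError(
            f"unknown stimulus kind {spec.kind!r}; choose from {sorted(_GENERATORS)}"
        ) from None
    return gen(spec)
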