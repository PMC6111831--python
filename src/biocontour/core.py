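"""Shared numeric conventions and domain containers.

Coordinate convention used throughout the package: row-major arrays with
origin at the top-left, ``x`` running rightward along columns, ``y``
downward along rows, and angles measured from the +x axis toward +y.
All filtering is implemented as correlation (kernels are not flipped)
with reflect padding, so constant fields are fixed points of every
smoothing kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "convolve2d",
    "gaussian_kernel",
    "rescale_unit",
    "orientation_grid",
    "OrientationStack",
    "OpponentSet",
    "BoundaryGT",
    "validate_rgb_image",
]

MIN_IMAGE_SIDE = 16


def validate_rgb_image(img: np.ndarray) -> np.ndarray:
    """Validate an H×W×3 raster with values in [0, 1] and return it as float64.

    The side-length floor guarantees that every kernel in the cascade fits
    inside the image.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 array, got shape {img.shape}")
    if img.shape[0] < MIN_IMAGE_SIDE or img.shape[1] < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image must be at least {MIN_IMAGE_SIDE}×{MIN_IMAGE_SIDE}, got {img.shape[:2]}"
        )
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return img


def convolve2d(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlate ``field`` with ``kernel`` under reflect padding.

    Same-shape output; linear in the input. Kernels must have odd side
    lengths so the output is not shifted.
    """
    field = np.asarray(field, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2:
        raise ValueError("kernel must be 2-D")
    if kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValueError(f"kernel sides must be odd, got {kernel.shape}")
    if field.ndim != 2:
        raise ValueError("field must be 2-D")
    return ndimage.correlate(field, kernel, mode="reflect")


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Isotropic Gaussian, truncated at 3σ and renormalised to sum exactly 1."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    kernel = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    return kernel / kernel.sum()


def rescale_unit(field: np.ndarray) -> np.ndarray:
    """Divide a non-negative field by its global maximum.

    Fields whose peak is at numerical-noise level (≤ 1e−12; genuine
    responses on [0, 1] imagery are orders of magnitude larger) are
    returned as exact zeros rather than amplified — the "white wall"
    case must stay silent through every stage.
    """
    peak = float(np.max(field))
    if peak <= 1e-12:
        return np.zeros_like(field, dtype=np.float64)
    return np.asarray(field, dtype=np.float64) / peak


def orientation_grid(n: int) -> np.ndarray:
    """The N preferred directions θ_i = (i−1)·2π/N, i = 1…N."""
    if n < 2:
        raise ValueError("need at least 2 orientations")
    return np.arange(n) * (2.0 * np.pi / n)


@dataclass(frozen=True)
class OrientationStack:
    """H×W×N non-negative response tensor with its orientation list."""

    values: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        orientations = np.asarray(self.orientations, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "orientations", orientations)
        if values.ndim != 3:
            raise ValueError("values must be H×W×N")
        n = values.shape[2]
        if orientations.shape != (n,):
            raise ValueError("orientation list length must match stack depth")
        if n < 2:
            raise ValueError("need at least 2 orientations")
        step = 2.0 * np.pi / n
        expected = np.arange(n) * step
        if not np.allclose(orientations, expected, atol=1e-9):
            raise ValueError("orientations must be evenly spaced over [0, 2π)")
        if not np.all(np.isfinite(values)):
            raise ValueError("stack contains non-finite values")
        if values.min() < 0.0:
            raise ValueError("stack values must be non-negative (post-rectification)")

    @property
    def n_orientations(self) -> int:
        return self.values.shape[2]

    def argmax_orientation(self) -> np.ndarray:
        """Per-pixel preferred direction (the argmax slice's angle)."""
        return self.orientations[np.argmax(self.values, axis=2)]


@dataclass(frozen=True)
class OpponentSet:
    """The four rectified single-opponent fields: on/off pairs of r-g and b-y."""

    rg: np.ndarray  # r-on / g-off
    gr: np.ndarray  # r-off / g-on
    by: np.ndarray  # b-on / y-off
    yb: np.ndarray  # b-off / y-on

    def __post_init__(self) -> None:
        shape = None
        for name in ("rg", "gr", "by", "yb"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            object.__setattr__(self, name, arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {name} must be 2-D")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all opponent channels must share a shape")
            if arr.min() < 0.0:
                raise ValueError(f"channel {name} must be non-negative")

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"rg": self.rg, "gr": self.gr, "by": self.by, "yb": self.yb}

    @property
    def shape(self) -> tuple[int, int]:
        return self.rg.shape


@dataclass(frozen=True)
class BoundaryGT:
    """One or more annotator boundary masks plus their consensus mean."""

    maps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("need at least one annotator mask")
        cleaned = []
        shape = None
        for mask in self.maps:
            arr = np.asarray(mask, dtype=np.float64)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("annotator masks must share a shape")
            if not np.all((arr == 0.0) | (arr == 1.0)):
                raise ValueError("annotator masks must be strictly {0, 1}")
            cleaned.append(arr)
        object.__setattr__(self, "maps", cleaned)

    @property
    def consensus(self) -> np.ndarray:
        """Arithmetic mean over annotators, in [0, 1]."""
        return np.mean(np.stack(self.maps, axis=0), axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps[0].shape
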