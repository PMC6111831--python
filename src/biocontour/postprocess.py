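"""Contour thinning and binarisation: non-maxima suppression along the
edge normal and Canny-style quantile hysteresis.

The non-binarised (NMS-only) output is the default for evaluation;
hysteresis is an optional final step exposing the candidate-edge ratio p
and the low/high threshold ratio.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import filters

from .core import OrientationStack

#: offsets for the 8 quantised normal directions, as (dy, dx)
_EIGHT_DIRS = [
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
]


def _suppress_along(field: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Keep pixels that are ≥ both neighbours along the quantised normal."""
    h, w = field.shape
    padded = np.pad(field, 1, mode="constant")
    idx = np.round(normal / (np.pi / 4)).astype(int) % 8
    out = np.zeros_like(field)
    yy, xx = np.mgrid[0:h, 0:w]
    for k, (dy, dx) in enumerate(_EIGHT_DIRS):
        sel = idx == k
        if not sel.any():
            continue
        fwd = padded[1 + yy[sel] + dy, 1 + xx[sel] + dx]
        bwd = padded[1 + yy[sel] - dy, 1 + xx[sel] - dx]
        vals = field[sel]
        keep = (vals >= fwd) & (vals >= bwd)
        out[yy[sel][keep], xx[sel][keep]] = vals[keep]
    return out


def non_maxima_suppress(
    cd: np.ndarray, orientation_stack: OrientationStack | None = None
) -> np.ndarray:
    """Thin a contour response across the edge normal.

    With an orientation stack the per-pixel normal is the stack's argmax
    direction; without one it is estimated from the Sobel gradient of the
    response itself. A pixel survives iff its value is ≥ both
    nearest-neighbour values along the normal (8-connectivity
    quantisation); ties survive, so an ideal one-pixel ridge is unchanged
    and plateaus are left for hysteresis to resolve.
    """
    cd = np.asarray(cd, dtype=np.float64)
    if orientation_stack is not None:
        if orientation_stack.values.shape[:2] != cd.shape:
            raise ValueError("stack shape must match the contour map")
        normal = orientation_stack.argmax_orientation()
    else:
        gy = filters.sobel_h(cd)
        gx = filters.sobel_v(cd)
        normal = np.arctan2(gy, gx)
    return _suppress_along(cd, normal)


def hysteresis_binarise(
    thinned: np.ndarray, p: float, low_ratio: float = 0.4
) -> np.ndarray:
    """Two-threshold binarisation seeded by the strongest fraction p of pixels.

    The high threshold is the (1−p)-quantile of the positive values, the
    low one ``low_ratio`` times that; weak pixels survive only in
    8-connected components containing a strong pixel. Output is a strict
    {0, 1} mask.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if not (0.0 < low_ratio <= 1.0):
        raise ValueError("low_ratio must lie in (0, 1]")
    thinned = np.asarray(thinned, dtype=np.float64)
    if thinned.min() < 0:
        raise ValueError("thinned response must be non-negative")
    positives = thinned[thinned > 0]
    if positives.size == 0:
        return np.zeros_like(thinned)
    high = float(np.quantile(positives, 1.0 - p))
    low = low_ratio * high
    strong = thinned >= high
    weak = (thinned >= low) & (thinned > 0)
    labels, n_labels = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        return np.zeros_like(thinned)
    keep = np.zeros(n_labels + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return keep[labels].astype(np.float64)
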