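"""Image and boundary-map readers/writers.

PNG/PPM/JPEG in, PNG out (8-bit, or 16-bit for response maps). Ground
truth arrives either as PNG binary masks or whitespace-separated 0/1 text
matrices; multiple annotators are multiple files sharing a stem.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import BoundaryGT, validate_rgb_image

_GT_SUFFIXES = (".png", ".txt")


def read_image(path: str | Path) -> np.ndarray:
    """Read a raster to an H×W×3 float64 array in [0, 1].

    Greyscale inputs are replicated to three identical channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError, SyntaxError, RuntimeError) as exc:
        # Pillow signals truncated PNGs with SyntaxError; fold every
        # decoder failure into one I/O error with the path attached
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"image {path} is empty")
    arr = np.asarray(raw)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float64) / scale
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        arr = np.stack([arr, arr, arr], axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    arr = np.clip(arr, 0.0, 1.0)
    return validate_rgb_image(arr)


def write_image(path: str | Path, field: np.ndarray, bit_depth: int = 8) -> None:
    """Write a field (2-D in [0,1] or H×W×3) as an 8- or 16-bit PNG."""
    field = np.asarray(field, dtype=np.float64)
    if field.min() < 0.0 or field.max() > 1.0:
        raise ValueError("values must lie in [0, 1] before quantisation")
    if bit_depth == 8:
        out = np.round(field * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(field * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), out)


def _read_single_mask(path: Path) -> np.ndarray:
    if path.suffix == ".txt":
        mask = np.loadtxt(path)
    else:
        raw = iio.imread(path)
        arr = np.asarray(raw)
        if arr.ndim == 3:
            arr = arr[..., 0]
        if np.issubdtype(arr.dtype, np.integer):
            mask = (arr.astype(np.float64) > np.iinfo(arr.dtype).max / 2).astype(float)
        else:
            mask = (arr > 0.5).astype(float)
    mask = np.asarray(mask, dtype=np.float64)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"mask {path} is not strictly binary (values {uniq[:5]})")
    return mask


def read_boundary_gt(stem_or_path: str | Path) -> BoundaryGT:
    """Load one or several annotator masks.

    ``stem_or_path`` may be a single mask file or a stem: every file named
    ``<stem>*.png`` / ``<stem>*.txt`` is read as one annotator.
    """
    p = Path(stem_or_path)
    if p.is_file():
        return BoundaryGT(maps=[_read_single_mask(p)])
    candidates = sorted(
        q
        for q in p.parent.glob(p.name + "*")
        if q.suffix in _GT_SUFFIXES and q.is_file()
    )
    if not candidates:
        raise IOError(f"no ground-truth files matching stem {stem_or_path}")
    return BoundaryGT(maps=[_read_single_mask(q) for q in candidates])


def write_boundary_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a strict {0,1} mask as an 8-bit PNG (0/255)."""
    mask = np.asarray(mask, dtype=np.float64)
    if not np.all((mask == 0.0) | (mask == 1.0)):
        raise ValueError("mask must be strictly {0, 1}")
    iio.imwrite(Path(path), (mask * 255).astype(np.uint8))
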