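"""Non-classical receptive field (NCRF) surround-modulation weights.

The annular surround, 2–5× the CRF diameter, inhibits the centre response
in proportion to how similar the surround is to the centre: similar
luminance, contrast and colour-orientation statistics mark disorderly
texture (suppress), dissimilar ones mark a region boundary (retain). Four
cues are computed: a distance weight (rectified difference-of-Gaussians
annulus W_d), luminance and contrast similarity weights (W_L, W_C from
local statistics under a raised-cosine window), and a colour-orientation
similarity weight (W_θ from centre vs surround weighted orientation-vector
means).
"""

from __future__ import annotations

import numpy as np

from .core import OrientationStack, convolve2d, gaussian_kernel, validate_rgb_image
from .synthetic import LUMA

#: floor for the L² denominator of the contrast statistic in dark regions
_DARK_GUARD = 1e-4


def dog_plus_kernel(sigma: float, rho: float, strict: bool = False) -> np.ndarray:
    """Distance weight W_d: rectified DoG annulus, L1-normalised to sum 1.

    ⌊G(ρσ) − G(σ)⌋ pointwise: zero at the centre (where the narrow
    Gaussian dominates), a positive ring peaking in the surround, then a
    decaying tail. Requires ρ > 1 for the annulus to exist; ``strict``
    lifts that check so the degenerate printed ρ = 0.4 variant (a centre
    blob, not a surround) can be demonstrated.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not strict and rho <= 1.0:
        raise ValueError(f"rho must exceed 1 for an annular surround, got {rho}")
    radius = int(np.ceil(3.0 * max(sigma, rho * sigma)))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(np.float64)
    r2 = x * x + y * y
    wide = np.exp(-r2 / (2.0 * (rho * sigma) ** 2)) / (2.0 * np.pi * (rho * sigma) ** 2)
    narrow = np.exp(-r2 / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    dog = np.maximum(wide - narrow, 0.0)
    total = dog.sum()
    if total <= 0:
        raise ValueError("degenerate DoG: no positive surround mass")
    return dog / total


def raised_cosine_window(window_size: int) -> np.ndarray:
    """Raised-cosine window w = (cos(πr/R) + 1)/2 with R = (size−1)/2 + 1.

    Centre value 1, zero at and beyond radius R (the corners).
    """
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError("window_size must be odd and >= 3")
    half = (window_size - 1) // 2
    r_max = half + 1.0
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    r = np.sqrt(x * x + y * y)
    window = np.where(r < r_max, (np.cos(np.pi * r / r_max) + 1.0) / 2.0, 0.0)
    return window


def _rescale01(field: np.ndarray) -> np.ndarray:
    """Linear min-max rescale; a constant field maps to zero by convention."""
    lo, hi = float(field.min()), float(field.max())
    if hi - lo <= 0.0:
        return np.zeros_like(field)
    return (field - lo) / (hi - lo)


def local_statistics(
    img: np.ndarray, window: np.ndarray, rescale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Local luminance L and luminance contrast C under the window.

    L = (1/η)·I∗w with I the greyscale projection and η the window sum;
    C = (1/η)·((I − L)²/L²)∗w with L² floored in dark regions. Both are
    then linearly rescaled to [0, 1] over the image (a constant field
    rescales to zero); ``rescale=False`` returns the raw statistics.
    """
    img = validate_rgb_image(img)
    eta = window.sum()
    grey = img @ LUMA
    lum = convolve2d(grey, window) / eta
    dev = (grey - lum) ** 2 / np.maximum(lum * lum, _DARK_GUARD)
    contrast = convolve2d(dev, window) / eta
    if not rescale:
        return lum, contrast
    return _rescale01(lum), _rescale01(contrast)


def _similarity_weight(feature: np.ndarray, wd_kernel: np.ndarray, scale: float) -> np.ndarray:
    """Σ_surround exp(−(F(x,y) − F(x_i,y_i))²/(2·scale²)) · W_d(offset).

    A bilateral-style accumulation over the annulus support, vectorised
    per offset; reflect padding matches the convolution convention.
    """
    h, w = feature.shape
    radius = wd_kernel.shape[0] // 2
    padded = np.pad(feature, radius, mode="reflect")
    out = np.zeros_like(feature)
    inv = 1.0 / (2.0 * scale * scale)
    ys, xs = np.nonzero(wd_kernel)
    for ky, kx in zip(ys, xs):
        shifted = padded[ky : ky + h, kx : kx + w]
        diff = feature - shifted
        out += wd_kernel[ky, kx] * np.exp(-(diff * diff) * inv)
    return out


def feature_modulation_weights(
    lum: np.ndarray,
    contrast: np.ndarray,
    wd_kernel: np.ndarray,
    sigma1: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Luminance and contrast surround-similarity weights W_L, W_C ∈ (0, 1].

    Each is a W_d-weighted (convex) combination of Gaussian similarities
    between the centre's statistic and every surround point's statistic;
    uniform inputs give exactly 1 (maximal suppression weight).
    """
    if sigma1 <= 0:
        raise ValueError("sigma1 must be positive")
    w_l = _similarity_weight(np.asarray(lum, dtype=np.float64), wd_kernel, sigma1)
    w_c = _similarity_weight(np.asarray(contrast, dtype=np.float64), wd_kernel, sigma1)
    return w_l, w_c


def orientation_difference(
    theta_stack: OrientationStack,
    sigma: float,
    wd_kernel: np.ndarray,
    sigma2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Centre-surround colour-orientation difference Δθ and weight W_θ.

    Per orientation i, the centre mean is the Gaussian(σ)-weighted local
    average of the colour-orientation response and the surround mean is
    its W_d-weighted average; Δθ is the Euclidean norm over the
    N-dimensional per-pixel difference vector and
    W_θ = exp(−Δθ²/(2σ2²)) ∈ (0, 1]. Uniform texture gives Δθ = 0 and
    maximal suppression weight 1.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    g = gaussian_kernel(sigma)
    sq_sum = np.zeros(theta_stack.values.shape[:2])
    for i in range(theta_stack.n_orientations):
        slice_i = theta_stack.values[:, :, i]
        centre = convolve2d(slice_i, g)
        surround = convolve2d(slice_i, wd_kernel)
        sq_sum += (centre - surround) ** 2
    delta_theta = np.sqrt(sq_sum)
    w_theta = np.exp(-(delta_theta**2) / (2.0 * sigma2 * sigma2))
    return delta_theta, w_theta
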