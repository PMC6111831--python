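"""V2 stage: orientation-elongated elliptical pooling of V1 responses and
the single-pass feedforward + feedback combination.

V2 "slender type" receptive fields integrate collinear edge evidence: each
channel's normalised V1 field is pooled with an elliptical Gaussian whose
long axis (scale σ′, default 2σ) lies along the local edge tangent — the
direction perpendicular to the per-pixel argmax filter normal. The edge
map then combines the feedforward channel sum with a one-shot feedback
term, the per-pixel maximum over channels (global shape reinforcing local
contours).
"""

from __future__ import annotations

import numpy as np

from .core import convolve2d, rescale_unit
from .params import ModelParams
from .v1 import V1Response


def elliptical_kernel(
    theta: float,
    sigma: float,
    sigma_prime: float,
    printed_form: bool = False,
) -> np.ndarray:
    """Rotated elliptical Gaussian, short axis σ along θ, long axis σ′ across.

    f(x, y) = exp(−(a x² − 2 b x y + c y²)) with
      a = cos²θ/(2σ²) + sin²θ/(2σ′²)
      b = −sin 2θ/(4σ²) + sin 2θ/(4σ′²)
      c = sin²θ/(2σ²) + cos²θ/(2σ′²)

    which is exactly exp(−(x̃²/2σ² + ỹ²/2σ′²)) for x̃ along θ. The
    ``printed_form`` flag swaps c for the dimensionally inconsistent
    product variant c = sin²θ/(2σ²)·cos²θ/(2σ′²), retained only so the
    discrepancy is demonstrable; it is never used by the pipeline.
    Kernel is renormalised to sum 1.
    """
    if sigma <= 0 or sigma_prime <= 0:
        raise ValueError("scales must be positive")
    ct, st = np.cos(theta), np.sin(theta)
    s2 = np.sin(2.0 * theta)
    a = ct * ct / (2 * sigma**2) + st * st / (2 * sigma_prime**2)
    b = -s2 / (4 * sigma**2) + s2 / (4 * sigma_prime**2)
    if printed_form:
        c = (st * st / (2 * sigma**2)) * (ct * ct / (2 * sigma_prime**2))
    else:
        c = st * st / (2 * sigma**2) + ct * ct / (2 * sigma_prime**2)
    radius = int(np.ceil(3.0 * max(sigma, sigma_prime)))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(np.float64)
    kernel = np.exp(-(a * x * x - 2.0 * b * x * y + c * y * y))
    return kernel / kernel.sum()


def v2_pool(v1: V1Response, params: ModelParams) -> dict[str, np.ndarray]:
    """Pool each channel's complex-cell field along its local edge tangent.

    Pixels are quantised into the N orientation classes by the argmax of
    the channel's simple-cell stack; for class θ* the ellipse's short axis
    is along θ* (the edge normal), elongating the pooling along the
    contour. Implemented as per-class masked convolutions.
    """
    sigma = v1.sigma
    sigma_prime = params.sigma_prime_at(sigma)
    pooled: dict[str, np.ndarray] = {}
    kernels: dict[int, np.ndarray] = {}
    for name, d_field in v1.d.items():
        stack = v1.stacks[name]
        class_idx = np.argmax(stack.values, axis=2)
        out = np.zeros_like(d_field)
        for i, theta in enumerate(stack.orientations):
            mask = class_idx == i
            if not mask.any():
                continue
            if i not in kernels:
                kernels[i] = elliptical_kernel(theta, sigma, sigma_prime)
            out[mask] = convolve2d(d_field, kernels[i])[mask]
        pooled[name] = np.maximum(out, 0.0)
    return pooled


def combine_feedforward_feedback(
    v2: dict[str, np.ndarray], feedback: bool = True, rescale: bool = True
) -> np.ndarray:
    """Edge map D = Σ_channel V2_channel (+ max_channel V2_channel feedback).

    The feedback max is taken per pixel and applied exactly once. The
    result is rescaled to [0, 1] by its global maximum so the two scales
    of the hierarchy are compared on a common footing.
    """
    expected = {"rg", "gr", "by", "yb"}
    if set(v2) != expected:
        raise ValueError(f"need all four channels {sorted(expected)}, got {sorted(v2)}")
    fields = [np.asarray(v2[name], dtype=np.float64) for name in sorted(expected)]
    d = np.sum(fields, axis=0)
    if feedback:
        d = d + np.maximum.reduce(fields)
    return rescale_unit(d) if rescale else d
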