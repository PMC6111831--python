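"""Multi-scale guided combination: the full two-scale hierarchy, the
surround-weight fusion, and the final inhibited contour response.

The LGN→V1→V2 cascade is run at a fine scale σ and a coarse scale 2σ,
each edge map normalised to [0, 1]. Inside texture regions the blurred
coarse map fills the gaps between texture elements and exceeds the
sparse fine map, so a non-negative coarse-minus-fine energy difference
marks internal texture: there the strongest (max) of the three surround
weights is applied, elsewhere the weakest (min). The fused weight field
gates a subtractive surround inhibition of the fine-scale edge response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import convolve2d, rescale_unit, validate_rgb_image
from .lgn import single_opponent
from .params import ModelParams
from .surround import (
    dog_plus_kernel,
    feature_modulation_weights,
    local_statistics,
    orientation_difference,
    raised_cosine_window,
)
from .v1 import V1Response, colour_orientation_map, v1_response
from .v2 import combine_feedforward_feedback, v2_pool


@dataclass(frozen=True)
class ScalePair:
    """Fine/coarse edge responses, each in [0, 1], and their energy difference.

    ``delta`` = coarse − fine. With each scale normalised by its own
    maximum, the blurred coarse map fills the gaps between texture
    elements and so dominates the sparse fine map inside texture regions
    (delta ≥ 0 ⇒ suppress), while salient contours keep localised
    fine-scale peaks (delta < 0 ⇒ retain).
    """

    fine: np.ndarray
    coarse: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.coarse - self.fine


def run_hierarchy(
    img: np.ndarray,
    params: ModelParams,
    sigma: float | None = None,
    no_v2: bool = False,
    no_feedback: bool = False,
    return_v1: bool = False,
):
    """LGN → V1 → V2 cascade at one scale; returns the [0, 1] edge map.

    Ablations: ``no_v2`` stops at V1 and sums the channel responses;
    ``no_feedback`` drops the per-pixel channel-max feedback term.
    With ``return_v1`` the (edge map, V1Response) pair is returned so the
    caller can reuse the orientation stacks.
    """
    img = validate_rgb_image(img)
    if sigma is None:
        sigma = params.sigma
    opp = single_opponent(img, params, sigma)
    v1 = v1_response(opp, sigma, params)
    if no_v2:
        d = rescale_unit(np.sum([v1.d[name] for name in sorted(v1.d)], axis=0))
    else:
        pooled = v2_pool(v1, params)
        d = combine_feedforward_feedback(pooled, feedback=not no_feedback)
    return (d, v1) if return_v1 else d


def combine_weights(
    w_theta: np.ndarray,
    w_l: np.ndarray,
    w_c: np.ndarray,
    delta_d: np.ndarray,
) -> np.ndarray:
    """Multi-scale guided fusion of the three surround weights.

    W = max(W_θ, W_L, W_C) where the coarse-minus-fine energy difference
    is ≥ 0 (texture: suppress hard), else min(W_θ, W_L, W_C) (contour:
    suppress gently). The tie ΔD = 0 takes the max branch.
    """
    shapes = {np.shape(a) for a in (w_theta, w_l, w_c, delta_d)}
    if len(shapes) != 1:
        raise ValueError("all weight fields must share a shape")
    hi = np.maximum.reduce([w_theta, w_l, w_c])
    lo = np.minimum.reduce([w_theta, w_l, w_c])
    return np.where(delta_d >= 0.0, hi, lo)


def final_contour(
    d_fine: np.ndarray,
    weight: np.ndarray,
    wd_kernel: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Inhibited contour response CD = ⌊D − α·W·(D ∗ W_d)⌋.

    The annular W_d pools fine-scale energy from the surround; the fused
    weight W gates how much of it is subtracted, and α scales the texture
    attenuation overall. Half-wave rectification keeps CD ≥ 0, and CD is
    pointwise non-increasing in α.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    inhibition = alpha * weight * convolve2d(d_fine, wd_kernel)
    return np.maximum(d_fine - inhibition, 0.0)


def detect(
    img: np.ndarray,
    params: ModelParams | None = None,
    no_v2: bool = False,
    no_feedback: bool = False,
    no_multiscale: bool = False,
    return_intermediates: bool = False,
):
    """Full contour detection on an RGB image.

    Runs the hierarchy at σ and 2σ, computes the surround weights at the
    fine scale, fuses them under multi-scale guidance, and applies the
    final surround inhibition. ``no_multiscale`` drops the scale guidance
    and applies max(W_θ, W_L, W_C) everywhere.

    Returns the contour response CD (H×W, in [0, 1]); with
    ``return_intermediates`` also a dict of the stage outputs.
    """
    if params is None:
        params = ModelParams()
    img = validate_rgb_image(img)
    fine, v1_fine = run_hierarchy(
        img, params, params.sigma, no_v2=no_v2, no_feedback=no_feedback, return_v1=True
    )
    coarse = run_hierarchy(
        img,
        params,
        params.scale_factor * params.sigma,
        no_v2=no_v2,
        no_feedback=no_feedback,
    )
    pair = ScalePair(fine=fine, coarse=coarse)

    wd = dog_plus_kernel(params.sigma, params.rho_dog)
    window = raised_cosine_window(params.window_size)
    lum, contrast = local_statistics(img, window)
    w_l, w_c = feature_modulation_weights(lum, contrast, wd, params.sigma1)
    theta_stack = colour_orientation_map(v1_fine.stacks)
    delta_theta, w_theta = orientation_difference(
        theta_stack, params.sigma, wd, params.sigma2
    )
    if no_multiscale:
        weight = np.maximum.reduce([w_theta, w_l, w_c])
    else:
        weight = combine_weights(w_theta, w_l, w_c, pair.delta)
    cd = final_contour(pair.fine, weight, wd, params.alpha)
    if not return_intermediates:
        return cd
    intermediates = {
        "fine": fine,
        "coarse": coarse,
        "delta": pair.delta,
        "L": lum,
        "C": contrast,
        "W_L": w_l,
        "W_C": w_c,
        "W_theta": w_theta,
        "delta_theta": delta_theta,
        "W": weight,
        "v1_fine": v1_fine,
        "theta_stack": theta_stack,
        "wd_kernel": wd,
    }
    return cd, intermediates
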