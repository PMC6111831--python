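"""Retina/LGN stage: single-opponent, spatially low-pass colour responses.

The retina and LGN are merged into one layer (their receptive fields are
qualitatively alike). Each opponent channel combines a Gaussian-smoothed
excitatory cone input with a weighted (w ∈ [−1, 0]) antagonist input:

    U_rg = I_r ∗ G(σ) + w · I_g ∗ G(σ)
    U_by = I_b ∗ G(σ) + w · I_y ∗ G(σ),   I_y = (I_r + I_g) / 2

and the signed field is split into a half-wave-rectified on/off cell pair
(r-on/g-off vs r-off/g-on, likewise for blue-yellow), because firing
rates are non-negative.
"""

from __future__ import annotations

import numpy as np

from .core import OpponentSet, convolve2d, gaussian_kernel, validate_rgb_image
from .params import ModelParams


def single_opponent(
    img: np.ndarray, params: ModelParams, sigma: float | None = None
) -> OpponentSet:
    """Single-opponent LGN responses of an RGB image at scale ``sigma``.

    Parameters
    ----------
    img : H×W×3 array in [0, 1]
    params : ModelParams (uses ``w``)
    sigma : CRF scale; defaults to ``params.sigma``

    Returns
    -------
    OpponentSet with the four rectified channels {rg, gr, by, yb}.
    """
    img = validate_rgb_image(img)
    if sigma is None:
        sigma = params.sigma
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (-1.0 <= params.w <= 0.0):
        raise ValueError("w must lie in [-1, 0]")
    g = gaussian_kernel(sigma)
    i_r, i_g, i_b = img[..., 0], img[..., 1], img[..., 2]
    i_y = 0.5 * (i_r + i_g)
    u_rg = convolve2d(i_r, g) + params.w * convolve2d(i_g, g)
    u_by = convolve2d(i_b, g) + params.w * convolve2d(i_y, g)
    return OpponentSet(
        rg=np.maximum(u_rg, 0.0),
        gr=np.maximum(-u_rg, 0.0),
        by=np.maximum(u_by, 0.0),
        yb=np.maximum(-u_by, 0.0),
    )


def opponent_identity_check(opp: OpponentSet) -> bool:
    """True iff the on/off pairs are never simultaneously active at a pixel."""
    return bool(np.all(opp.rg * opp.gr == 0.0) and np.all(opp.by * opp.yb == 0.0))
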