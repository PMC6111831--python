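"""V1 stage: oriented simple cells, double-opponent wiring, complex-cell
MAX pooling and self-normalisation.

The simple-cell receptive field is the first derivative (along its
preferred direction θ) of an anisotropic Gaussian with aspect ratio λ and
width kσ. Each double-opponent channel feeds the on-lobe of the kernel
with its on-centre opponent input and the off-lobe with the off-centre
input; responses stay non-negative throughout (half-wave rectification).
Complex cells take the MAX over orientations, then a global squared
self-normalisation bounds responses to [0, 1) while guarding the
"white wall" zero-energy case with a floor ε.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import OpponentSet, OrientationStack, convolve2d, orientation_grid
from .params import ModelParams

#: on-channel → off-channel pairing of the double-opponent wiring
_OPPONENT_PAIRS = {"rg": "gr", "gr": "rg", "by": "yb", "yb": "by"}


@dataclass(frozen=True)
class V1Response:
    """Complex-cell fields and pre-normalisation stacks per opponent channel."""

    d: dict  # channel -> H×W normalised complex-cell field, in [0, 1)
    stacks: dict  # channel -> OrientationStack of simple-cell responses
    sigma: float


def v1_simple_kernel(theta: float, sigma: float, params: ModelParams) -> np.ndarray:
    """Oriented derivative-of-Gaussian simple-cell kernel.

    V(x, y) = −x̃/(k²σ²) · f(x, y) with f the rotated anisotropic Gaussian
    (x̃ along θ, aspect λ, width kσ). Odd in x̃ on the symmetric grid, so
    entries sum to zero exactly up to rounding.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ks = params.k * sigma
    radius = int(np.ceil(3.0 * ks))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(np.float64)
    xt = x * np.cos(theta) + y * np.sin(theta)
    yt = -x * np.sin(theta) + y * np.cos(theta)
    f = (
        1.0
        / (2.0 * np.pi * ks * ks)
        * np.exp(-(xt * xt + (params.aspect * yt) ** 2) / (2.0 * ks * ks))
    )
    return -(xt / (params.k * params.k * sigma * sigma)) * f


def double_opponent_stack(
    opp: OpponentSet, sigma: float, params: ModelParams, n_orient: int | None = None
) -> dict[str, OrientationStack]:
    """Simple-cell response stacks E_co(x, y, θ_i) for all four channels.

    The on-subfield of the double-opponent receptive field receives the
    on-centre opponent input and the off-subfield the off-centre input,
    so the drive for channel ``co`` with off-partner ``co'`` is the signed
    filtering (S_co − S_co') ∗ V(θ_i), half-wave rectified into a firing
    rate. Because S_co − S_co' is the signed opponent field, the opposite
    polarity appears in the θ_i + π slice, and structureless (constant)
    input drives no simple cell at all — which is what lets the ε floor
    of the later normalisation handle the "white wall" case as intended.
    """
    n = params.n_orient if n_orient is None else n_orient
    thetas = orientation_grid(n)
    h, w = opp.shape
    signed = {"rg": opp.rg - opp.gr, "by": opp.by - opp.yb}
    raw = {name: np.empty((h, w, n)) for name in _OPPONENT_PAIRS}
    for i, theta in enumerate(thetas):
        v = v1_simple_kernel(theta, sigma, params)
        for pair, off_name in (("rg", "gr"), ("by", "yb")):
            drive = convolve2d(signed[pair], v)
            raw[pair][:, :, i] = np.maximum(drive, 0.0)
            raw[off_name][:, :, i] = np.maximum(-drive, 0.0)
    return {
        name: OrientationStack(values=vals, orientations=thetas)
        for name, vals in raw.items()
    }


def max_pool(stack: OrientationStack) -> np.ndarray:
    """Complex-cell MAX pooling over orientations."""
    if stack.values.shape[2] == 0:
        raise ValueError("empty orientation stack")
    return stack.values.max(axis=2)


def normalise_response(field: np.ndarray, eps: float) -> np.ndarray:
    """Squared self-normalisation D = Ẽ²/(max Ẽ² + ε), globally per field.

    Bounds the output to [0, 1); an all-zero field (the white-wall case)
    passes through as zeros with no division error.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    field = np.asarray(field, dtype=np.float64)
    if field.min() < 0.0:
        raise ValueError("normalisation input must be non-negative")
    sq = field * field
    return sq / (sq.max() + eps)


def v1_response(opp: OpponentSet, sigma: float, params: ModelParams) -> V1Response:
    """Full V1 stage: stacks → MAX pooling → self-normalisation per channel."""
    stacks = double_opponent_stack(opp, sigma, params)
    d = {
        name: normalise_response(max_pool(stack), params.eps)
        for name, stack in stacks.items()
    }
    return V1Response(d=d, stacks=stacks, sigma=sigma)


def colour_orientation_map(stacks: dict[str, OrientationStack]) -> OrientationStack:
    """Colour-orientation responses: per-orientation max over the four channels."""
    missing = set(_OPPONENT_PAIRS) - set(stacks)
    if missing:
        raise ValueError(f"missing opponent channel(s): {sorted(missing)}")
    ref = stacks["rg"]
    for name, stack in stacks.items():
        if stack.values.shape != ref.values.shape or not np.allclose(
            stack.orientations, ref.orientations
        ):
            raise ValueError("stacks must share shape and orientation list")
    values = np.maximum.reduce([stacks[name].values for name in _OPPONENT_PAIRS])
    peak = values.max()
    if peak > 0:
        # put the colour-orientation responses on a [0, 1] footing so the
        # centre-surround difference Δθ lives on the scale of σ2
        values = values / peak
    return OrientationStack(values=values, orientations=ref.orientations)


def tuning_profile(
    img: np.ndarray,
    pixel: tuple[int, int],
    params: ModelParams,
    n_probe: int = 36,
) -> list[tuple[float, float]]:
    """Per-orientation normalised V1 response at one pixel (polar-plot probe).

    Runs the LGN and simple-cell stages with ``n_probe`` orientations,
    normalises each channel's stack by its global squared maximum, and
    returns, per probe direction, the maximum over opponent channels.
    """
    from .lgn import single_opponent  # local import avoids a module cycle

    row, col = pixel
    h, w = img.shape[:2]
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError(f"pixel {pixel} outside image of shape {(h, w)}")
    opp = single_opponent(img, params)
    stacks = double_opponent_stack(opp, params.sigma, params, n_orient=n_probe)
    profile = np.zeros(n_probe)
    for stack in stacks.values():
        sq = stack.values**2
        norm = sq / (sq.max() + params.eps)
        profile = np.maximum(profile, norm[row, col, :])
    thetas = orientation_grid(n_probe)
    return [(float(t), float(r)) for t, r in zip(thetas, profile)]
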