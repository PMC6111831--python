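"""Model parameters, validated in one record.

Every constant of the cascade lives here so a run is reproducible from a
single YAML snapshot. Defaults follow the reference operating point of the
model: a classical-receptive-field (CRF) scale of 1.1 px, a V1/LGN size
ratio k = 2, receptive-field aspect λ = 0.5, six preferred orientations,
a non-classical surround four times the CRF diameter, and the tuned free
parameters w = −0.8 (retina→ganglion cone weight) and α = 1.0 (texture
attenuation factor).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class ModelParams:
    #: retina→ganglion weight of the antagonist cone input, in [−1, 0]
    w: float = -0.8
    #: CRF scale σ in pixels (fine scale of the two-scale hierarchy)
    sigma: float = 1.1
    #: V1/LGN receptive-field size ratio
    k: float = 2.0
    #: receptive-field aspect ratio λ (width-to-length of the V1 simple cell)
    aspect: float = 0.5
    #: number of preferred orientations N over [0, 2π)
    n_orient: int = 6
    #: NCRF/CRF diameter ratio ρ of the rectified difference-of-Gaussians surround
    rho_dog: float = 4.0
    #: side of the raised-cosine local-statistics window, odd, in pixels
    window_size: int = 11
    #: luminance/contrast surround-attenuation scale σ1
    sigma1: float = 0.05
    #: colour-orientation surround-attenuation scale σ2
    sigma2: float = 0.2
    #: texture attenuation factor α multiplying the surround-inhibition term
    alpha: float = 1.0
    #: normalisation floor ε guarding the white-wall (zero-energy) case
    eps: float = 1e-8
    #: V2 ellipse long-axis scale σ′; None means 2σ (2:1 elongation)
    sigma_prime: float | None = None
    #: coarse/fine scale ratio of the two-scale hierarchy
    scale_factor: float = 2.0
    #: boundary-matching distance for P/R, in pixels; None means 0.0075·diagonal
    eval_tolerance: float | None = None
    #: hysteresis candidate-edge pixel ratio p
    hysteresis_p: float = 0.1
    #: low/high hysteresis threshold ratio
    hysteresis_low_ratio: float = 0.4

    def __post_init__(self) -> None:
        if not (-1.0 <= self.w <= 0.0):
            raise ValueError(f"w must lie in [-1, 0], got {self.w}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.aspect <= 0:
            raise ValueError("aspect must be positive")
        if self.n_orient < 2:
            raise ValueError("n_orient must be at least 2")
        if self.rho_dog <= 1.0:
            raise ValueError("rho_dog must exceed 1 (the surround is an annulus)")
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ValueError("window_size must be odd and >= 3")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.sigma_prime is not None and self.sigma_prime <= 0:
            raise ValueError("sigma_prime must be positive")
        if self.scale_factor <= 1.0:
            raise ValueError("scale_factor must exceed 1")
        if not (0.0 < self.hysteresis_p < 1.0):
            raise ValueError("hysteresis_p must lie in (0, 1)")

    def sigma_prime_at(self, sigma: float) -> float:
        """V2 ellipse long-axis scale at pipeline scale ``sigma``.

        When σ′ is left unset the elongation is 2:1 at every scale; an
        explicit σ′ is interpreted at the fine scale and scaled
        proportionally at the coarse one.
        """
        if self.sigma_prime is None:
            return 2.0 * sigma
        return self.sigma_prime * (sigma / self.sigma)

    def matching_tolerance(self, shape: tuple[int, int]) -> float:
        """Pixel tolerance for boundary matching (0.0075·diagonal by default)."""
        if self.eval_tolerance is not None:
            return self.eval_tolerance
        h, w = shape
        return 0.0075 * float((h * h + w * w) ** 0.5)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
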