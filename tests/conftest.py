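"""Shared fixtures: model parameters and the canonical synthetic stimuli.

Expensive pipeline runs are session-scoped so geography and suppression
properties reuse one detect pass.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import biocontour as bc


@pytest.fixture(scope="session")
def params() -> bc.ModelParams:
    return bc.ModelParams()


@pytest.fixture(scope="session")
def textured_square_96():
    """Canonical textured-square stimulus: 96×96, seed 0, default texture."""
    spec = bc.StimulusSpec(kind="textured_square", size=(96, 96), seed=0)
    return bc.generate(spec)


@pytest.fixture(scope="session")
def cluttered_96():
    spec = bc.StimulusSpec(kind="cluttered_scene", size=(96, 96), seed=0)
    return bc.generate(spec)


@pytest.fixture(scope="session")
def isoluminant_64():
    spec = bc.StimulusSpec(kind="isoluminant_edge", size=(64, 64), seed=0)
    return bc.generate(spec)


@pytest.fixture(scope="session")
def detect_textured_96(textured_square_96, params):
    """Full detect run with intermediates on the canonical textured square."""
    img, gt = textured_square_96
    cd, inter = bc.detect(img, params, return_intermediates=True)
    return img, gt, cd, inter


@pytest.fixture(scope="session")
def square_regions_96(textured_square_96):
    """(interior, perimeter-band) masks for the canonical textured square."""
    _, gt = textured_square_96
    mask = gt.maps[0].astype(bool)
    perim = ndimage.binary_dilation(mask, iterations=1)
    side, r0 = 48, 24
    interior = np.zeros_like(mask)
    interior[r0 + 5 : r0 + side - 5, r0 + 5 : r0 + side - 5] = True
    interior &= ~perim
    return interior, perim
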