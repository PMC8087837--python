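"""Shared fixtures: small crafted frames and table-mode datasets."""

import numpy as np
import pytest

from colonygate.particles import ParticleImage
from colonygate.synthetic import GenerationConfig, default_profiles, generate_dataset


def make_frame(shape=(64, 64), background=230):
    """Uniform RGB background frame, float-safe uint8."""
    return np.full((*shape, 3), background, dtype=np.uint8)


def frame_with_rect(top, left, height, width, color=(90, 90, 90), shape=(64, 64)):
    """Frame holding one filled axis-aligned rectangle of the given colour."""
    px = make_frame(shape)
    px[top : top + height, left : left + width] = color
    return ParticleImage(px, pixel_size_um=1.0)


@pytest.fixture(scope="session")
def disk_image():
    """One dark disk of radius 20 px, constant colour, 1 um/px."""
    from skimage.draw import disk

    px = make_frame((96, 96))
    rr, cc = disk((48, 48), 20)
    px[rr, cc] = (90, 90, 90)
    return ParticleImage(px, pixel_size_um=1.0)


@pytest.fixture(scope="session")
def table_dataset():
    """Balanced 7-class table-mode dataset, 60 particles per class."""
    cfg = GenerationConfig(
        profiles=default_profiles(), n_per_class=60, seed=7, mode="table"
    )
    return generate_dataset(cfg)
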