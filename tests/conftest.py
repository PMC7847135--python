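"""Shared fixtures: fast half-resolution synthetic specimens for unit tests.

Structural and determinism checks do not depend on rendering resolution, so
most unit tests use half-size renders for speed; accuracy-sensitive checks
(and everything in test_acceptance.py) use the full default archetypes.
"""

from dataclasses import replace

import numpy as np
import pytest

from spotmorph.standardize import polygon_mask
from spotmorph.synthetic import default_archetypes, generate_specimen


@pytest.fixture(scope="session")
def small_archetypes():
    """Half-resolution versions of the default archetypes (fast renders)."""
    return tuple(replace(a, abdomen_axes=(400, 560)) for a in default_archetypes())


@pytest.fixture(scope="session")
def clean_small_archetypes(small_archetypes):
    """Half-resolution, noise-free archetypes."""
    return tuple(
        replace(a, intensity_sd=0.0, speckle_density=0.0) for a in small_archetypes
    )


@pytest.fixture(scope="session")
def h2_specimen(small_archetypes):
    return generate_specimen(small_archetypes[1], seed=11)


def roi_mask_of(specimen):
    """Source-frame abdomen mask rasterized from the specimen's ROI polygon."""
    return polygon_mask(specimen.image.pixels.shape, specimen.roi.polygon)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210129)
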