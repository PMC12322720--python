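"""Shared fixtures: small deterministic layouts, cameras, optics."""

import numpy as np
import pytest

from nwloc.array_model import generate_layout, place_molecules
from nwloc.image_synthesis import CameraModel, OpticalModel


@pytest.fixture(scope="session")
def optics():
    return OpticalModel()


@pytest.fixture()
def small_layout():
    """12x12 lattice — big enough for lattice estimation (>=10 periods)."""
    return generate_layout(n_rows=12, n_cols=12, seed=42)


@pytest.fixture()
def small_camera(small_layout):
    return CameraModel.for_layout(small_layout, exposure_ms=100.0)


@pytest.fixture()
def populated(small_layout):
    gt = place_molecules(small_layout, 1.22, seed=7)
    return small_layout, gt
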