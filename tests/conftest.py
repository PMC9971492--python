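"""Shared fixtures: a desk-scale phantom, its ground-truth field, and a
noise-free exhale/inhale image pair (expensive to build, so session-scoped)."""

import numpy as np
import pytest

from ctvent.image import ImageVolume
from ctvent.phantom import (
    AcquisitionSpec,
    BreathingModel,
    GroundTruthField,
    PhantomSpec,
    make_subject_images,
)
from ctvent.ventilation import VentilationMap


@pytest.fixture(scope="session")
def small_spec():
    """48^3 phantom at 6 mm: coarse but fast, lungs ~15 voxels across."""
    return PhantomSpec(grid_shape=(48, 48, 48), spacing=(6.0, 6.0, 6.0))


@pytest.fixture(scope="session")
def breathing():
    return BreathingModel()


@pytest.fixture(scope="session")
def small_field(small_spec, breathing):
    return GroundTruthField.build(small_spec, breathing)


@pytest.fixture(scope="session")
def small_pair(small_spec, breathing, small_field):
    """Noise-free (0EX, 100IN) pair with ground truth at 48^3."""
    acq = AcquisitionSpec("4DCT", 100, noise_scale=0.0)
    return make_subject_images(
        small_spec, breathing, small_field, acq, ["0EX", "100IN"], seed=11
    )


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_field(default_spec, breathing):
    return GroundTruthField.build(default_spec, breathing)


def make_map(data, spacing=(3.0, 3.0, 3.0), mask=None):
    """Wrap an array as a VentilationMap with a full (or given) mask."""
    data = np.asarray(data, dtype=float)
    img = ImageVolume(data, spacing)
    if mask is None:
        mask = np.ones(data.shape, dtype=np.uint8)
    return VentilationMap(img, ImageVolume(np.asarray(mask, np.uint8), spacing))
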