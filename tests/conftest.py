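"""Shared fixtures.

Expensive artefacts (the default phantom, its calibration, the parametric
sweeps) are session-scoped so the acceptance tests and unit tests share one
computation.  A reduced "small" phantom keeps solver-heavy property tests
fast; the default phantom is reserved for the checks whose statistical
power needs its ~11k trabecular elements.
"""

from __future__ import annotations

import numpy as np
import pytest

from vertefem.calibration import DiscProperties, calibrate
from vertefem.fe_core import build_model
from vertefem.grids import LabelMap
from vertefem.imaging import ModulusField, greyscale_to_modulus
from vertefem.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def default_modulus(default_phantom):
    image, labels = default_phantom
    return greyscale_to_modulus(image, labels)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A geometrically similar but much smaller segment for solver tests."""
    return PhantomSpec(
        body_radius_lat=9.8,
        body_radius_ap=7.0,
        body_height=11.2,
        disc_height=4.2,
        housing_height=2.8,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_modulus(small_phantom):
    image, labels = small_phantom
    return greyscale_to_modulus(image, labels)


@pytest.fixture(scope="session")
def small_builder(small_phantom, small_modulus):
    _, labels = small_phantom

    def builder(disc: DiscProperties):
        return build_model(
            labels, small_modulus, annulus=disc.annulus, nucleus=disc.nucleus
        )

    return builder


@pytest.fixture(scope="session")
def default_builder(default_phantom, default_modulus):
    _, labels = default_phantom

    def builder(disc: DiscProperties):
        return build_model(
            labels, default_modulus, annulus=disc.annulus, nucleus=disc.nucleus
        )

    return builder


@pytest.fixture(scope="session")
def default_calibration(default_builder):
    """Disc properties of the default phantom tuned to 617 N/mm."""
    return calibrate(default_builder, target_k=617.0)


def column_model(E, voxel_size: float = 1.0, nu: float = 0.0):
    """A 1x1xn all-bone column model; the EA/L and series-spring oracle rig."""
    E = np.asarray(E, dtype=float).reshape(1, 1, -1)
    labels = LabelMap(np.ones(E.shape, dtype=np.int64), voxel_size)
    modulus = ModulusField(E.copy(), labels)
    model = build_model(labels, modulus, bone_poisson=nu)
    return model
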