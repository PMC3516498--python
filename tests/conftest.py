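"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

import numpy as np
import pytest

from orbitovol import (
    GroundTruth,
    OrbitSpec,
    PhantomSpec,
    generate_phantom,
    make_asymmetric_pair,
    measure_orbit,
)
from orbitovol.phantom import label_volume


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Default bilateral phantom (rim 40 x 35 mm, depth 45 mm, noisy)."""
    vol, gt = generate_phantom(default_spec)
    return vol, gt


@pytest.fixture(scope="session")
def default_labels(default_spec):
    labels, spacing, origin = label_volume(default_spec)
    return labels, spacing, origin


@pytest.fixture(scope="session")
def measured_pair(default_phantom):
    """Both orbits of the default phantom measured with the default protocol."""
    vol, _ = default_phantom
    return {
        "left": measure_orbit(vol, "left", (-25.0, 0.0, 0.0)),
        "right": measure_orbit(vol, "right", (25.0, 0.0, 0.0)),
    }


@pytest.fixture(scope="session")
def shrunk_phantom(default_spec):
    """Default phantom with the left orbit shrunk 10% (operated side)."""
    spec = make_asymmetric_pair(default_spec, 0.1, side="left")
    vol, gt = generate_phantom(spec)
    return spec, vol, gt


def _small_spec(**overrides):
    kw = dict(
        left=OrbitSpec(rim_width=24, rim_height=20, depth=30, rim_center=(-16, 0, 0)),
        right=OrbitSpec(rim_width=24, rim_height=20, depth=30, rim_center=(16, 0, 0)),
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced gapless phantom for cheap pipeline-level tests."""
    return _small_spec()


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    vol, gt = generate_phantom(small_spec)
    return vol, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
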