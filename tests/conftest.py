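"""Shared fixtures: a small fast head model and the full benchmark context."""

import numpy as np
import pytest

from nlbench.experiments import SimulationContext, SweepConfig, build_context
from nlbench.head_model import (
    HeadModelSpec,
    build_sensor_array,
    build_source_grid,
    compute_leadfield,
)
from nlbench.synthetic import NoiseModelSpec


@pytest.fixture(scope="session")
def head():
    return HeadModelSpec()


@pytest.fixture(scope="session")
def small_ctx(head):
    """32-sensor quasi-uniform cap on a 15 mm grid — fast unit-test context."""
    sensors = build_sensor_array("synthetic32", head)
    grid = build_source_grid(head, 15.0)
    leadfield = compute_leadfield(sensors, grid, head)
    return SimulationContext(
        head=head,
        leadfield=leadfield,
        noise_model=NoiseModelSpec(n_noise_dipoles=150),
    )


@pytest.fixture(scope="session")
def medium_ctx(head):
    """64-channel montage on a 10 mm grid — point-recovery tests."""
    sensors = build_sensor_array("biosemi64", head)
    grid = build_source_grid(head, 10.0)
    leadfield = compute_leadfield(sensors, grid, head)
    return SimulationContext(head=head, leadfield=leadfield, noise_model=NoiseModelSpec())


@pytest.fixture(scope="session")
def full_ctx(head):
    """The benchmark's own operating point: biosemi64 on the 5 mm grid."""
    return build_context(SweepConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
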