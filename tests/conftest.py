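"""Shared fixtures: small synthetic sessions in the configurations the
tests exercise repeatedly. Session-scoped, since assembly is the dominant
cost and the pipeline never mutates its inputs."""

import numpy as np
import pytest

import footimu as fi


@pytest.fixture(scope="session")
def rigid_session():
    """Noise-free, attachment dynamics off, straight strides only: every
    sensor sees the pure rigid-body signal of its mounting."""
    proto = [fi.TestSpec("straight_normal", "normal", 12, 0.0)]
    return fi.assemble_session(
        proto, seed=5, feet=("left",),
        noise=False, attachment=False, marker_gaps=False, clock_jitter=False,
    )


@pytest.fixture(scope="session")
def rigid_results(rigid_session):
    return fi.run_pipeline(rigid_session, compute_features=False)["left"]


@pytest.fixture(scope="session")
def default_session():
    """Realistic small session: noise, attachment dynamics, marker gaps,
    clock jitter, a fifth of the strides turning."""
    proto = [fi.TestSpec("straight_normal", "normal", 10, 0.2)]
    return fi.assemble_session(proto, seed=3, feet=("left",))


@pytest.fixture(scope="session")
def default_results(default_session):
    return fi.run_pipeline(default_session)["left"]


@pytest.fixture(scope="session")
def toy_turn_session():
    """Noise on but no marker gaps: exclusions must be purely geometric."""
    proto = [fi.TestSpec("straight_normal", "normal", 10, 0.2)]
    return fi.assemble_session(
        proto, seed=9, feet=("left",), marker_gaps=False, clock_jitter=False
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
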