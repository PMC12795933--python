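import numpy as np
import pytest
import trimesh

from surfnav import PhantomSpec, generate_head_phantom, place_fiducials, plan_trajectories


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def head(default_spec):
    """The default phantom head, shared across the session (deterministic)."""
    return generate_head_phantom(default_spec)


@pytest.fixture(scope="session")
def fiducials(head, default_spec):
    return place_fiducials(head, default_spec)


@pytest.fixture(scope="session")
def trajectories(fiducials):
    return plan_trajectories(fiducials)


@pytest.fixture(scope="session")
def small_mesh():
    """A low-poly sphere for brute-force oracles (<= 1000 faces)."""
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
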