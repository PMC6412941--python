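import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_instance():
    """Default 3-block relation-layer instance with a planted candidate,
    shared across tests that only read it."""
    from modnmf import generate_joint_layers
    x1, x2, x3, truth = generate_joint_layers(seed=11)
    return (x1, x2, x3), truth


@pytest.fixture(scope="session")
def planted_fit(planted_instance):
    from modnmf import fit_joint_nmf
    (x1, x2, x3), truth = planted_instance
    fact = fit_joint_nmf([x1, x2, x3], truth.generator_params["K_true"],
                         n_restarts=20, max_iter=500, tol=1e-6, seed=11)
    return fact, truth


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A simulated input bundle on disk, shared read-only."""
    from modnmf.synthetic_data import generate_bundle
    out = tmp_path_factory.mktemp("bundle")
    truth = generate_bundle(out, seed=7)
    return out, truth
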