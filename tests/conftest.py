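import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nmadesign as nd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def chain_network():
    """Two contrast-level studies A-B and B-C: the textbook indirect chain."""
    records = [
        nd.ContrastRecord("S1", "A", "B", 2.007, 0.30),
        nd.ContrastRecord("S2", "B", "C", -0.50, 0.40),
    ]
    return nd.assemble_network(records, baseline="A")


@pytest.fixture(scope="session")
def brd_like_network():
    return nd.generate_network(nd.brd_like_blueprint(seed=7))


@pytest.fixture(scope="session")
def brd_like_fit(brd_like_network):
    return nd.fit_fixed_effects_nma(brd_like_network)


@pytest.fixture(scope="session")
def brd_sigma2_exg(brd_like_fit):
    """Existing-network variance of the NC-vs-ENFO estimate (synthetic stand-in)."""
    return nd.contrast_variance(brd_like_fit, "NC", "ENFO")


@pytest.fixture
def three_arm_study():
    return nd.Study(
        study_id="S9",
        arms=(
            nd.ArmRecord("S9", "A", 50, 100),
            nd.ArmRecord("S9", "B", 30, 100),
            nd.ArmRecord("S9", "Z", 20, 100),
        ),
    )


def brute_force_gls(network):
    """Independent normal-equations oracle: dense S, explicit inverses."""
    from nmadesign.nma import build_covariance, build_design_matrix, _study_rows

    x = build_design_matrix(network).matrix
    s = build_covariance(network).dense()
    y = np.concatenate(
        [_study_rows(st, network.baseline)[1] for st in network.studies]
    )
    s_inv = np.linalg.inv(s)
    cov = np.linalg.inv(x.T @ s_inv @ x)
    return cov @ x.T @ s_inv @ y, cov
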