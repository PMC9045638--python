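"""Shared fixtures: topology, random rigid motions, and one session-scoped
default campaign used by the acceptance-level planted-recovery tests."""

import numpy as np
import pytest

from spcdimer.topology import DimerTopology
from spcdimer.synthetic import CampaignConfig, make_campaign


@pytest.fixture(scope="session")
def topo():
    return DimerTopology()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def default_campaign(tmp_path_factory):
    """The scaled-down default campaign (144 windows), built once per session.

    Seed 1 is the campaign's reference seed throughout the test suite.
    """
    path = tmp_path_factory.mktemp("campaign") / "default"
    return make_campaign(path, CampaignConfig(), seed=1)
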