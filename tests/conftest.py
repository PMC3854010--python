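import numpy as np
import pytest

from spikeinit import cable, core, experiments


@pytest.fixture(scope="session")
def disc():
    return cable.Discretization()


@pytest.fixture(scope="session")
def standard_spec():
    """Ball-and-stick neuron with the Na cluster 40 µm out (the reference model)."""
    return core.ball_and_stick(40.0)


@pytest.fixture(scope="session")
def passive_spec():
    return core.ball_and_stick(profile=None)


@pytest.fixture(scope="session")
def kink_one(disc):
    """Pulse experiment with a single Nav1.6 cluster at 40 µm (shared: slow)."""
    return experiments.run_kink_study("one-channel", disc=disc)


@pytest.fixture(scope="session")
def kink_two(disc):
    """Pulse experiment with Nav1.2 at 15 µm added (shared: slow)."""
    return experiments.run_kink_study("two-channel", disc=disc)
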