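import numpy as np
import pytest

from spisim.atomic_data import load_element_table
from spisim.pulse import gaussian_profile
from spisim.synthetic import ClusterSpec, radius_for_density, toy_molecule


@pytest.fixture(scope="session")
def table():
    return load_element_table(4.96)


@pytest.fixture(scope="session")
def nominal_pulse():
    return gaussian_profile(nt=512)


@pytest.fixture(scope="session")
def small_cluster():
    """100-atom biomolecule-like cluster at realistic density."""
    spec = ClusterSpec(n_atoms=100, radius=radius_for_density(100), seed=11)
    return toy_molecule(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
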