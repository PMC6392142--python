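import numpy as np
import pytest

from abgas.fixtures import SyntheticAntibodyParams, make_synthetic_antibody


@pytest.fixture(scope="session")
def std_params():
    """Standard synthetic antibody used across the suite."""
    return SyntheticAntibodyParams()


@pytest.fixture(scope="session")
def std_antibody(std_params):
    return make_synthetic_antibody(std_params)


@pytest.fixture(scope="session")
def std_radii(std_params):
    return std_params.radii_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cluster(rng, n=50, scale=8.0, element="C"):
    """Random bead cluster as a Structure (test helper)."""
    from abgas.structure import Structure

    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(["X"] * n),
        element=np.array([element] * n),
        res_name=np.array(["BEA"] * n),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
        coord=rng.normal(scale=scale, size=(n, 3)),
    )
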