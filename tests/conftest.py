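import pytest
from hypothesis import settings

import episcreen as ep

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return ep.default_library()


@pytest.fixture(scope="session")
def small_config(library):
    """A compact screen: 2 cell lines, 10 compounds, moderate noise."""
    return ep.SimConfig(
        seed=11,
        cell_lines=("LINE-A", "LINE-B"),
        library=library[:10],
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    truth = ep.default_ground_truth(small_config, n_sensitizers=3)
    return ep.simulate_screen(small_config, truth)


@pytest.fixture(scope="session")
def noiseless_config(library):
    return ep.SimConfig(
        seed=5,
        cell_lines=("LINE-A",),
        library=library[:8],
        multiplicative_cv=0.0,
        additive_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_screen(noiseless_config):
    truth = ep.default_ground_truth(noiseless_config, n_sensitizers=3)
    return ep.simulate_screen(noiseless_config, truth)
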