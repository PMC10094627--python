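import pytest

from aromakey import quantify, synthetic
from aromakey.datamodel import RunConfig


@pytest.fixture(scope="session")
def default_table():
    """Default calibrated study design: 31 samples x 6 replicates, 135 compounds."""
    return synthetic.generate(synthetic.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_conc(default_table):
    return quantify.semi_quantify(default_table)


@pytest.fixture(scope="session")
def default_group_means(default_conc):
    return quantify.group_mean_concentrations(default_conc)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_table():
    """Reduced design (1 sample per group, 2 replicates) for I/O round-trips."""
    groups = tuple((g, 1) for g, _ in synthetic.DEFAULT_GROUP_SIZES)
    return synthetic.generate(
        synthetic.GeneratorConfig(groups=groups, replicates=2, seed=3)
    )
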