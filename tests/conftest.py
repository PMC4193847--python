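import numpy as np
import pytest

import coalitionsim as cs


@pytest.fixture(scope="session")
def neighborhoods():
    return cs.teotihuacan_preset("neighborhoods")


@pytest.fixture(scope="session")
def districts():
    return cs.teotihuacan_preset("districts")


@pytest.fixture(scope="session")
def study_config():
    """Study-scale configuration: r=0.0015, tau from N, 200 rituals and
    200 probes per phase."""
    return cs.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def neighborhoods_comparison(study_config):
    """Full-scale pre/post comparison (100 runs -> 20,000 convergences per
    phase) on the neighborhoods preset."""
    return cs.run_comparison("neighborhoods", 100, study_config)


@pytest.fixture(scope="session")
def districts_comparison(study_config):
    return cs.run_comparison("districts", 100, study_config)


def random_modular_network(rng, max_groups=4, max_group_size=3):
    """Small random modular all-positive network for oracle cross-checks."""
    groups = int(rng.integers(2, max_groups + 1))
    size = int(rng.integers(2, max_group_size + 1))
    w_within = float(rng.uniform(0.5, 1.0))
    w_between = float(rng.uniform(0.005, 0.2))
    return cs.build_modular_topology(groups, size, w_within, w_between)
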