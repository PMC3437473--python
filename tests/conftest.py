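"""Shared fixtures: small deterministic runs and scaled-down ensembles.

Ensemble sizes and horizons here are scaled-down study conditions chosen so
the full suite runs on one CPU in minutes; the scientific checks themselves
are unchanged.
"""

import pytest
from hypothesis import HealthCheck, settings

from crisprcoevo import SimConfig, replicate_ensemble, run
from crisprcoevo.fixtures import make_fixture

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_ensemble():
    """Four replicates at baseline parameters, 1000 h horizon."""
    return replicate_ensemble(SimConfig(t_max=1000.0), 4, seeds=[101, 102, 103, 104])


@pytest.fixture(scope="session")
def short_default_record():
    """One short diversifying run for structural checks."""
    return run(SimConfig(t_max=120.0, seed=7))


@pytest.fixture(scope="session")
def lv_pair_record():
    """Mutation-free host-virus pair integrated to its coexistence equilibrium."""
    config, expectations = make_fixture("lv-pair", seed=0)
    return run(config), expectations


@pytest.fixture(scope="session")
def immune_pair_record():
    """Fully immune host vs a virus that cannot replace its losses."""
    config, expectations = make_fixture("immune-pair", seed=0)
    return run(config), expectations
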