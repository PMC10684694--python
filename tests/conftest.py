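import numpy as np
import pytest

import cohortnet as cn


@pytest.fixture(scope="session")
def registry():
    return cn.default_registry()


@pytest.fixture(scope="session")
def raw_cohort(registry):
    """Default 200-row synthetic cohort (156 complete + 44 incomplete)."""
    return cn.simulate_cohort(cn.SimulationConfig(seed=1), registry)


@pytest.fixture(scope="session")
def cohort(raw_cohort, registry):
    """The 156-row complete-case table."""
    table, _ = cn.filter_complete(raw_cohort, registry)
    return table


@pytest.fixture(scope="session")
def fa_partition(cohort, registry):
    """Full-sample module partition with clustered fatty acids."""
    corr = cn.correlation_matrix(cohort, registry).abs()
    fa = registry.fatty_acids
    clusters = cn.cluster_fatty_acids(corr.loc[fa, fa])
    return cn.build_partition(registry, clusters)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
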