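import numpy as np
import pytest

import pseudotree as pt


@pytest.fixture(scope="session")
def path_cohort():
    """Small linear-trajectory cohort with clinical labels."""
    cohort, truth = pt.simulate_cohort(
        topology="path", n_samples=120, n_genes=400, seed=7, plant_resistance=False
    )
    return cohort, truth


@pytest.fixture(scope="session")
def y_cohort():
    """Default branching cohort with a planted resistant cluster."""
    cohort, truth = pt.simulate_cohort(topology="y", n_samples=300, n_genes=2000, seed=5)
    return cohort, truth


@pytest.fixture(scope="session")
def fitted_path(path_cohort):
    cohort, truth = path_cohort
    model = pt.fit(cohort.log_expression, pt.DDRTreeParams(seed=7))
    return cohort, truth, model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
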