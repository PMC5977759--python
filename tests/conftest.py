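import numpy as np
import pytest

from aftsurv import SimulationDesign, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A small censored cohort shared across tests (read-only)."""
    design = SimulationDesign(
        n_train=120, n_test=60, p=30, n_nonzero=6, beta_scale=0.6,
        censor_rate_target=0.3, seed=11,
    )
    dataset, truth = generate_dataset(design)
    return design, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def stack_expression(dataset, ids):
    """Sample-major covariate matrix over all annotation blocks, in the
    generator's original column order."""
    return np.column_stack(
        [dataset.expression[k].values[ids].to_numpy().T
         for k in ("gene", "transcript", "intron")]
    )
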