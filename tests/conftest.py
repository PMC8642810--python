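import numpy as np
import pytest

import pedimmune as pi


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared by read-only tests."""
    cfg = pi.SimulationConfig(
        seed=7,
        n_genes=400,
        tumor_types={"OS": 12, "EWS": 12},
        normal_panel={
            "heart": 3,
            "brain": 3,
            "testis": 3,
            "ovary": 3,
            "lung": 3,
            "liver": 3,
        },
        immune_geneset_size=40,
    )
    cm, truth = pi.simulate_expression(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def normalized(small_cohort):
    _, cm, _ = small_cohort
    factors = pi.tmm_factors(cm)
    return pi.fpkm(cm, factors)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
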