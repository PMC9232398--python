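import numpy as np
import pytest

from diffomics.ingest import LabeledDataset
from diffomics.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Balanced cohort with one differential expression pair (rho +0.8 / -0.8)."""
    cfg = SimulationConfig(
        n_samples=400,
        p_genes=6,
        class_fraction=0.5,
        differential_pairs=[(0, 1, 0.8, -0.8)],
        seed=101,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_dataset(planted_cohort):
    c = planted_cohort
    return LabeledDataset(
        matrix=c.expression, labels=c.true_class, horizon_years=5.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
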