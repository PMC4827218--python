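import numpy as np
import pytest

from mbsubtype import SimulationConfig, generate_cohort


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160411)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 3-class cohort with strong signal, shared across read-only tests."""
    config = SimulationConfig(
        n_per_class=8,
        classes=("SHH", "Group3", "Group4"),
        n_genes=240,
        n_genesets=16,
        genes_per_set=15,
        signature_sets_per_class=2,
        signal_shift=3.0,
        noise_sd=1.0,
        seed=11,
    )
    expr, labels, collection = generate_cohort(config)
    return config, expr, labels, collection
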