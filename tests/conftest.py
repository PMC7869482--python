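import numpy as np
import pytest

from mugsel import CohortSpec, generate


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small paired cohort: 3 classes x 12 samples, 200 genes, 10 planted/class."""
    spec = CohortSpec(
        n_per_class={"breast": 20, "lung": 20, "kidney": 20},
        n_genes=200,
        n_informative_per_class=10,
        informative_mutation_rate=0.8,
        seed=7,
    )
    counts, expression, truth = generate(spec)
    return spec, counts, expression, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
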