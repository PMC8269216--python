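import numpy as np
import pytest

from step3.synthetic import SynthSpec, generate_dataset, generate_pssm_fixture

#: Small grid keeping SVM training fast in unit tests.
FAST_GRID = (-2, 2, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_separable_dataset():
    """Small, strongly class-separated dataset (shared across tests)."""
    return generate_dataset(
        SynthSpec(n_pos=10, n_neg=25, length_range=(30, 50), seed=2)
    )


@pytest.fixture(scope="session")
def tiny_separable_test_set():
    return generate_dataset(
        SynthSpec(n_pos=10, n_neg=10, length_range=(30, 50), seed=90,
                  id_prefix="t_")
    )


@pytest.fixture(scope="session")
def random_profile():
    return generate_pssm_fixture(12, "random", seed=5)
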