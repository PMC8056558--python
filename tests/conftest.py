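import numpy as np
import pytest

from dtidae import FingerprintMatrix, InteractionMatrix, TrainingConfig
from dtidae.synthetic import SyntheticSpec, generate, paper_scale_fixture


def im(values, drug_ids=None, target_ids=None) -> InteractionMatrix:
    values = np.asarray(values)
    n, m = values.shape
    return InteractionMatrix(
        values=values,
        drug_ids=drug_ids or tuple(f"d{i}" for i in range(n)),
        target_ids=target_ids or tuple(f"t{j}" for j in range(m)),
    )


def fm(values, bit_ids=None, drug_ids=None) -> FingerprintMatrix:
    values = np.asarray(values)
    f, n = values.shape
    return FingerprintMatrix(
        values=values,
        bit_ids=bit_ids or tuple(f"fp{k}" for k in range(f)),
        drug_ids=drug_ids or tuple(f"d{i}" for i in range(n)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240819)


@pytest.fixture(scope="session")
def fixture_dataset():
    """Benchmark-shaped synthetic dataset (54 drugs x 26 targets)."""
    return paper_scale_fixture()


@pytest.fixture(scope="session")
def noisy_dataset():
    """Dataset with 10% flip noise used by recovery-style tests."""
    return generate(
        SyntheticSpec(
            n_drugs=54, n_targets=26, n_bits=200, latent_dim=3,
            interaction_density=0.064, noise_flip_rate=0.1, seed=7,
        )
    )


@pytest.fixture
def quick_config():
    """Small, fast training config for integration-style tests."""
    return TrainingConfig(
        lambda_reg=0.001,
        epochs=100,
        learning_rate=1.0,
        corruption_rate=0.2,
        zeros_are_observed=True,
        seed=11,
    )


RECOVERY_CONFIG_KWARGS = dict(
    lambda_reg=0.001,
    epochs=1000,
    learning_rate=1.0,
    corruption_rate=0.3,
    zeros_are_observed=True,
)
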