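import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

hyp_settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A 3-subject synthetic study used by several structural tests."""
    from gaindcm.synthetic import SyntheticStudyConfig, simulate_dataset

    return simulate_dataset(SyntheticStudyConfig(n_subjects=3, seed=11))


@pytest.fixture(scope="session")
def small_modes(small_dataset):
    from gaindcm.pipeline import dataset_modes

    return dataset_modes(small_dataset)


# -- heavy replicate studies shared across the acceptance tests ------------


@pytest.fixture(scope="session")
def architecture_study():
    from gaindcm.studies import architecture_recovery_study

    return architecture_recovery_study(n_replicates=10, base_seed=1)


@pytest.fixture(scope="session")
def gain_study():
    from gaindcm.studies import gain_recovery_study

    return gain_recovery_study(n_replicates=10, base_seed=2, n_subjects=6)


@pytest.fixture(scope="session")
def null_study():
    from gaindcm.studies import null_evidence_study

    return null_evidence_study(n_replicates=3, base_seed=5, n_subjects=6)
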