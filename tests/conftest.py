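import numpy as np
import pytest
from hypothesis import settings

from enpkit.boost import BoostConfig, EnsembleModel
from enpkit.cohort import CohortConfig, label_with_truth, make_experimental_set, sample_compositions
from enpkit.data import split_dataset
from enpkit.gan import GANConfig, train_gan

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_cfg():
    return CohortConfig(seed=202)


@pytest.fixture(scope="session")
def experimental_cohort(cohort_cfg):
    """The default 225-record synthetic experimental set."""
    return make_experimental_set(cohort_cfg)


@pytest.fixture(scope="session")
def desk_dataset(cohort_cfg):
    """2,000 labeled records at desk scale (noisy truth-map labels)."""
    rng = np.random.default_rng(77)
    comps = sample_compositions(2000, cohort_cfg, rng)
    return label_with_truth(comps, cohort_cfg, with_noise=True, seed=78)


@pytest.fixture(scope="session")
def desk_split(desk_dataset):
    return split_dataset(desk_dataset, 0.7, seed=5, stratify_on="size_nm")


@pytest.fixture(scope="session")
def desk_model(desk_split):
    train, _ = desk_split
    return EnsembleModel(BoostConfig(seed=5)).fit(train)


@pytest.fixture(scope="session")
def desk_predictions(desk_model, desk_split):
    _, blind = desk_split
    return blind.cqas(), desk_model.predict(blind.compositions()), blind


@pytest.fixture(scope="session")
def trained_gan(experimental_cohort):
    """LipidGAN trained at the default schedule (4,000 epochs)."""
    return train_gan(experimental_cohort, GANConfig(seed=42))
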