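import numpy as np
import pytest

import matplotlib
matplotlib.use("Agg")

from gaitkinetics.experiment import (ExperimentConfig, PopulationConfig,
                                     SplitConfig, build_dataset)
from gaitkinetics.synthetic import GeneratorConfig, sample_population, simulate_trial

NOISE_FREE = GeneratorConfig(marker_noise_mm=0.0, force_noise_bw=0.0)


@pytest.fixture(scope="session")
def population():
    return sample_population(4, 4, seed=11)


@pytest.fixture(scope="session")
def subject(population):
    return population[0]


@pytest.fixture(scope="session")
def quiet_trial(subject):
    """One noise-free gait cycle."""
    return simulate_trial(subject, trial_seed=0, config=NOISE_FREE)


@pytest.fixture(scope="session")
def noisy_trial(subject):
    """One gait cycle with default measurement noise."""
    return simulate_trial(subject, trial_seed=0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 subjects x 3 trials with default noise, 1+1 subjects held out."""
    cfg = ExperimentConfig(
        master_seed=42,
        population=PopulationConfig(n_male=4, n_female=4, trials_per_subject=3),
        split=SplitConfig(n_test_male=1, n_test_female=1),
    )
    return build_dataset(cfg)


@pytest.fixture(scope="session")
def one_sample(tiny_dataset):
    return tiny_dataset.samples[0]
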