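import numpy as np
import pandas as pd
import pytest

from icerec.preprocessing import (
    FeatureMatrix,
    drop_degenerate_features,
    encode_features,
    impute_median_mode,
)
from icerec.synthetic_trial import GeneratorConfig, generate_trial


@pytest.fixture(scope="session")
def small_trial():
    """An 80-patient trial with missingness, shared across tests."""
    return generate_trial(GeneratorConfig(n_patients=80, seed=3))


@pytest.fixture(scope="session")
def noiseless_trial():
    """A trial without utility observation noise or missingness: observed
    outcomes equal the assigned arm's potential outcomes exactly."""
    cfg = GeneratorConfig(n_patients=120, seed=5, utility_noise_sd=0.0, missing_rate=0.0)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def encoded_small_trial(small_trial):
    """Design matrix + outcome frame for the 80-patient trial."""
    dataset, _ = small_trial
    fm = FeatureMatrix.from_dataframe(dataset.baseline)
    fm, _ = drop_degenerate_features(fm, arm_split=dataset.arm)
    fm = impute_median_mode(fm)
    X = encode_features(fm).values
    y = pd.DataFrame(
        {
            "arm": dataset.arm,
            "qaly": dataset.observed_qaly(),
            "cost": dataset.observed_cost(),
        }
    )
    return X, y


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
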