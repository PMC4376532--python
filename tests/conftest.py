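import numpy as np
import pytest

from nutrilat import CompetitionConfig, Environment


@pytest.fixture
def mild_env() -> Environment:
    """3-food environment: one balanced food flanked by two mildly
    imbalanced, complementary foods."""
    return Environment.from_ratios([0.5, 1.0, 2.0])


@pytest.fixture
def severe_env() -> Environment:
    """2-food environment: one balanced and one severely imbalanced food."""
    return Environment.from_ratios([1.0, 16.0])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def competition(c: float, n_food: int = 3, n_ind: int = 150, eta: float = 25.0) -> CompetitionConfig:
    return CompetitionConfig.from_competition(c, n_food, n_ind, eta)
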