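import warnings

import numpy as np
import pytest

from ccmbn.simulate import SimConfig, simulate_four_species, simulate_lake_like

# statsmodels emits interpolation warnings from ADF p-values on extreme
# statistics; they are expected on chaotic segments
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def four_species():
    """Homogeneous four-species run, 1000 post-burn-in steps."""
    return simulate_four_species(SimConfig(n_steps=1000, seed=0))


@pytest.fixture(scope="session")
def lake_like():
    """Seasonal fixture with known lagged edges."""
    return simulate_lake_like(
        n_steps=800,
        edges=[("temp", "oxygen", 1, 0.9), ("temp", "nutrient", 3, 0.8),
               ("oxygen", "microcystis", 2, 0.7),
               ("nutrient", "microcystis", 4, 0.6)],
        seasonal_period=73, noise_sd=0.15, seed=7)


def logistic_series(n: int, x0: float = 0.31, r: float = 3.9) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for i in range(n - 1):
        x[i + 1] = r * x[i] * (1.0 - x[i])
    return x


@pytest.fixture(scope="session")
def logistic_map():
    return logistic_series(600)
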