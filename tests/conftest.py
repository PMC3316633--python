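import numpy as np
import pandas as pd
import pytest

from primedisc import DesignConfig, DiscountParams, build_design
from primedisc.simulate import simulate_choices

CANONICAL = DiscountParams(k=0.024, a=0.06, omega=0.3)


@pytest.fixture(scope="session")
def canonical_params() -> DiscountParams:
    """Group-mean generating parameters used throughout."""
    return CANONICAL


@pytest.fixture(scope="session")
def schedule() -> pd.DataFrame:
    """One default 324-trial session schedule."""
    return build_design(DesignConfig(seed=11), k_pretest=CANONICAL.k)


@pytest.fixture(scope="session")
def dataset(schedule) -> pd.DataFrame:
    """Schedule plus simulated choices from the canonical subject."""
    return simulate_choices(CANONICAL, schedule, seed=12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
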