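import numpy as np
import pandas as pd
import pytest

from gwyield.config import GWEffectParams, SimConfig
from gwyield.synthetic_world import simulate_world


@pytest.fixture(scope="session")
def default_world() -> pd.DataFrame:
    """Moderate default-parameter world shared by read-only tests."""
    return simulate_world(SimConfig(n_cells=400, n_years=15, seed=42))


@pytest.fixture(scope="session")
def null_world() -> pd.DataFrame:
    """World with no groundwater effect at all."""
    cfg = SimConfig(
        n_cells=400,
        n_years=15,
        seed=42,
        gw_effect=GWEffectParams(s_max=0.0, penalty_slope=0.0),
    )
    return simulate_world(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
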