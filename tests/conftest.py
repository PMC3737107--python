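import logging

import numpy as np
import pandas as pd
import pytest

from nestsurvey import SimulationConfig, simulate_survey

logging.getLogger("nestsurvey").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_survey():
    """One synthetic survey at the default study regime, shared read-only."""
    return simulate_survey(SimulationConfig(seed=20260928))


@pytest.fixture
def obs_frame():
    """Small hand-written observation table."""
    rng = np.random.default_rng(42)
    n = 40
    return pd.DataFrame(
        {
            "transect_id": [f"T{1 + i % 4:02d}" for i in range(n)],
            "visit": [1] * n,
            "year": [2010] * n,
            "distance_m": np.abs(rng.normal(0.0, 15.0, size=n)),
            "habitat": ["DF", "OF", "SAV", "DF"] * (n // 4),
        }
    )
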