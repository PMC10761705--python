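import time

import numpy as np
import pytest

from soiltau import gen_world
from soiltau.pipeline import run_pipeline
from soiltau.types import PoolParams


@pytest.fixture(scope="session")
def world_small():
    return gen_world(12, 12, seed=7)


@pytest.fixture(scope="session")
def world20():
    return gen_world(20, 20, seed=1)


@pytest.fixture(scope="session")
def recovery_params():
    """Three-pool truth used for the inversion recovery checks: chosen for
    maximal Fisher information under 2-yr weekly sampling."""
    return PoolParams(k=np.array([0.05, 6e-3, 1e-5]), f=np.array([0.10, 0.50, 0.40]))


@pytest.fixture(scope="session")
def pipeline_full():
    """Full-size pipeline run (20x20 world, 3 ESMs, 3 scenarios)."""
    t0 = time.time()
    result = run_pipeline(seed=1)
    result.summary["wall_time_s"] = time.time() - t0
    return result


@pytest.fixture(scope="session")
def ctx_small():
    """Reduced pipeline context for sensitivity-experiment wiring tests."""
    return run_pipeline(seed=3, n_lat=12, n_lon=12, n_models=2,
                        scenarios=("ssp126", "ssp585"), n_sites=100)
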