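import numpy as np
import pytest

from arcbio.synthetic_data.environment import VariableSpec, simulate_environment
from arcbio.synthetic_data.grid import Grid, make_grid


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    """10-degree cells, 4x36, 4 regions — fast enough for everything."""
    return make_grid((-180, 180, 50, 90), 10.0, 4, seed=7)


def noise_free_spec(grid: Grid, ssst_trend=0.5, ssic_trend=-8.0) -> dict:
    lat = grid.lat_grid.astype(float)
    frac = (lat - lat.min()) / (lat.max() - lat.min())
    return {
        "SSST": VariableSpec(10.0 - 12.0 * frac, ssst_trend),
        "SSIC": VariableSpec(np.clip(120.0 * frac - 20.0, 0, 100), ssic_trend),
        "SCHL": VariableSpec(2.0 - frac, 0.1),
        "SZOOC": VariableSpec(1.5 - frac, 0.1),
        "salinity": VariableSpec(33.0 + 2 * frac),
        "depth": VariableSpec(-2000.0 + 1500 * np.exp(-3 * frac)),
    }


@pytest.fixture(scope="session")
def small_env(small_grid):
    env, truth = simulate_environment(
        small_grid, range(2000, 2010), trend_spec=noise_free_spec(small_grid), seed=7
    )
    return env


@pytest.fixture(scope="session")
def small_env_truth(small_grid):
    return simulate_environment(
        small_grid, range(2000, 2010), trend_spec=noise_free_spec(small_grid), seed=7
    )
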