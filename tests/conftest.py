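import numpy as np
import pandas as pd
import pytest

from odmodels.synthetic import SyntheticConfig, generate_districts, simulate_flows


@pytest.fixture(scope="session")
def small_world():
    """A 12-district world with its Euclidean distance matrix."""
    cfg = SyntheticConfig(n_districts=12, seed=7)
    d = generate_districts(cfg)
    xy = d[["x_km", "y_km"]].to_numpy()
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    return d, dist


@pytest.fixture(scope="session")
def small_od(small_world):
    d, _ = small_world
    cfg = SyntheticConfig(n_districts=12, seed=7)
    return simulate_flows(d, cfg.gravity_truth, seed=7)


@pytest.fixture(scope="session")
def study_world():
    """The full-size study conditions: 69 districts, gravity truth as planted."""
    cfg = SyntheticConfig(seed=11)
    d = generate_districts(cfg)
    od = simulate_flows(d, cfg.gravity_truth, seed=11)
    return cfg, d, od


def toy_districts(pops, coords):
    return pd.DataFrame(
        {
            "district_id": [f"X{i}" for i in range(len(pops))],
            "population": pops,
            "x_km": [c[0] for c in coords],
            "y_km": [c[1] for c in coords],
        }
    )
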