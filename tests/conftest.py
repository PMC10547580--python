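import numpy as np
import pandas as pd
import pytest

from occubear import (
    DetectionHistory,
    SimulationScenario,
    SiteCovariates,
    simulate_dataset,
    standardize,
)


@pytest.fixture
def toy_history() -> DetectionHistory:
    """Three sites x three occasions with one NA."""
    mat = pd.DataFrame(
        {
            "occ_1": [1.0, 0.0, 0.0],
            "occ_2": [0.0, np.nan, 0.0],
            "occ_3": [1.0, 0.0, 1.0],
        }
    )
    return DetectionHistory(
        site_ids=np.array(["s1", "s2", "s3"]), occasion_matrix=mat
    )


@pytest.fixture
def small_covariates() -> SiteCovariates:
    rng = np.random.default_rng(7)
    n = 12
    return SiteCovariates(
        pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n)],
                "x": rng.uniform(0, 1e4, n),
                "y": rng.uniform(0, 1e4, n),
                "cc": rng.uniform(0, 100, n),
                "human": rng.integers(0, 300, n).astype(float),
                "livestock": rng.integers(0, 100, n).astype(float),
                "predators": rng.uniform(0, 1, n),
                "d_settlement": rng.uniform(0, 5000, n),
                "d_road": rng.uniform(0, 3000, n),
                "d_water": rng.uniform(0, 8000, n),
            }
        )
    )


@pytest.fixture(scope="session")
def default_fit_inputs():
    """One default-scale synthetic dataset, standardized, for model tests."""
    ds = simulate_dataset(SimulationScenario(seed=11))
    std, spec = standardize(ds.covariates)
    return ds, std, spec
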