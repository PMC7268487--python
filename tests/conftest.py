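import numpy as np
import pandas as pd
import pytest

import geotree as gt


@pytest.fixture(scope="session")
def small_panel():
    """Deterministic 300-country synthetic cross-section with truth record."""
    params = gt.SimulationParams(n_countries=300, seed=7)
    panel, truth = gt.generate_panel(params)
    return panel, truth


@pytest.fixture(scope="session")
def model_frame(small_panel):
    """Design frame (covariates + true group labels) for the small panel."""
    panel, truth = small_panel
    return gt.design_frame(panel.data, truth.assignments)


@pytest.fixture(scope="session")
def mortality_spec():
    return gt.CrossClassifiedSpec("ncd_mortality_rate", gt.DEFAULT_COVARIATES)


@pytest.fixture()
def tiny_frame(tmp_path):
    """Three valid hand-written panel rows as a CSV file."""
    df = pd.DataFrame(
        {
            "country_id": ["A", "B", "C"],
            "year": [2015, 2015, 2015],
            "gdp_per_capita": [800.0, 5000.0, 40000.0],
            "urbanization_rate": [25.0, 55.0, 85.0],
            "neonatal_mortality": [30.0, 12.0, 2.0],
            "ncd_mortality_rate": [700.0, 550.0, 380.0],
            "ncd_death_share": [35.0, 60.0, 88.0],
        }
    )
    path = tmp_path / "tiny.csv"
    df.to_csv(path, index=False)
    return df, path


def brute_force_q(values, strata):
    """Independent q oracle: direct per-stratum population-variance sums."""
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    n = len(values)
    sst = n * values.var()
    ssw = 0.0
    for level in set(strata.tolist()):
        grp = values[strata == level]
        ssw += len(grp) * grp.var()
    return 1.0 - ssw / sst


def exhaustive_breaks(values, k):
    """Independent Fisher-Jenks oracle: enumerate all contiguous partitions
    of the sorted unique values and return the minimal within-class SS."""
    import itertools

    u = np.unique(np.asarray(values, dtype=float))
    v = np.sort(np.asarray(values, dtype=float))
    best = np.inf
    for cuts in itertools.combinations(range(1, len(u)), k - 1):
        bounds = [u[c - 1] for c in cuts]
        labels = np.searchsorted(bounds, v, side="left")
        ssw = sum(
            ((v[labels == c] - v[labels == c].mean()) ** 2).sum()
            for c in range(k)
            if (labels == c).any()
        )
        if len(set(labels.tolist())) == k and ssw < best - 0.0:
            best = min(best, ssw)
    return best
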