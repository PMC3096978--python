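import numpy as np
import pandas as pd
import pytest

from tnegsig import CohortBundle, SimulationParams, simulate_cohort


def make_bundle(
    values,
    times=None,
    events=None,
    sources=None,
    feature_ids=None,
    feature_map=None,
):
    """Small hand-built CohortBundle for unit tests.

    ``values`` is a 2-D array-like (features x samples).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_feat, n = values.shape
    samples = [f"s{i}" for i in range(n)]
    features = feature_ids or [f"g{i}" for i in range(n_feat)]
    expr = pd.DataFrame(values, index=features, columns=samples)
    clinical = pd.DataFrame(
        {
            "source": sources if sources is not None else ["A"] * n,
            "dmfs_months": times if times is not None else np.arange(1, n + 1, dtype=float),
            "dmfs_event": events if events is not None else [1] * n,
            "er_status": "neg",
            "pr_status": "neg",
            "her2_status": "unknown",
        },
        index=samples,
    )
    fmap = None
    if feature_map is not None:
        fmap = pd.Series(feature_map)
    return CohortBundle(expression=expr, clinical=clinical, feature_map=fmap)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 300-gene, two-source cohort with defaults."""
    params = SimulationParams(
        n_genes=300, n_sources=2, samples_per_source=[80, 70], seed=42
    )
    return simulate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
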