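import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_dataset():
    """Default 26-variant / 16-trait / k=3 synthetic dataset (seed 0)."""
    from clustmr import simulate_clustered_sumstats

    tables, panel, truth = simulate_clustered_sumstats(seed=0)
    return tables, panel, truth


@pytest.fixture(scope="session")
def planted_zmatrix(planted_dataset):
    from clustmr import build_zscore_matrix, filter_complete, harmonize_to_panel

    tables, panel, _ = planted_dataset
    harmonized = {t: harmonize_to_panel(recs, panel)[0] for t, recs in tables.items()}
    return filter_complete(build_zscore_matrix(harmonized, panel, list(tables)))


def adjusted_rand_index(a, b) -> float:
    """Small self-contained ARI (pair-counting form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    labels_a, labels_b = np.unique(a), np.unique(b)
    contingency = np.array(
        [[(np.logical_and(a == la, b == lb)).sum() for lb in labels_b] for la in labels_a]
    )

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
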