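import numpy as np
import pytest
from hypothesis import settings

import histotype as ht

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_matrix(values, gene_ids=None, sample_ids=None, cohort=None):
    """ExpressionMatrix from a plain 2-D array with generated ids."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    cohort = np.asarray(cohort if cohort is not None else ["all"] * n,
                        dtype=object)
    return ht.ExpressionMatrix(gene_ids, sample_ids, values, cohort)


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down simulation used by several integration tests."""
    return ht.SimulationSpec(n_cohorts=2, n_per_cohort=150, n_genes=500,
                             n_informative=60, seed=42)


@pytest.fixture(scope="session")
def small_study(small_spec):
    return ht.simulate_cohorts(small_spec)


@pytest.fixture(scope="session")
def trained(small_study):
    """Classifier trained once on the small synthetic study."""
    X, clinical, truth = small_study
    art = ht.train_classifier(X, clinical["histology"].to_numpy(),
                              ht.RunConfig(seed=42, cv_folds=5))
    return art, X, clinical, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
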