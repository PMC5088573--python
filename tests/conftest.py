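import numpy as np
import pytest

import colisurf as cs


@pytest.fixture(scope="session")
def small_cohort():
    """A 12+12 synthetic cohort shared across tests (read-only)."""
    return cs.generate_cohort(cs.CohortConfig(n_sediment=12, n_water=12, seed=11))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    c = small_cohort
    return cs.build_property_table(c.records, c.blank, c.protein_curve, c.sugar_curve)


def random_similarity(rng: np.random.Generator, n: int):
    """A valid random similarity matrix (symmetric, unit diagonal, [-1, 1])."""
    from colisurf.fingerprint import SimilarityMatrix

    a = rng.uniform(0.0, 1.0, size=(n, n))
    s = (a + a.T) / 2
    np.fill_diagonal(s, 1.0)
    labels = [f"S{i:02d}" for i in range(n)]
    return SimilarityMatrix(labels, s)
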