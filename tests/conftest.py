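import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sigscore as ss

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_matrix() -> ss.ExpressionMatrix:
    """Random sparse 10-cell x 50-gene counts fixture for oracle checks."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(0.8, size=(10, 50)).astype(float)
    counts[:, 0] = rng.integers(1, 6, size=10)  # no all-zero cells
    genes = [f"g{i:02d}" for i in range(50)]
    cells = [f"c{i}" for i in range(10)]
    return ss.ExpressionMatrix(counts, genes, cells, layer_tag="counts")


@pytest.fixture(scope="session")
def small_signatures(small_matrix) -> list[ss.GeneSet]:
    rng = np.random.default_rng(11)
    gids = list(small_matrix.gene_ids)
    sigs = []
    for i, size in enumerate((5, 12, 20)):
        genes = tuple(rng.choice(gids, size, replace=False))
        sigs.append(ss.GeneSet(f"sig{i}", genes))
    # one signature with genes partly outside the matrix universe
    sigs.append(ss.GeneSet("sig_mixed", tuple(rng.choice(gids, 8,
                                                         replace=False))
                           + ("absent1", "absent2")))
    return sigs


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic tumor/normal cohort, shared across tests."""
    matrix, truth = ss.generate_cohort(ss.CohortConfig(seed=1))
    return matrix, truth
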