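import numpy as np
import pandas as pd
import pytest

import synlethal as sl
from synlethal.pair_features import FeatureConfig, build_feature_table


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 20-gene x 30-sample cohort with 3 planted SL pairs."""
    return sl.small_fixture()


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong planted effects at the standard evaluation scale.

    rho = 0.2 (co-loss suppressed five-fold), kappa = 3 (up-down enriched),
    100 SL + 2000 non-SL labeled pairs, 2000 genes, 500 samples.
    """
    return sl.generate_cohort(sl.SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def strong_features(strong_cohort):
    c = strong_cohort
    cfg = FeatureConfig(
        high_deletion_threshold=c.config.n_genes // 10,
        include_genomic_updown=True,
    )
    pairs = list(zip(c.labels.pairs["gene_a"], c.labels.pairs["gene_b"]))
    return build_feature_table(pairs, c.cnv, c.expr_status, cfg), cfg


@pytest.fixture
def tiny_cnv():
    # spec-style toy: 2 genes x 8 samples covering every fraction denominator
    status = np.array([
        [-2, -2, -2, 0, 0, -1, 1, 0],
        [-2, 0, 0, -2, 0, 0, 2, -2],
    ])
    return sl.CNVMatrix(["A", "B"], [f"s{i}" for i in range(8)], status)


def random_status_matrix(rng, codes, n_genes=6, n_samples=15):
    status = rng.choice(codes, size=(n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return genes, samples, status
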