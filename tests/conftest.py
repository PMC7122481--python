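import numpy as np
import pytest

import reosig as rs


def make_matrix(values, gene_ids=None, sample_ids=None) -> rs.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    return rs.ExpressionMatrix(gene_ids, sample_ids, values)


def random_matrix(rng, n_genes, n_samples, missing_rate=0.0, tie_prone=False):
    """Random matrix; tie_prone draws small integers so ties actually occur.

    Genes get distinct baseline means so a realistic share of pairs shows
    consistent within-sample ordering.
    """
    if tie_prone:
        values = rng.integers(0, 4, size=(n_genes, n_samples)).astype(float)
    else:
        gene_means = rng.normal(8.0, 2.5, size=n_genes)
        values = gene_means[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan
    return make_matrix(values)


@pytest.fixture(scope="session")
def standard_cohort():
    """The standard synthetic study condition with full ground truth."""
    cfg = rs.SyntheticConfig(seed=20240)
    m, labels, truth = rs.generate(cfg)
    return cfg, m, labels, truth


@pytest.fixture(scope="session")
def standard_discovery(standard_cohort):
    """Full discovery run on the standard cohort (shared: it is deterministic)."""
    cfg, m, labels, truth = standard_cohort
    return rs.discover(m, labels, seed=cfg.seed)
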