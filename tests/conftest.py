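import numpy as np
import pytest

from arrayimpute import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 3 samples with one missing entry."""
    vals = np.array([[1.0, 2.0, np.nan],
                     [1.1, 2.0, 3.0],
                     [10.0, 10.0, 10.0]])
    return ExpressionMatrix(gene_ids=["g1", "g2", "g3"],
                            sample_ids=["s1", "s2", "s3"], values=vals)


@pytest.fixture
def complete_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(20)],
        sample_ids=[f"s{j}" for j in range(6)],
        values=rng.standard_normal((20, 6)),
    )


def random_matrix_with_missing(n_genes: int, n_samples: int, rate: float,
                               seed: int) -> ExpressionMatrix:
    """Random complete matrix with entries blanked at ``rate``, guarded so
    every row keeps >=2 observed entries and every column >=1."""
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n_genes, n_samples))
    n = max(1, int(round(rate * n_genes * n_samples)))
    for _ in range(200):
        flat = rng.choice(n_genes * n_samples, size=n, replace=False)
        mask = np.zeros((n_genes, n_samples), dtype=bool)
        mask[np.unravel_index(flat, mask.shape)] = True
        if ((~mask).sum(axis=1) >= 2).all() and ((~mask).sum(axis=0) >= 1).all():
            break
    out = vals.copy()
    out[mask] = np.nan
    return ExpressionMatrix(gene_ids=[f"g{i}" for i in range(n_genes)],
                            sample_ids=[f"s{j}" for j in range(n_samples)],
                            values=out)
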