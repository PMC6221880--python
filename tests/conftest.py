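import numpy as np
import pytest

import blupkit as bk


def random_instance(seed, n=12, n_cov=1, rank=None):
    """Random phenotype / design / genotype-derived relationship instance."""
    rng = np.random.default_rng(seed)
    r = rank if rank is not None else 3 * n
    B = rng.normal(size=(n, r))
    A = B @ B.T / r
    A = A / np.mean(np.diag(A))
    cols = [np.ones(n)] + [rng.normal(size=n) for _ in range(n_cov)]
    X = np.column_stack(cols)
    y = rng.normal(size=n) + 0.5 * rng.multivariate_normal(np.zeros(n), A)
    K = bk.KinshipMatrix([f"i{j}" for j in range(n)], A)
    return y, X, K


@pytest.fixture(scope="session")
def small_genotypes():
    cfg = bk.SimConfig(n_families=12, sibs_per_family=4, n_markers=400, seed=11)
    return bk.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def small_trait(small_genotypes):
    return bk.simulate_phenotype(small_genotypes, n_qtn=5, h2=0.75, seed=12)


@pytest.fixture(scope="session")
def small_kinship(small_genotypes):
    return bk.vanraden_kinship(small_genotypes)
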