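import numpy as np
import pytest

from dagmm import (
    CovariateMatrix,
    EdgeParams,
    FitConfig,
    GraphSupport,
    ModelFit,
    NodeMatrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dag_fit(rng, p=3, d=2, n_edges=2, re_edges=2, seed_vars=True):
    """A random acyclic ModelFit with at most `re_edges` random-effect edges.

    Edges always point from a higher to a lower node index, so acyclicity
    holds by construction.
    """
    pairs = [(j, k) for j in range(p) for k in range(j + 1, p)]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    edges = {}
    n_re = 0
    for i in idx:
        j, k = pairs[i]
        s2 = 0.0
        if n_re < re_edges:
            s2 = float(rng.uniform(0.1, 0.6))
            n_re += 1
        edges[(j, k)] = EdgeParams(j, k, rng.normal(size=d), s2)
    error_vars = rng.uniform(0.5, 1.5, size=p) if seed_vars else np.ones(p)
    fit = ModelFit(
        GraphSupport(edges.keys()), edges, error_vars, 0.0, 0.0,
        sum(d + 1 for _ in edges) + p,
    )
    return fit


@pytest.fixture
def small_data(rng):
    """A small dataset with one real edge (parent 1 -> child 0)."""
    n = 120
    X = CovariateMatrix(np.column_stack([rng.normal(size=n), rng.binomial(1, 0.5, n)]))
    m1 = rng.normal(size=n)
    m0 = (0.8 * X.values[:, 0] - 0.6) * m1 + rng.normal(scale=0.7, size=n)
    M = NodeMatrix(np.column_stack([m0, m1]))
    return M, X


@pytest.fixture
def fast_cfg():
    """Small grids so skeleton tuning stays quick in unit tests."""
    return FitConfig(n_lambda=12, lambda_min_ratio=1e-4)
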