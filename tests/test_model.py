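"""Likelihood evaluation, per-node fitting, BIC, and the quadrature oracle."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

import dagmm
from dagmm import (
    CovariateMatrix,
    EdgeParams,
    GraphSupport,
    ModelFit,
    NodeMatrix,
    bic,
    fit_node,
    fit_support,
    neg_log_likelihood,
)
from dagmm.model import _node_design, marginal_density_oracle, node_objective

from conftest import random_dag_fit


def _fit_from_params(edges, error_vars, p):
    params = {(j, k): EdgeParams(j, k, b, s2) for (j, k), (b, s2) in edges.items()}
    return ModelFit(
        GraphSupport(params.keys()), params, np.asarray(error_vars, float),
        0.0, 0.0, sum(len(b) + 1 for b, _ in edges.values()) + p,
    )


class TestNegLogLikelihood:
    def test_empty_support_is_iid_gaussian_quadratic_form(self, rng):
        m = rng.normal(size=40)
        v = 0.8
        M = NodeMatrix(m[:, None])
        X = CovariateMatrix(rng.normal(size=(40, 2)))
        fit = _fit_from_params({}, [v], 1)
        expected = np.sum(m**2 / v + math.log(v))
        assert neg_log_likelihood(M, X, fit) == pytest.approx(expected, rel=1e-12)

    def test_zero_random_effect_matches_weighted_regression(self, small_data):
        M, X = small_data
        beta = np.array([0.5, -0.3])
        ev = np.array([0.6, 1.1])
        fit = _fit_from_params({(0, 1): (beta, 0.0)}, ev, 2)
        r = M.values[:, 0] - (X.values @ beta) * M.values[:, 1]
        expected = (
            np.sum(r**2 / ev[0] + math.log(ev[0]))
            + np.sum(M.values[:, 1] ** 2 / ev[1] + math.log(ev[1]))
        )
        assert neg_log_likelihood(M, X, fit) == pytest.approx(expected, rel=1e-12)

    def test_matches_quadrature_oracle_on_random_dag(self, rng):
        """Closed form equals -2 log of the integrated density plus the
        omitted 2*pi constant, on a random 3-node DAG."""
        n, p, d = 50, 3, 2
        fit = random_dag_fit(rng, p=p, d=d, n_edges=3, re_edges=2)
        X = CovariateMatrix(rng.normal(size=(n, d)))
        M = NodeMatrix(rng.normal(size=(n, p)))
        closed = neg_log_likelihood(M, X, fit)
        from_oracle = 0.0
        for i in range(n):
            dens = marginal_density_oracle(M.values[i], X.values[i], fit, 64)
            from_oracle += -2.0 * math.log(dens)
        from_oracle -= n * p * math.log(2 * math.pi)
        assert closed == pytest.approx(from_oracle, rel=1e-4)

    def test_separability_over_nodes(self, rng):
        n, p, d = 30, 4, 2
        fit = random_dag_fit(rng, p=p, d=d, n_edges=4, re_edges=3)
        X = CovariateMatrix(rng.normal(size=(n, d)))
        M = NodeMatrix(rng.normal(size=(n, p)))
        total = 0.0
        for j, nf in fit.node_fits().items():
            Z, A = _node_design(M.values, X.values, j, nf.parents)
            total += node_objective(
                M.values[:, j], Z, A, nf.beta.ravel(), nf.sigma2, nf.error_var
            )
        assert neg_log_likelihood(M, X, fit) == pytest.approx(total, abs=1e-10)

    def test_dimension_mismatch_raises(self, rng, small_data):
        M, X = small_data
        fit = _fit_from_params({}, [1.0], 1)
        with pytest.raises(ValueError):
            neg_log_likelihood(M, X, fit)


class TestOracle:
    def test_no_random_effects_closed_form_gaussian(self, rng):
        p, d = 3, 2
        fit = random_dag_fit(rng, p=p, d=d, n_edges=2, re_edges=0)
        x = rng.normal(size=d)
        m = rng.normal(size=p)
        dens = marginal_density_oracle(m, x, fit, 16)
        log_expected = 0.0
        for j in range(p):
            mean = sum(
                float(fit.edge_params[(j, k)].beta @ x) * m[k]
                for k in fit.support.parents_of(j)
            )
            v = fit.error_vars[j]
            log_expected += -0.5 * math.log(2 * math.pi * v) - 0.5 * (m[j] - mean) ** 2 / v
        assert dens == pytest.approx(math.exp(log_expected), rel=1e-12)

    def test_single_random_effect_matches_node_factor(self, rng):
        """1-D quadrature equals the closed-form marginal Gaussian factor."""
        beta = np.array([0.4, -0.2])
        fit = _fit_from_params({(0, 1): (beta, 0.3)}, [0.7, 1.2], 2)
        x = np.array([0.5, 1.0])
        m = np.array([1.3, -0.8])
        dens = marginal_density_oracle(m, x, fit, 64)
        log_expected = 0.0
        for j, v, mean in [
            (0, 0.3 * m[1] ** 2 + 0.7, float(beta @ x) * m[1]),
            (1, 1.2, 0.0),
        ]:
            log_expected += -0.5 * math.log(2 * math.pi * v) - 0.5 * (m[j] - mean) ** 2 / v
        assert dens == pytest.approx(math.exp(log_expected), rel=1e-6)

    def test_two_random_effects_factorize_over_children(self, rng):
        """Tensor quadrature over two children equals the product of the
        per-child 1-D integrals (node separability)."""
        b = np.array([0.3, 0.1])
        fit = _fit_from_params(
            {(0, 2): (b, 0.4), (1, 2): (-b, 0.2)}, [0.9, 0.6, 1.1], 3
        )
        x = np.array([0.2, -1.0])
        m = np.array([0.5, -0.3, 1.7])
        joint = marginal_density_oracle(m, x, fit, 48)
        f0 = _fit_from_params({(0, 2): (b, 0.4)}, [0.9, 0.6, 1.1], 3)
        f1 = _fit_from_params({(1, 2): (-b, 0.2)}, [0.9, 0.6, 1.1], 3)
        d0 = marginal_density_oracle(m, x, f0, 48)
        d1 = marginal_density_oracle(m, x, f1, 48)
        null = _fit_from_params({}, [0.9, 0.6, 1.1], 3)
        dn = marginal_density_oracle(m, x, null, 48)
        assert joint == pytest.approx(d0 * d1 / dn, rel=1e-8)

    def test_too_many_random_effects_rejected(self, rng):
        fit = random_dag_fit(rng, p=5, d=2, n_edges=4, re_edges=4)
        with pytest.raises(ValueError, match="at most 3"):
            marginal_density_oracle(np.zeros(5), np.zeros(2), fit, 8)

    def test_cyclic_support_rejected(self):
        fit = ModelFit.__new__(ModelFit)  # bypass validation for the cycle
        fit.support = GraphSupport([(0, 1), (1, 0)])
        fit.edge_params = {
            e: EdgeParams(*e, np.zeros(1), 0.0) for e in fit.support
        }
        fit.error_vars = np.ones(2)
        with pytest.raises(ValueError, match="acyclic"):
            marginal_density_oracle(np.zeros(2), np.zeros(1), fit, 8)


class TestFitNode:
    def test_no_parents_closed_form(self, rng, small_data):
        M, X = small_data
        nf = fit_node(1, (), M, X)
        m = M.values[:, 1]
        assert nf.error_var == pytest.approx(np.mean(m**2), rel=1e-12)
        assert nf.nll == pytest.approx(
            len(m) * (1 + math.log(np.mean(m**2))), rel=1e-12
        )

    def test_recovers_single_edge_parameters(self, small_data):
        M, X = small_data
        nf = fit_node(0, (1,), M, X)
        assert nf.beta[0] == pytest.approx([0.8, -0.6], abs=0.15)
        assert nf.error_var == pytest.approx(0.49, abs=0.2)

    def test_matches_general_purpose_optimizer(self):
        """Node objective agrees with a generic minimizer started from the
        generating truth (mixed-effects data, true parent set)."""
        truth = dagmm.make_setting(3, 2000, 20, seed=5)
        M, X = dagmm.simulate_data(truth)
        parents = (1, 2, 3)  # true parents of node 0
        nf = fit_node(0, parents, M, X)
        Z, A = _node_design(M.values, X.values, 0, parents)
        m = M.values[:, 0]
        K, d = len(parents), X.d

        def obj(th):
            return node_objective(
                m, Z, A, th[: K * d], np.exp(th[K * d : K * d + K]),
                float(np.exp(th[-1])),
            )

        beta0 = np.tile([-0.5, 1.0, -1.5], K)
        x0 = np.concatenate([beta0, np.log(np.full(K, 0.5)), [math.log(1.0)]])
        res = minimize(obj, x0, method="Nelder-Mead",
                       options=dict(maxiter=40000, fatol=1e-12, xatol=1e-9))
        res = minimize(obj, res.x, method="Nelder-Mead",
                       options=dict(maxiter=40000, fatol=1e-13, xatol=1e-10))
        assert nf.nll == pytest.approx(res.fun, rel=1e-6)
        assert nf.nll <= res.fun + 1e-6 * abs(res.fun)

    def test_nesting_monotonicity(self, rng):
        """Dropping a parent cannot decrease the minimized node objective."""
        truth = dagmm.make_setting(3, 400, 20, seed=9)
        M, X = dagmm.simulate_data(truth)
        full = fit_node(0, (1, 2, 3), M, X)
        for drop in (1, 2, 3):
            sub = fit_node(0, tuple(k for k in (1, 2, 3) if k != drop), M, X)
            assert sub.nll >= full.nll - 1e-6 * (abs(full.nll) + 1)

    def test_too_few_observations_raises(self, rng):
        M = NodeMatrix(rng.normal(size=(6, 3)))
        X = CovariateMatrix(rng.normal(size=(6, 3)))
        with pytest.raises(ValueError, match="free parameters"):
            fit_node(0, (1, 2), M, X)

    def test_self_parent_raises(self, small_data):
        M, X = small_data
        with pytest.raises(ValueError):
            fit_node(0, (0, 1), M, X)


class TestBic:
    def test_values(self):
        fit = _fit_from_params({}, [1.0], 1)
        fit.nll, fit.n_params = 0.0, 0
        assert bic(fit, 10) == 0.0
        fit.nll, fit.n_params = 10.0, 3
        assert bic(fit, round(math.e**2)) == pytest.approx(20 + 3 * math.log(round(math.e**2)))
        with pytest.raises(ValueError):
            bic(fit, 1)

    def test_nested_difference_identity(self, small_data):
        M, X = small_data
        f_full = fit_support(GraphSupport([(0, 1)]), M, X)
        f_null = fit_support(GraphSupport([]), M, X)
        dk = f_full.n_params - f_null.n_params
        expected = 2 * (f_full.nll - f_null.nll) + dk * math.log(M.n)
        assert f_full.bic - f_null.bic == pytest.approx(expected, rel=1e-12)


class TestDeterminantIdentity:
    def test_unit_determinant_on_random_dags(self, rng):
        """det(I - B(X) - Gamma) = 1 for any DAG-compatible coefficients."""
        for _ in range(25):
            p = int(rng.integers(2, 8))
            fit = random_dag_fit(rng, p=p, d=2, n_edges=min(6, p * (p - 1) // 2),
                                 re_edges=3)
            x = rng.normal(size=2)
            total = np.zeros((p, p))
            for (j, k), ep in fit.edge_params.items():
                total[j, k] = float(ep.beta @ x) + rng.normal() * math.sqrt(ep.sigma2)
            assert np.linalg.det(np.eye(p) - total) == pytest.approx(1.0, abs=1e-8)


class TestIdentifiabilitySmoke:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_true_orientation_has_lower_objective(self, seed):
        """With heterogeneous covariate effects the minimized objective at
        the generating orientation beats the reversed one (2 nodes, large n)."""
        rng = np.random.default_rng(seed)
        n = 5000
        X = CovariateMatrix(
            np.column_stack([rng.normal(size=n), rng.binomial(1, 0.5, n)])
        )
        m2 = rng.normal(size=n)
        coef = X.values @ np.array([1.0, -1.2]) + rng.normal(scale=math.sqrt(0.5), size=n)
        m1 = coef * m2 + rng.normal(scale=0.8, size=n)
        M = NodeMatrix(np.column_stack([m1, m2]))
        fwd = fit_node(0, (1,), M, X).nll + fit_node(1, (), M, X).nll
        rev = fit_node(1, (0,), M, X).nll + fit_node(0, (), M, X).nll
        assert fwd < rev


class TestContainers:
    def test_covariate_intercept_flag_validated(self, rng):
        with pytest.raises(ValueError, match="constant 1"):
            CovariateMatrix(rng.normal(size=(5, 2)), has_intercept=True)

    def test_with_intercept_prepends_ones(self, rng):
        X = CovariateMatrix(rng.normal(size=(5, 2)))
        Xi = X.with_intercept()
        assert Xi.has_intercept and Xi.d == 3
        assert np.all(Xi.values[:, 0] == 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            NodeMatrix(np.array([[1.0, np.nan]]))

    def test_support_rejects_self_loops(self):
        with pytest.raises(ValueError):
            GraphSupport([(1, 1)])

    def test_negative_error_variance_rejected(self):
        with pytest.raises(ValueError):
            ModelFit(GraphSupport([]), {}, np.array([0.0]), 0.0, 0.0, 1)
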