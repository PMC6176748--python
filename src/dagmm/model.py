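"""Mixed-effects structural equation model (mSEM) for subject-specific DAGs.

Each node j of a directed acyclic graph satisfies, for subject i,

    M_ij = sum_{k in pa(j)} (beta_jk' X_i + gamma_ijk) * M_ik + eps_ij,

where ``beta_jk`` is a vector of covariate-driven fixed effects,
``gamma_ijk ~ N(0, sigma2_jk)`` is a subject-level random effect capturing
latent heterogeneity of the edge strength, and ``eps_ij ~ N(0, sigma2_eps_j)``.
An edge k -> j is present when ``beta_jk != 0`` or ``sigma2_jk > 0``.

Because the Jacobian of the structural system has unit determinant for any
acyclic support, the marginal likelihood integrates in closed form and the
(constant-free) negative log-likelihood separates over nodes:

    l_n = sum_i sum_j [ r_ij^2 / v_ij + log v_ij ],
    r_ij = M_ij - sum_k (beta_jk' X_i) M_ik,
    v_ij = sum_k sigma2_jk M_ik^2 + sigma2_eps_j.

This module holds the data containers, evaluates ``l_n``, fits the parameters
of a node given its parent set (weighted least squares for the fixed effects
alternating with a safeguarded Newton-Raphson on log-variances), computes BIC,
and provides a numerical-quadrature density oracle used only for testing the
closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import nnls

from ._graph import topological_order

__all__ = [
    "NodeMatrix",
    "CovariateMatrix",
    "EdgeParams",
    "GraphSupport",
    "NodeFit",
    "ModelFit",
    "FitConfig",
    "neg_log_likelihood",
    "node_objective",
    "fit_node",
    "fit_support",
    "bic",
    "marginal_density_oracle",
]


def _check_matrix(values: np.ndarray, names: list[str], what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"{what} values must be 2-D, got shape {values.shape}")
    n, p = values.shape
    if n < 1 or p < 1:
        raise ValueError(f"{what} must have at least one row and one column")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what} contains non-finite entries")
    if len(names) != p:
        raise ValueError(
            f"{what} has {p} columns but {len(names)} names were given"
        )
    return values


@dataclass
class NodeMatrix:
    """n subjects x p nodes of (assumed centered) observations."""

    values: np.ndarray
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_names:
            self.node_names = [f"M{j + 1}" for j in range(np.asarray(self.values).shape[1])]
        self.values = _check_matrix(self.values, self.node_names, "node matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateMatrix:
    """n subjects x d exogenous covariates; optionally led by a ones column."""

    values: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    has_intercept: bool = False

    def __post_init__(self) -> None:
        if not self.covariate_names:
            d = np.asarray(self.values).shape[1]
            names = [f"X{l + 1}" for l in range(d)]
            if self.has_intercept:
                names[0] = "intercept"
            self.covariate_names = names
        self.values = _check_matrix(self.values, self.covariate_names, "covariate matrix")
        if self.has_intercept and not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("has_intercept is set but first column is not constant 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def with_intercept(self) -> "CovariateMatrix":
        """Return a copy with a leading constant-1 column prepended."""
        if self.has_intercept:
            return self
        ones = np.ones((self.n, 1))
        return CovariateMatrix(
            np.hstack([ones, self.values]),
            ["intercept", *self.covariate_names],
            has_intercept=True,
        )


@dataclass(frozen=True)
class EdgeParams:
    """Parameters of the directed edge parent -> child (indices 0-based).

    ``beta_mask`` marks which fixed-effect coefficients are free; masked
    entries are structural zeros carried over from the penalized screening
    step (None means all free).
    """

    child: int
    parent: int
    beta: np.ndarray
    sigma2: float
    beta_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.child == self.parent:
            raise ValueError("self-loops are not allowed")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if self.beta_mask is not None:
            mask = np.atleast_1d(np.asarray(self.beta_mask, dtype=bool))
            if mask.shape != self.beta.shape:
                raise ValueError("beta_mask shape differs from beta")
            if np.any(self.beta[~mask] != 0.0):
                raise ValueError("masked beta entries must be zero")
            object.__setattr__(self, "beta_mask", mask)

    @property
    def n_free_beta(self) -> int:
        return int(self.beta_mask.sum()) if self.beta_mask is not None else self.beta.size


class GraphSupport:
    """A set of directed edges stored as (child, parent) pairs.

    The pair (j, k) means k is a parent of j, i.e. the arrow k -> j.
    """

    __slots__ = ("edges",)

    def __init__(self, edges=()):
        edges = frozenset((int(j), int(k)) for j, k in edges)
        for j, k in edges:
            if j == k:
                raise ValueError(f"self-loop on node {j}")
        self.edges = edges

    def __contains__(self, edge) -> bool:
        return tuple(edge) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges))

    def __eq__(self, other) -> bool:
        return isinstance(other, GraphSupport) and self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)

    def __repr__(self) -> str:
        return f"GraphSupport({sorted(self.edges)!r})"

    def parents_of(self, j: int) -> tuple[int, ...]:
        return tuple(sorted(k for (c, k) in self.edges if c == j))

    def bidirected_pairs(self) -> list[tuple[int, int]]:
        """Ordered pairs (j, k) such that both (j, k) and (k, j) are present."""
        return sorted((j, k) for (j, k) in self.edges if (k, j) in self.edges)

    def remove(self, edge) -> "GraphSupport":
        return GraphSupport(self.edges - {tuple(edge)})

    def issubset(self, other: "GraphSupport") -> bool:
        return self.edges <= other.edges


@dataclass
class NodeFit:
    """Fitted parameters for one node given its parent set."""

    node: int
    parents: tuple[int, ...]
    beta: np.ndarray  # (len(parents), d); structural zeros where masked
    sigma2: np.ndarray  # (len(parents),)
    error_var: float
    nll: float
    converged: bool = True
    n_iter: int = 0
    beta_mask: np.ndarray | None = None  # (len(parents), d) bool, None = all free

    @property
    def n_params(self) -> int:
        # Each edge is charged its full coefficient budget (d betas + 1
        # variance) even when screening froze some coefficients at zero:
        # edges are the selection unit, and the frozen zeros are
        # data-dependent choices rather than genuine dimension reductions.
        k = len(self.parents)
        d = self.beta.shape[1] if k else 0
        return k * d + k + 1


@dataclass
class ModelFit:
    """A graph support together with all mSEM parameter estimates."""

    support: GraphSupport
    edge_params: dict[tuple[int, int], EdgeParams]
    error_vars: np.ndarray
    nll: float
    bic: float
    n_params: int
    node_nll: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.error_vars = np.asarray(self.error_vars, dtype=float)
        if np.any(self.error_vars <= 0):
            raise ValueError("error variances must be strictly positive")
        if not np.isfinite(self.nll):
            raise ValueError("nll must be finite")

    @property
    def p(self) -> int:
        return len(self.error_vars)

    def node_fits(self) -> dict[int, NodeFit]:
        """Re-group edge parameters per child node."""
        out: dict[int, NodeFit] = {}
        nn = self.node_nll if self.node_nll is not None else np.full(self.p, np.nan)
        for j in range(self.p):
            parents = self.support.parents_of(j)
            mask = None
            if parents:
                eps = [self.edge_params[(j, k)] for k in parents]
                beta = np.vstack([ep.beta for ep in eps])
                sigma2 = np.array([ep.sigma2 for ep in eps])
                if any(ep.beta_mask is not None for ep in eps):
                    mask = np.vstack(
                        [
                            ep.beta_mask
                            if ep.beta_mask is not None
                            else np.ones(ep.beta.size, dtype=bool)
                            for ep in eps
                        ]
                    )
            else:
                beta = np.zeros((0, 0))
                sigma2 = np.zeros(0)
            out[j] = NodeFit(
                j, parents, beta, sigma2, float(self.error_vars[j]), float(nn[j]),
                beta_mask=mask,
            )
        return out


@dataclass
class FitConfig:
    """Tuning knobs for estimation and the penalized skeleton search."""

    max_iter: int = 100
    rel_tol: float = 1e-6
    variance_floor: float = 1e-8
    lambda1_grid: np.ndarray | None = None
    lambda2_grid: np.ndarray | None = None
    n_lambda: int = 40
    lambda_min_ratio: float = 1e-5
    cd_tol: float = 1e-7
    cd_max_sweeps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        for name in ("lambda1_grid", "lambda2_grid"):
            g = getattr(self, name)
            if g is not None:
                g = np.asarray(g, dtype=float)
                if g.size == 0 or np.any(g <= 0):
                    raise ValueError(f"{name} must be non-empty and positive")
                setattr(self, name, np.sort(g)[::-1])


# ---------------------------------------------------------------------------
# likelihood evaluation


def _node_design(M: np.ndarray, X: np.ndarray, j: int, parents: tuple[int, ...]):
    """Interaction design Z (n x K*d, parent-major) and squared-parent matrix A."""
    Mp = M[:, list(parents)]
    n, d = X.shape
    # column block for parent k is X * M_k
    Z = (Mp[:, :, None] * X[:, None, :]).reshape(n, len(parents) * d)
    A = Mp**2
    return Z, A


def node_objective(
    m: np.ndarray, Z: np.ndarray, A: np.ndarray,
    beta: np.ndarray, sigma2: np.ndarray, error_var: float,
) -> float:
    """Constant-free per-node negative log-likelihood term."""
    r = m - Z @ beta if beta.size else m
    v = A @ sigma2 + error_var if sigma2.size else np.full(m.shape, error_var)
    if np.any(v <= 0):
        raise ValueError("non-positive variance in likelihood evaluation")
    return float(np.sum(r**2 / v + np.log(v)))


def neg_log_likelihood(M: NodeMatrix, X: CovariateMatrix, fit: ModelFit) -> float:
    """Evaluate the constant-free marginal negative log-likelihood.

    Edges absent from ``fit.support`` contribute beta = 0 and sigma2 = 0; the
    additive ``n p log(2 pi)`` constant is omitted.
    """
    if M.n != X.n:
        raise ValueError("node and covariate matrices have different row counts")
    if fit.p != M.p:
        raise ValueError("fit dimension does not match node matrix")
    total = 0.0
    for j, nf in fit.node_fits().items():
        Z, A = _node_design(M.values, X.values, j, nf.parents)
        total += node_objective(
            M.values[:, j], Z, A, nf.beta.ravel(), nf.sigma2, nf.error_var
        )
    return total


def bic(fit: ModelFit, n: int) -> float:
    """Bayesian information criterion 2*nll + n_params*log(n)."""
    if n <= 1:
        raise ValueError("n must exceed 1")
    return 2.0 * fit.nll + fit.n_params * math.log(n)


# ---------------------------------------------------------------------------
# per-node estimation


def _variance_newton(
    r2: np.ndarray, Aa: np.ndarray, u: np.ndarray,
    floor_log: float, max_steps: int = 12, tol: float = 1e-9,
):
    """Minimize sum(r2/v + log v), v = Aa @ exp(u), over log-variances u.

    Safeguarded Newton-Raphson: the step is halved (Armijo backtracking) when
    the objective does not decrease, and the Hessian is ridge-regularized when
    it is not positive definite. ``u`` is clipped below at ``floor_log``.
    """

    def clip_u(u_):
        return np.minimum(np.maximum(u_, floor_log), 25.0)

    def objective(u_):
        v = Aa @ np.exp(u_)
        return float(np.sum(r2 / v) + np.sum(np.log(v)))

    obj = objective(u)
    for _ in range(max_steps):
        theta = np.exp(u)
        v = Aa @ theta
        gv = (v - r2) / v**2
        hv = (2.0 * r2 - v) / v**3
        At = Aa * theta  # d v / d u
        grad = At.T @ gv
        H = At.T @ (At * hv[:, None]) + np.diag(grad)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(u)), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        if grad @ step >= 0:  # not a descent direction
            step = -grad
        t, g_dot = 1.0, grad @ step
        new_obj = obj
        for _ in range(16):
            u_try = clip_u(u + t * step)
            new_obj = objective(u_try)
            if new_obj <= obj + 1e-4 * t * g_dot or new_obj < obj:
                break
            t *= 0.5
        if new_obj >= obj - tol * (abs(obj) + 1.0):
            u = clip_u(u + t * step) if new_obj < obj else u
            obj = min(obj, new_obj)
            break
        u = clip_u(u + t * step)
        obj = new_obj
    return u, obj


def fit_node(
    j: int,
    parents,
    M: NodeMatrix,
    X: CovariateMatrix,
    init: tuple[np.ndarray, np.ndarray, float] | None = None,
    cfg: FitConfig | None = None,
    beta_mask: np.ndarray | None = None,
    sigma_mask: np.ndarray | None = None,
) -> NodeFit:
    """Fit node j's parameters for a fixed parent set by minimizing its
    likelihood term.

    Alternates weighted least squares for the stacked fixed effects (weights
    ``1/v_i``) with Newton-Raphson on the log variances until the relative
    change of the node objective drops below ``cfg.rel_tol``. Non-convergence
    issues a warning and returns the best iterate.

    ``beta_mask`` (len(parents) x d bool) restricts which fixed-effect
    coefficients are free; masked entries are held at zero.
    ``sigma_mask`` (len(parents) bool) likewise pins the random-effect
    variance of de-selected parents at exactly zero (used for evidence tests
    on single variance components).
    """
    cfg = cfg or FitConfig()
    parents = tuple(sorted(int(k) for k in parents))
    if j in parents:
        raise ValueError("a node cannot be its own parent")
    m = M.values[:, j]
    n = M.n
    floor = cfg.variance_floor
    K, d = len(parents), X.d

    if not parents:
        ev = max(float(np.mean(m**2)), floor)
        nll = float(np.sum(m**2) / ev + n * math.log(ev))
        return NodeFit(j, parents, np.zeros((0, d)), np.zeros(0), ev, nll)

    Z_full, A = _node_design(M.values, X.values, j, parents)
    if beta_mask is None:
        mask_flat = np.ones(K * d, dtype=bool)
    else:
        mask_flat = np.asarray(beta_mask, dtype=bool).reshape(K * d)
    Z = Z_full[:, mask_flat]
    n_beta = int(mask_flat.sum())
    if sigma_mask is None:
        smask = np.ones(K, dtype=bool)
    else:
        smask = np.asarray(sigma_mask, dtype=bool).reshape(K)
    ns = int(smask.sum())
    if n <= n_beta + ns + 1:
        raise ValueError(
            f"node {j}: n={n} does not exceed the {n_beta + ns + 1} free parameters"
        )

    Aa = np.hstack([A[:, smask], np.ones((n, 1))])
    floor_log = math.log(floor)

    # Moment-based starting point: OLS for beta, then non-negative least
    # squares of the squared residuals on the squared-parent features. The
    # moment estimators are consistent, which keeps the variance Newton out
    # of spurious local minima (e.g. all sigma2 collapsing to zero).
    if n_beta:
        G0 = Z.T @ Z
        try:
            beta0 = np.linalg.solve(G0 + 1e-10 * np.trace(G0) * np.eye(n_beta), Z.T @ m)
        except np.linalg.LinAlgError:
            beta0, *_ = np.linalg.lstsq(Z, m, rcond=None)
        r2_0 = (m - Z @ beta0) ** 2
    else:
        beta0 = np.zeros(0)
        r2_0 = m**2
    theta0, _ = nnls(Aa, r2_0)
    theta0 = np.maximum(theta0, floor)
    starts = [(beta0, np.log(theta0))]
    if init is not None:
        beta_w, sigma2_w, ev_w = init
        beta_w = np.asarray(beta_w, dtype=float).reshape(K * d)[mask_flat]
        sig_w = np.maximum(np.asarray(sigma2_w, dtype=float), floor)[smask]
        theta_w = np.concatenate([sig_w, [max(float(ev_w), floor)]])
        starts.insert(0, (beta_w, np.log(theta_w)))

    best = None
    for beta, u in starts:
        obj = np.inf
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            v = Aa @ np.exp(u)
            if n_beta:
                w = 1.0 / v
                Zw = Z * w[:, None]
                G = Z.T @ Zw
                try:
                    beta = np.linalg.solve(G, Zw.T @ m)
                except np.linalg.LinAlgError as exc:
                    raise np.linalg.LinAlgError(
                        f"singular weighted design for node {j} "
                        "(collinear parents/covariates)"
                    ) from exc
                r2 = (m - Z @ beta) ** 2
            else:
                r2 = m**2
            u, new_obj = _variance_newton(
                r2, Aa, u, floor_log, tol=0.1 * cfg.rel_tol
            )
            if np.isfinite(obj) and abs(obj - new_obj) <= cfg.rel_tol * (abs(new_obj) + 1.0):
                obj = new_obj
                converged = True
                break
            obj = new_obj
        if best is None or obj < best[0]:
            best = (obj, beta, u, converged, it)
    obj, beta, u, converged, it = best
    if not converged:
        warnings.warn(
            f"fit_node: node {j} did not converge in {cfg.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    theta = np.exp(u)
    sigma2 = np.zeros(K)
    sigma2[smask] = np.where(theta[:ns] <= 2 * floor, 0.0, theta[:ns])
    ev = max(float(theta[ns]), floor)
    beta_full = np.zeros(K * d)
    beta_full[mask_flat] = beta
    nll = node_objective(m, Z_full, A, beta_full, sigma2, ev)
    out_mask = None if beta_mask is None else mask_flat.reshape(K, d)
    return NodeFit(
        j, parents, beta_full.reshape(K, d), sigma2, ev, nll, converged, it,
        beta_mask=out_mask,
    )


def fit_support(
    support: GraphSupport,
    M: NodeMatrix,
    X: CovariateMatrix,
    cfg: FitConfig | None = None,
    warm: dict[int, NodeFit] | None = None,
    beta_masks: dict[tuple[int, int], np.ndarray] | None = None,
) -> ModelFit:
    """Fit every node on a fixed support and assemble a :class:`ModelFit`.

    ``beta_masks`` optionally maps edges to boolean coefficient masks
    (structural zeros carried over from the screening step).
    """
    cfg = cfg or FitConfig()
    node_fits = {}
    for j in range(M.p):
        parents = support.parents_of(j)
        if warm is not None and j in warm and warm[j].parents == parents:
            node_fits[j] = warm[j]
            continue
        mask = None
        if beta_masks is not None and parents:
            mask = np.vstack(
                [
                    beta_masks.get((j, k), np.ones(X.d, dtype=bool))
                    for k in parents
                ]
            )
        node_fits[j] = fit_node(j, parents, M, X, None, cfg, beta_mask=mask)
    return assemble_fit(node_fits, M.n)


def assemble_fit(node_fits: dict[int, NodeFit], n: int) -> ModelFit:
    """Combine per-node fits into a ModelFit with total NLL and BIC."""
    edges = []
    edge_params = {}
    p = len(node_fits)
    error_vars = np.empty(p)
    node_nll = np.empty(p)
    n_params = 0
    converged = True
    for j, nf in node_fits.items():
        error_vars[j] = nf.error_var
        node_nll[j] = nf.nll
        n_params += nf.n_params
        converged &= nf.converged
        for idx, k in enumerate(nf.parents):
            edges.append((j, k))
            mask = None if nf.beta_mask is None else nf.beta_mask[idx]
            edge_params[(j, k)] = EdgeParams(
                j, k, nf.beta[idx], float(nf.sigma2[idx]), beta_mask=mask
            )
    nll = float(np.sum(node_nll))
    fit = ModelFit(
        GraphSupport(edges), edge_params, error_vars, nll, np.nan, n_params,
        node_nll=node_nll, converged=converged,
    )
    fit.bic = bic(fit, n)
    return fit


# ---------------------------------------------------------------------------
# quadrature oracle (testing only)


def marginal_density_oracle(
    row_m: np.ndarray,
    row_x: np.ndarray,
    fit: ModelFit,
    quad_points: int = 64,
) -> float:
    """Marginal density of one subject's node vector by Gauss-Hermite
    quadrature over the random effects.

    Integrates the conditional Gaussian density of the structural system (unit
    Jacobian for any acyclic support) against the random-effect distribution on
    a tensor grid. Supports at most three random-effect edges; used only as an
    independent oracle for :func:`neg_log_likelihood` in the test suite.
    """
    row_m = np.asarray(row_m, dtype=float)
    row_x = np.asarray(row_x, dtype=float)
    p = fit.p
    acyclic = topological_order(fit.support.edges, p)[0]
    if not acyclic:
        raise ValueError("oracle requires an acyclic support")
    re_edges = [e for e in fit.support if fit.edge_params[e].sigma2 > 1e-12]
    if len(re_edges) > 3:
        raise ValueError("oracle supports at most 3 random-effect edges")

    def conditional_density(gamma: np.ndarray) -> float:
        # gamma aligned with re_edges
        log_dens = 0.0
        for j in range(p):
            mean = 0.0
            for k in fit.support.parents_of(j):
                coef = float(fit.edge_params[(j, k)].beta @ row_x)
                if (j, k) in re_edges:
                    coef += gamma[re_edges.index((j, k))]
                mean += coef * row_m[k]
            ev = fit.error_vars[j]
            log_dens += -0.5 * math.log(2 * math.pi * ev) - 0.5 * (row_m[j] - mean) ** 2 / ev
        return math.exp(log_dens)

    if not re_edges:
        return conditional_density(np.zeros(0))

    # probabilists' Hermite rule: integral of f against N(0,1) weights
    nodes, weights = hermegauss(quad_points)
    weights = weights / math.sqrt(2 * math.pi)
    sds = np.array([math.sqrt(fit.edge_params[e].sigma2) for e in re_edges])
    total = 0.0
    grids = np.meshgrid(*([nodes] * len(re_edges)), indexing="ij")
    wgrids = np.meshgrid(*([weights] * len(re_edges)), indexing="ij")
    flat = [g.ravel() for g in grids]
    wflat = np.prod([w.ravel() for w in wgrids], axis=0)
    for idx in range(len(wflat)):
        gamma = sds * np.array([f[idx] for f in flat])
        total += wflat[idx] * conditional_density(gamma)
    return float(total)
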