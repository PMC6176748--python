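"""Edge orientation and hard-thresholded DAG search (the DAG-MM procedure).

Starting from the refit initial skeleton, the search (i) resolves every
bidirected pair by deleting the direction with the smaller strength ratio
``r_jk = c_jk / c_kj`` where ``c_jk = ||beta_jk||^2 / d + sigma2_jk``, and
(ii) greedily prunes the weakest edge, refitting only the affected child node
(the likelihood separates over nodes), recording BIC at every acyclic support
and returning the BIC-optimal DAG. The search only deletes edges, so the
final support is nested inside the oriented support, which is nested inside
the skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import skeleton as _skeleton
from ._graph import topological_order
from .model import (
    CovariateMatrix,
    EdgeParams,
    FitConfig,
    GraphSupport,
    ModelFit,
    NodeFit,
    NodeMatrix,
    assemble_fit,
    fit_node,
)

__all__ = [
    "SearchSnapshot",
    "SearchTrace",
    "edge_strength",
    "is_dag",
    "orient_edges",
    "build_dag",
    "dagmm_fit",
]


def edge_strength(params: EdgeParams, d_norm: int) -> float:
    """Pruning strength c_jk = ||beta_jk||^2 / d_norm + sigma2_jk."""
    if d_norm < 1:
        raise ValueError("d_norm must be at least 1")
    return float(params.beta @ params.beta) / d_norm + params.sigma2


def is_dag(support: GraphSupport, p: int):
    """Acyclicity check via Kahn's algorithm.

    Returns ``(True, topological_order)`` or ``(False, cycle)`` where the
    cycle is a witnessing list of nodes.
    """
    return topological_order(support.edges, p)


@dataclass
class SearchSnapshot:
    support: GraphSupport
    nll: float
    n_params: int
    is_dag: bool
    bic: float | None = None  # computed only at acyclic supports


@dataclass
class SearchTrace:
    snapshots: list[SearchSnapshot] = field(default_factory=list)
    best_index: int | None = None
    removed_edges: list[tuple[int, int]] = field(default_factory=list)


class _NodeFitCache:
    """Per-child fit bookkeeping so an edge removal refits one node only."""

    def __init__(self, M: NodeMatrix, X: CovariateMatrix, cfg: FitConfig,
                 node_fits: dict[int, NodeFit]):
        self.M, self.X, self.cfg = M, X, cfg
        self.fits = dict(node_fits)

    def refit(self, j: int, parents: tuple[int, ...]) -> None:
        old = self.fits[j]
        init = None
        mask = None
        if old.parents and set(parents) <= set(old.parents):
            keep = [old.parents.index(k) for k in parents]
            if keep:
                init = (old.beta[keep], old.sigma2[keep], old.error_var)
                if old.beta_mask is not None:
                    mask = old.beta_mask[keep]
        self.fits[j] = fit_node(
            j, parents, self.M, self.X, init, self.cfg, beta_mask=mask
        )

    def strengths(self, support: GraphSupport) -> dict[tuple[int, int], float]:
        d = self.X.d
        out = {}
        for j, k in support:
            nf = self.fits[j]
            idx = nf.parents.index(k)
            out[(j, k)] = float(nf.beta[idx] @ nf.beta[idx]) / d + float(nf.sigma2[idx])
        return out

    def assemble(self) -> ModelFit:
        return assemble_fit(self.fits, self.M.n)


def orient_edges(
    skeleton_fit: ModelFit,
    M: NodeMatrix,
    X: CovariateMatrix,
    cfg: FitConfig | None = None,
) -> ModelFit:
    """Resolve bidirected pairs by relative edge strength.

    While some pair is present in both directions, remove the single
    direction with the smallest ratio r_jk = c_jk / c_kj (lexicographic
    (child, parent) tie-break) and refit the child that lost a parent.
    """
    cfg = cfg or FitConfig()
    support = skeleton_fit.support
    cache = _NodeFitCache(M, X, cfg, skeleton_fit.node_fits())
    while True:
        pairs = support.bidirected_pairs()
        if not pairs:
            break
        c = cache.strengths(support)
        tiny = 1e-300
        best = min(pairs, key=lambda jk: (c[jk] / max(c[(jk[1], jk[0])], tiny), jk))
        support = support.remove(best)
        cache.refit(best[0], support.parents_of(best[0]))
    return cache.assemble()


def build_dag(
    oriented_fit: ModelFit,
    M: NodeMatrix,
    X: CovariateMatrix,
    cfg: FitConfig | None = None,
) -> tuple[ModelFit, SearchTrace]:
    """Iterative hard-thresholding search for the BIC-optimal DAG.

    Repeatedly records the current support (computing BIC whenever it is
    acyclic), removes the minimum-strength edge, and refits the affected
    child, until the support is empty. Returns the fit at the BIC-optimal
    acyclic snapshot together with the full trace.
    """
    cfg = cfg or FitConfig()
    if oriented_fit.support.bidirected_pairs():
        raise ValueError("build_dag requires an oriented support (no 2-cycles)")
    support = oriented_fit.support
    cache = _NodeFitCache(M, X, cfg, oriented_fit.node_fits())
    trace = SearchTrace()
    best_bic = np.inf
    best_fit: ModelFit | None = None
    while True:
        fit = cache.assemble()
        acyclic, _ = is_dag(support, M.p)
        snap = SearchSnapshot(support, fit.nll, fit.n_params, acyclic)
        if acyclic:
            snap.bic = fit.bic
            if fit.bic < best_bic:
                best_bic = fit.bic
                best_fit = fit
                trace.best_index = len(trace.snapshots)
        trace.snapshots.append(snap)
        if len(support) == 0:
            break
        c = cache.strengths(support)
        drop = min(support, key=lambda jk: (c[jk], jk))
        trace.removed_edges.append(drop)
        support = support.remove(drop)
        cache.refit(drop[0], support.parents_of(drop[0]))
    assert best_fit is not None  # the empty graph is always a DAG
    return best_fit, trace


def dagmm_fit(
    M: NodeMatrix,
    X: CovariateMatrix,
    cfg: FitConfig | None = None,
    return_skeleton: bool = False,
):
    """Full DAG-MM pipeline: skeleton -> orientation -> DAG search.

    Returns ``(fit, trace)``, or ``(fit, trace, skeleton_estimate,
    oriented_fit)`` when ``return_skeleton`` is set.
    """
    cfg = cfg or FitConfig()
    skel = _skeleton.initial_skeleton(M, X, cfg)
    oriented = orient_edges(skel.refit, M, X, cfg)
    best, trace = build_dag(oriented, M, X, cfg)
    if return_skeleton:
        return best, trace, skel, oriented
    return best, trace
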