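"""Scoring of estimated graphs and parameters against a generating truth.

Edge recovery is counted on directed pairs: an edge recovered with the wrong
direction contributes one false positive and one false negative. Estimation
error is reported as root-sum-squared (RSS) differences over all ordered node
pairs, with zeros imputed for pairs absent from either side, so false-positive
edges are penalized too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GraphSupport, ModelFit
from .simulate import SimulationTruth

__all__ = ["EdgeConfusion", "RssReport", "edge_confusion", "rss_metrics",
           "possible_edge_count"]


@dataclass(frozen=True)
class EdgeConfusion:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class RssReport:
    rss_beta: float
    rss_sigma2: float
    rss_sigma_eps: float


def possible_edge_count(p: int) -> int:
    """Number of possible directed edges among p nodes, p(p-1)."""
    if p < 1:
        raise ValueError("p must be positive")
    return p * (p - 1)


def edge_confusion(estimated: GraphSupport, truth: SimulationTruth) -> EdgeConfusion:
    """Directed true/false positive and false negative counts."""
    est = set(estimated.edges)
    true = set(truth.edges.keys())
    for j, k in est:
        if j >= truth.p or k >= truth.p:
            raise ValueError("estimated support references nodes beyond the truth")
    return EdgeConfusion(
        tp=len(est & true), fp=len(est - true), fn=len(true - est)
    )


def rss_metrics(fit: ModelFit, truth: SimulationTruth) -> RssReport:
    """Root-sum-squared errors of beta, sigma2, and error variances."""
    p, d = truth.p, truth.d
    if fit.p != p:
        raise ValueError("fit and truth have different node counts")
    for ep in fit.edge_params.values():
        if ep.beta.shape != (d,):
            raise ValueError(
                f"edge ({ep.child},{ep.parent}): beta has length "
                f"{ep.beta.shape[0]}, truth uses d={d} covariates"
            )
    beta_sq = 0.0
    sig_sq = 0.0
    pairs = set(fit.edge_params) | set(truth.edges)
    for j, k in pairs:
        b_hat, s_hat = np.zeros(d), 0.0
        if (j, k) in fit.edge_params:
            ep = fit.edge_params[(j, k)]
            b_hat, s_hat = ep.beta, ep.sigma2
        b_true, s_true = np.zeros(d), 0.0
        if (j, k) in truth.edges:
            b_true, s_true = truth.edges[(j, k)]
        diff = b_hat - b_true
        beta_sq += float(diff @ diff)
        sig_sq += (s_hat - s_true) ** 2
    eps_sq = float(np.sum((fit.error_vars - truth.error_vars) ** 2))
    return RssReport(np.sqrt(beta_sq), np.sqrt(sig_sq), np.sqrt(eps_sq))
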