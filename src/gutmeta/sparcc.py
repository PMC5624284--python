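"""SparCC compositional correlation networks.

Correlations between taxa are inferred from log-ratio variances
t_ij = Var(log x_i/x_j) under the sparse-correlation approximation: basis
variances omega solve the linear system [(D-2)I + J] omega = row-sums(t), and
rho_ij = (omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j)). Fractions are
Dirichlet-resampled from the counts (unit pseudocount posterior), the
strongest pair above an exclusion threshold is iteratively removed from the
system, and the final matrix averages a configurable number of resampling
iterations. Significance comes from per-taxon permutation nulls.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._utils import substream
from .tables import COUNTS, AbundanceTable, ValidationError

logger = logging.getLogger("gutmeta.sparcc")

EXCLUSION_THRESHOLD = 0.25  # pair-exclusion correlation strength
EDGE_THRESHOLD = 0.3        # display/edge magnitude cut
P_THRESHOLD = 0.01
STRONG_THRESHOLD = 0.5
OMEGA_FLOOR = 1e-8


@dataclass
class SparccResult:
    taxon_ids: list
    rho: np.ndarray
    omega: np.ndarray
    n_iterations: int
    exclusion_threshold: float


@dataclass
class NetworkDiff:
    edges_lost: set
    edges_gained: set
    edges_shared: set
    strong_lost: set
    strong_gained: set


def _log_ratio_variances(log_f: np.ndarray) -> np.ndarray:
    """t_ij = Var(log f_i - log f_j) from the covariance of log fractions."""
    C = np.cov(log_f, rowvar=False)
    v = np.diag(C)
    return v[:, None] + v[None, :] - 2.0 * C


def _basis_solution(t: np.ndarray, excluded: set) -> np.ndarray:
    """Solve the sparse-approximation system for the basis variances, with
    excluded pairs removed from the equations (reference bookkeeping)."""
    D = t.shape[0]
    M = np.ones((D, D)) + (D - 2) * np.eye(D)
    t_eff = t.copy()
    for i, j in excluded:
        M[i, j] -= 1
        M[j, i] -= 1
        M[i, i] -= 1
        M[j, j] -= 1
        t_eff[i, j] = 0.0
        t_eff[j, i] = 0.0
    omega = np.linalg.solve(M, t_eff.sum(axis=1))
    if (omega <= 0).any():
        logger.warning("%d negative basis variance(s) clipped", int((omega <= 0).sum()))
        omega = np.maximum(omega, OMEGA_FLOOR)
    return omega


def _rho_from(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    if (np.abs(rho) > 1 + 1e-9).any():
        logger.debug("correlation magnitudes above 1 clipped")
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def _single_inference(log_f, exclusion_threshold, max_exclusion_rounds):
    t = _log_ratio_variances(log_f)
    excluded: set = set()
    omega = _basis_solution(t, excluded)
    rho = _rho_from(t, omega)
    D = t.shape[0]
    for _ in range(max_exclusion_rounds):
        work = np.abs(rho.copy())
        np.fill_diagonal(work, 0.0)
        for i, j in excluded:
            work[i, j] = work[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if work[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        omega = _basis_solution(t, excluded)
        rho = _rho_from(t, omega)
    return rho, omega


def sparcc_correlations(
    counts: AbundanceTable,
    n_iterations: int = 20,
    exclusion_threshold: float = EXCLUSION_THRESHOLD,
    max_exclusion_rounds: int = 10,
    seed: int = 0,
) -> SparccResult:
    """Average SparCC correlation matrix over Dirichlet-resampling iterations."""
    if counts.mode != COUNTS:
        raise ValidationError("sparcc_correlations requires a counts table")
    X = counts.values
    if X.shape[1] < 4:
        raise ValidationError("SparCC needs at least 4 taxa")
    rng = substream(seed, "sparcc-resampling")
    rho_sum = np.zeros((X.shape[1], X.shape[1]))
    omega_sum = np.zeros(X.shape[1])
    for _ in range(n_iterations):
        # posterior fractions with unit pseudocount, via the gamma trick
        g = rng.standard_gamma(X + 1.0)
        f = g / g.sum(axis=1, keepdims=True)
        rho, omega = _single_inference(
            np.log(f), exclusion_threshold, max_exclusion_rounds
        )
        rho_sum += rho
        omega_sum += omega
    rho = rho_sum / n_iterations
    np.fill_diagonal(rho, 1.0)
    return SparccResult(
        counts.feature_ids, rho, omega_sum / n_iterations, n_iterations, exclusion_threshold
    )


def sparcc_pvalues(
    counts: AbundanceTable,
    observed: SparccResult,
    n_null: int = 1000,
    seed: int = 0,
    null_iterations: int = 5,
    **sparcc_kwargs,
) -> np.ndarray:
    """Two-sided empirical p-values from per-taxon permutation nulls.

    Each null dataset permutes every taxon's counts independently across
    samples; p = (1 + #{|rho_null| >= |rho_obs|}) / (1 + n_null).
    """
    if n_null < 100:
        raise ValidationError("n_null must be at least 100")
    logger.info("null SparCC runs use %d resampling iterations", null_iterations)
    X = counts.values.astype(np.int64)
    rng = substream(seed, "sparcc-null")
    abs_obs = np.abs(observed.rho)
    exceed = np.zeros_like(abs_obs)
    for b in range(n_null):
        Xp = np.column_stack(
            [rng.permutation(X[:, j]) for j in range(X.shape[1])]
        )
        null_table = AbundanceTable(
            counts.data.copy().astype(np.int64), mode=COUNTS
        )
        null_table.data.iloc[:, :] = Xp
        res = sparcc_correlations(
            null_table,
            n_iterations=null_iterations,
            seed=int(rng.integers(2**31)),
            **sparcc_kwargs,
        )
        exceed += np.abs(res.rho) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_null)
    np.fill_diagonal(p, 1.0)
    return p


def build_network(
    result: SparccResult,
    p: np.ndarray,
    edge_threshold: float = EDGE_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    node_attrs: dict | None = None,
) -> nx.Graph:
    """Thresholded correlation network: keep i-j iff p < p_threshold and
    |rho| >= edge_threshold. Positive rho is co-occurrence, negative
    co-exclusion (edge attribute ``sign``)."""
    ids = result.taxon_ids
    G = nx.Graph()
    for idx, taxon in enumerate(ids):
        attrs = (node_attrs or {}).get(taxon, {})
        G.add_node(taxon, **attrs)
    D = len(ids)
    for i in range(D):
        for j in range(i + 1, D):
            rho = result.rho[i, j]
            if p[i, j] < p_threshold and abs(rho) >= edge_threshold:
                G.add_edge(
                    ids[i], ids[j], rho=float(rho), p=float(p[i, j]),
                    sign=1 if rho > 0 else -1,
                )
    return G


def compare_networks(net_a: nx.Graph, net_b: nx.Graph, strong_threshold: float = STRONG_THRESHOLD) -> NetworkDiff:
    """Edge census between two networks on their shared node universe."""
    shared_nodes = set(net_a.nodes) & set(net_b.nodes)
    if not shared_nodes:
        raise ValidationError("networks share no nodes")

    def edges(net):
        return {
            frozenset(e)
            for e in net.edges
            if e[0] in shared_nodes and e[1] in shared_nodes
        }

    ea, eb = edges(net_a), edges(net_b)
    lost = ea - eb
    gained = eb - ea
    shared = ea & eb

    def strong(net, edge_set):
        out = set()
        for e in edge_set:
            u, v = tuple(e)
            if abs(net.edges[u, v]["rho"]) > strong_threshold:
                out.add(e)
        return out

    return NetworkDiff(
        edges_lost=lost,
        edges_gained=gained,
        edges_shared=shared,
        strong_lost=strong(net_a, lost),
        strong_gained=strong(net_b, gained),
    )
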