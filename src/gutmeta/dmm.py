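"""Dirichlet-multinomial mixture (DMM) metacommunity typing.

Samples are modelled as draws from a K-component mixture in which each
component is a multinomial compounded with its own Dirichlet(alpha_k). The EM
fit alternates posterior responsibilities (E-step) with responsibility-
weighted fixed-point updates of each alpha_k (M-step). The number of
components is chosen by the Laplace-approximated negative log posterior,
evaluated at the EM optimum under a weak Normal(0, 10^2) prior on
theta = log alpha.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp, psi
from sklearn.cluster import KMeans

from ._utils import derived_seed
from .tables import COUNTS, AbundanceTable, ValidationError

logger = logging.getLogger("gutmeta.dmm")

PRIOR_SD = 10.0  # sd of the Normal prior on theta = log alpha
_ALPHA_FLOOR = 1e-10


@dataclass
class DMMModel:
    K: int
    pi: np.ndarray
    alpha: np.ndarray  # K x D
    responsibilities: np.ndarray  # N x K
    nll: float
    laplace_nlp: float
    converged: bool
    n_restarts_used: int
    n_iter: int
    sample_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)

    def component_proportions(self) -> np.ndarray:
        """Mean composition of each component (alpha_k normalized)."""
        return self.alpha / self.alpha.sum(axis=1, keepdims=True)


@dataclass
class ModelSelection:
    candidate_ks: list
    laplace_nlp: dict
    models: dict
    best_k: int


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------
def _log_multinomial_coef(X: np.ndarray) -> np.ndarray:
    n = X.sum(axis=1)
    return gammaln(n + 1.0) - gammaln(X + 1.0).sum(axis=1)


def _dm_logpmf(X: np.ndarray, alpha: np.ndarray, log_coef: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log pmf of each sample (row of X) under one alpha."""
    A = alpha.sum()
    n = X.sum(axis=1)
    return (
        log_coef
        + gammaln(A)
        - gammaln(n + A)
        + (gammaln(X + alpha[None, :]) - gammaln(alpha[None, :])).sum(axis=1)
    )


def _mixture_log_matrix(X, pi, alpha, log_coef):
    """N x K matrix of log(pi_k) + log DM(x_i | alpha_k)."""
    K = alpha.shape[0]
    out = np.empty((X.shape[0], K))
    for k in range(K):
        out[:, k] = np.log(pi[k] + 1e-300) + _dm_logpmf(X, alpha[k], log_coef)
    return out


def mixture_nll(X, pi, alpha):
    log_coef = _log_multinomial_coef(X)
    return -logsumexp(_mixture_log_matrix(X, pi, alpha, log_coef), axis=1).sum()


def _weighted_dirichlet_fit(X, n, weights, alpha0, tol=1e-8, max_inner=200):
    """Minka-style fixed point for the weighted Dirichlet-multinomial MLE."""
    alpha = np.maximum(alpha0, _ALPHA_FLOOR)
    wsum = weights.sum()
    if wsum <= 0:
        return alpha
    for _ in range(max_inner):
        A = alpha.sum()
        num = weights @ (psi(X + alpha[None, :]) - psi(alpha[None, :]))
        den = weights @ (psi(n + A) - psi(A))
        if den <= 0:
            break
        new = np.maximum(alpha * num / den, _ALPHA_FLOOR)
        delta = np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-12))
        alpha = new
        if delta < tol:
            break
    return alpha


def _moment_alpha(X, n, weights):
    """Moment-matched Dirichlet init: alpha = A_hat * weighted mean proportions."""
    w = weights / max(weights.sum(), 1e-12)
    props = X / n[:, None]
    m = w @ props
    m = np.maximum(m, 1e-12)
    v = w @ (props - m[None, :]) ** 2
    n_h = 1.0 / max((w / np.maximum(n, 1.0)).sum(), 1e-300)  # weighted harmonic depth
    denom = np.maximum(m * (1 - m), 1e-12)
    excess = np.median(v / denom) - 1.0 / n_h
    if excess <= 1e-12:
        A = 10.0 * n_h
    else:
        A = max(1.0 / excess - 1.0, 1.0)
    A = float(np.clip(A, 1.0, 1e8))
    return np.maximum(A * m, _ALPHA_FLOOR)


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------
def _fit_once(X, K, seed, tol, max_iter, inner_tol, max_inner):
    N, D = X.shape
    n = X.sum(axis=1)
    log_coef = _log_multinomial_coef(X)
    # partial M-steps keep each EM iteration cheap (generalized EM: every
    # fixed-point step is monotone); the full inner budget is spent once at
    # the end as a polish.
    em_inner = min(max_inner, 25)

    # k-means on proportions, one-hot responsibilities
    if K == 1:
        resp = np.ones((N, 1))
    else:
        props = X / n[:, None]
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(props)
        resp = np.zeros((N, K))
        resp[np.arange(N), km.labels_] = 1.0

    pi = resp.mean(axis=0)
    alpha = np.vstack(
        [
            _weighted_dirichlet_fit(
                X, n, resp[:, k], _moment_alpha(X, n, resp[:, k]), inner_tol, max_inner
            )
            for k in range(K)
        ]
    )

    prev_nll = np.inf
    converged = False
    reinit_done = np.zeros(K, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        log_mat = _mixture_log_matrix(X, pi, alpha, log_coef)
        log_norm = logsumexp(log_mat, axis=1)
        nll = -log_norm.sum()
        # monotone EM up to float64 accumulation noise (relative 1e-8)
        if nll > prev_nll + 1e-8 * max(1.0, abs(prev_nll)):
            logger.warning("EM step increased the nll by %.3g; stopping", nll - prev_nll)
            break
        if abs(prev_nll - nll) < tol * max(1.0, abs(nll)):
            converged = True
            prev_nll = nll
            resp = np.exp(log_mat - log_norm[:, None])
            break
        prev_nll = nll
        resp = np.exp(log_mat - log_norm[:, None])

        # empty-component rule: reinitialize once from the worst-fit samples
        weights = resp.sum(axis=0)
        for k in range(K):
            if weights[k] < 0.1 and not reinit_done[k]:  # pi_k < 1/(10 n)
                reinit_done[k] = True
                worst = np.argsort(log_norm)[: max(2, N // 10)]
                mask = np.zeros(N)
                mask[worst] = 1.0
                alpha[k] = _weighted_dirichlet_fit(
                    X, n, mask, _moment_alpha(X, n, mask), inner_tol, max_inner
                )
                resp[:, k] = np.maximum(resp[:, k], 1e-6)
                resp /= resp.sum(axis=1, keepdims=True)
                logger.warning("reinitialized empty component %d", k)

        pi = resp.mean(axis=0)
        for k in range(K):
            alpha[k] = _weighted_dirichlet_fit(
                X, n, resp[:, k], alpha[k], inner_tol, em_inner
            )
    # final polish with the full inner budget
    for k in range(K):
        alpha[k] = _weighted_dirichlet_fit(X, n, resp[:, k], alpha[k], inner_tol, max_inner)
    log_mat = _mixture_log_matrix(X, pi, alpha, log_coef)
    log_norm = logsumexp(log_mat, axis=1)
    polished_nll = -log_norm.sum()
    if polished_nll <= prev_nll + 1e-8 * max(1.0, abs(prev_nll)):
        prev_nll = min(prev_nll, polished_nll)
        resp = np.exp(log_mat - log_norm[:, None])
    if not converged:  # re-sync nll/responsibilities with the final parameters
        log_mat = _mixture_log_matrix(X, pi, alpha, log_coef)
        log_norm = logsumexp(log_mat, axis=1)
        final_nll = -log_norm.sum()
        if final_nll <= prev_nll:
            prev_nll = final_nll
            resp = np.exp(log_mat - log_norm[:, None])
    return pi, alpha, resp, prev_nll, converged, it


def fit_dmm(
    counts: AbundanceTable,
    k: int,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    inner_tol: float = 1e-8,
    max_inner: int = 200,
    compute_laplace: bool = True,
) -> DMMModel:
    """Fit a K-component Dirichlet-multinomial mixture to a counts table."""
    if counts.mode != COUNTS:
        raise ValidationError("fit_dmm requires a counts-mode table")
    X = counts.values
    if not np.allclose(X, np.round(X)):
        raise ValidationError("fit_dmm requires integer counts")
    if (X.sum(axis=1) <= 0).any():
        raise ValidationError("every sample must have a positive total count")
    if k < 1 or k > counts.n_samples:
        raise ValidationError(f"K={k} outside [1, n_samples={counts.n_samples}]")

    best = None
    for r in range(n_restarts):
        res = _fit_once(
            X, k, derived_seed(seed, f"dmm-restart-{r}"), tol, max_iter, inner_tol, max_inner
        )
        if best is None or res[3] < best[3]:
            best = res
    pi, alpha, resp, nll, converged, n_iter = best
    laplace = laplace_nlp(X, pi, alpha) if compute_laplace else np.nan
    return DMMModel(
        K=k,
        pi=pi,
        alpha=alpha,
        responsibilities=resp,
        nll=float(nll),
        laplace_nlp=float(laplace),
        converged=converged,
        n_restarts_used=n_restarts,
        n_iter=n_iter,
        sample_ids=counts.sample_ids,
        feature_ids=counts.feature_ids,
    )


# ---------------------------------------------------------------------------
# Laplace-approximated negative log posterior
# ---------------------------------------------------------------------------
def _neg_log_post_grad(X, n, log_coef, pi, theta):
    """Gradient of -log p(X|theta) - log p(theta) w.r.t. theta = log alpha."""
    K, D = theta.shape
    alpha = np.exp(theta)
    log_mat = _mixture_log_matrix(X, pi, alpha, log_coef)
    log_norm = logsumexp(log_mat, axis=1)
    resp = np.exp(log_mat - log_norm[:, None])
    grad = np.empty_like(theta)
    for k in range(K):
        a = alpha[k]
        A = a.sum()
        common = psi(A) - psi(n + A)  # per-sample
        dl_dalpha = resp[:, k] @ (psi(X + a[None, :]) - psi(a[None, :]))
        dl_dalpha += resp[:, k] @ common * np.ones(D)
        grad[k] = -(dl_dalpha * a) + theta[k] / PRIOR_SD**2
    return grad.ravel(), -log_norm.sum()


def laplace_nlp(X, pi, alpha, fd_step: float = 1e-4):
    """Laplace approximation to the negative log posterior at the EM optimum.

    nlp = -log p(X|theta) - log p(theta) + 1/2 log|H| - (P/2) log 2pi, with H
    the finite-difference Hessian (of the negative log posterior) in theta.
    Falls back to the diagonal of H when the full matrix is not positive
    definite.
    """
    X = np.asarray(X, dtype=float)
    n = X.sum(axis=1)
    log_coef = _log_multinomial_coef(X)
    theta = np.log(np.maximum(alpha, _ALPHA_FLOOR))
    K, D = theta.shape
    P = K * D

    g0, nll = _neg_log_post_grad(X, n, log_coef, pi, theta)
    H = np.empty((P, P))
    flat = theta.ravel().copy()
    for p in range(P):
        h = fd_step * max(1.0, abs(flat[p]))
        tp = flat.copy()
        tp[p] += h
        gp, _ = _neg_log_post_grad(X, n, log_coef, pi, tp.reshape(K, D))
        tm = flat.copy()
        tm[p] -= h
        gm, _ = _neg_log_post_grad(X, n, log_coef, pi, tm.reshape(K, D))
        H[:, p] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)

    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        logger.warning("Hessian not positive definite; using its diagonal")
        diag = np.maximum(np.diag(H), 1e-12)
        logdet = float(np.log(diag).sum())

    log_prior = -0.5 * (flat**2).sum() / PRIOR_SD**2 - P * np.log(
        PRIOR_SD * np.sqrt(2 * np.pi)
    )
    return nll - log_prior + 0.5 * logdet - 0.5 * P * np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# model selection and assignment
# ---------------------------------------------------------------------------
def select_k(
    counts: AbundanceTable,
    k_min: int = 1,
    k_max: int = 7,
    n_restarts: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> ModelSelection:
    """Fit every K in [k_min, k_max]; pick the minimal Laplace negative log posterior."""
    if not (1 <= k_min <= k_max <= counts.n_samples):
        raise ValidationError("need 1 <= k_min <= k_max <= n_samples")
    models = {}
    curve = {}
    for k in range(k_min, k_max + 1):
        models[k] = fit_dmm(counts, k, n_restarts=n_restarts, seed=seed, **fit_kwargs)
        curve[k] = models[k].laplace_nlp
        logger.info("K=%d: nll=%.2f laplace_nlp=%.2f", k, models[k].nll, curve[k])
    best_k = min(curve, key=curve.get)
    return ModelSelection(list(curve), curve, models, best_k)


def assign_metacommunities(model: DMMModel, counts: AbundanceTable) -> np.ndarray:
    """Hard component labels (argmax responsibility) for the given samples."""
    if counts.feature_ids != model.feature_ids:
        raise ValidationError("feature ids do not match the fitted model")
    X = counts.values
    log_coef = _log_multinomial_coef(X)
    log_mat = _mixture_log_matrix(X, model.pi, model.alpha, log_coef)
    best = log_mat.max(axis=1, keepdims=True)
    ties = (np.isclose(log_mat, best)).sum(axis=1) > 1
    if ties.any():
        logger.warning(
            "%d sample(s) tie between components; assigned to the lowest index",
            int(ties.sum()),
        )
    return log_mat.argmax(axis=1)
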