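"""In-family comparison methods sharing the moderated-t density machinery.

*separate limma*: each study analysed on its own; equivalent to the
correlation-motif model with a single class (K = 1), and produces the same
per-study gene ranking as ranking by |t|.

*all concord*: a gene is either differential in every study or in none;
a two-configuration mixture whose single weight carries a Beta(2, 2) prior.
Its posterior is shared across studies for each gene, so it cannot report
study-specific patterns.

*full motif*: the saturated model with one class per binary configuration
(2^D classes) and Dirichlet(2, ..., 2) prior on the configuration weights.
Because the component densities are fixed, its incomplete-data objective is
concave in the weights and a single EM run finds the mode.  It is refused
for D > 12, where the configuration space is no longer tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .emfit import FitResult, MotifModel, PosteriorSummary, e_step, fit_motifs
from .moderated import log_densities
from .studydata import TStatMatrix

FULL_MOTIF_MAX_STUDIES = 12


@dataclass
class ConfigMixtureModel:
    """A mixture over an explicit list of binary differential configurations."""

    configs: np.ndarray       # (C, D) binary
    weights: np.ndarray       # (C,) probabilities

    def __post_init__(self) -> None:
        self.configs = np.asarray(self.configs, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.configs.ndim != 2:
            raise ValueError("configs must be a C x D binary matrix")
        if len(np.unique(self.configs, axis=0)) != len(self.configs):
            raise ValueError("configurations must be distinct")
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("weights must be a probability vector")


@dataclass
class ConfigFitResult:
    model: ConfigMixtureModel
    config_post: np.ndarray   # (G, C) posterior over configurations
    diff_post: np.ndarray     # (G, D) per-study differential posterior
    log_likelihood: float
    log_posterior: float
    n_iter: int
    converged: bool


def _config_logliks(matrix: TStatMatrix, configs: np.ndarray) -> np.ndarray:
    """(G, C) log-likelihood of each gene's t row under each configuration."""
    logf0, logf1 = log_densities(matrix)
    c = configs.astype(float)
    return logf1 @ c.T + logf0 @ (1.0 - c).T


def _weights_em(
    loglik: np.ndarray,
    prior_alpha: float = 2.0,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """MAP-EM over mixture weights with fixed component densities and a
    symmetric Dirichlet(alpha) prior; returns (weights, posterior, loglik,
    n_iter, converged)."""
    g, c = loglik.shape
    w = np.full(c, 1.0 / c)
    lp_prev = -np.inf
    converged = False
    it = 0
    post = np.full((g, c), 1.0 / c)
    ll = 0.0
    for it in range(1, max_iter + 1):
        logw = loglik + np.log(w)
        lse = logsumexp(logw, axis=1, keepdims=True)
        ll = float(lse.sum())
        lp = ll + (prior_alpha - 1.0) * float(np.log(w).sum())
        post = np.exp(logw - lse)
        if lp - lp_prev <= tol * (abs(lp_prev) + 1e-3) and it > 1:
            converged = True
            break
        lp_prev = lp
        w = (post.sum(axis=0) + (prior_alpha - 1.0)) / (g + c * (prior_alpha - 1.0))
        w = np.maximum(w, 1e-300)
        w = w / w.sum()
    return w, post, ll, it, converged


def fit_separate_limma(
    matrix: TStatMatrix, seed: int = 0, **em_kwargs
) -> tuple[FitResult, PosteriorSummary]:
    """Per-study analysis: the K = 1 correlation-motif model.

    With one class the joint model factorises over studies, so each study's
    posterior depends only on its own t-statistics.
    """
    fit = fit_motifs(matrix, 1, seed=seed, **em_kwargs)
    return fit, e_step(matrix, fit.model)


@dataclass
class ConcordFitResult:
    p1: float                 # weight of the all-differential configuration
    posterior: np.ndarray     # (G,) posterior of all-differential
    diff_post: np.ndarray     # (G, D): posterior broadcast across studies
    log_likelihood: float
    log_posterior: float
    n_iter: int
    converged: bool


def fit_all_concord(
    matrix: TStatMatrix, tol: float = 1e-10, max_iter: int = 5000
) -> ConcordFitResult:
    """Concordance model: configurations restricted to all-ones/all-zeros."""
    d = matrix.n_studies
    configs = np.vstack([np.ones(d, dtype=int), np.zeros(d, dtype=int)])
    loglik = _config_logliks(matrix, configs)
    w, post, ll, it, converged = _weights_em(loglik, tol=tol, max_iter=max_iter)
    p1 = float(w[0])
    lp = ll + float(np.log(p1) + np.log1p(-p1))
    return ConcordFitResult(
        p1=p1,
        posterior=post[:, 0],
        diff_post=np.repeat(post[:, [0]], d, axis=1),
        log_likelihood=ll,
        log_posterior=lp,
        n_iter=it,
        converged=converged,
    )


def all_configs(n_studies: int) -> np.ndarray:
    """All 2^D binary configurations, in binary counting order."""
    c = 1 << n_studies
    out = ((np.arange(c)[:, None] >> np.arange(n_studies - 1, -1, -1)) & 1)
    return out.astype(int)


def fit_full_motif(
    matrix: TStatMatrix, tol: float = 1e-10, max_iter: int = 5000
) -> ConfigFitResult:
    """Saturated configuration mixture over all 2^D patterns."""
    d = matrix.n_studies
    if d > FULL_MOTIF_MAX_STUDIES:
        raise ValueError(
            f"full motif infeasible for D = {d} (2^D configuration classes); "
            "use the correlation-motif model"
        )
    configs = all_configs(d)
    loglik = _config_logliks(matrix, configs)
    w, post, ll, it, converged = _weights_em(loglik, tol=tol, max_iter=max_iter)
    lp = ll + float(np.log(w).sum())
    return ConfigFitResult(
        model=ConfigMixtureModel(configs=configs, weights=w),
        config_post=post,
        diff_post=post @ configs.astype(float),
        log_likelihood=ll,
        log_posterior=lp,
        n_iter=it,
        converged=converged,
    )
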