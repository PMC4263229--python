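"""Correlation-motif mixture model and MAP-EM inference.

Genes fall into K latent classes with prior weights pi.  Class k carries a
*correlation motif*: a probability vector q_k of length D whose entry q_kd
is the probability that a gene of class k is differentially expressed in
study d.  Given the class label, the per-study differential states a_gd
are independent Bernoulli(q_kd), and the moderated t-statistic t_gd is
drawn from the alternative density f_d1 when a_gd = 1 and the null density
f_d0 otherwise.  Marginally over classes, the states of one gene across
studies become dependent, which is how the model encodes the cross-study
correlation of differential expression with only O(KD) parameters.

Inference targets the posterior mode of (pi, Q) under a Dir(2, ..., 2)
prior on pi and independent Beta(2, 2) priors on the q_kd, via an EM
ascent on the log posterior.  The MAP M-step updates are the usual
responsibility-weighted counts with the +1 / +2 posterior-mode pseudocount
increments implied by those priors:

    pi_k  = (sum_g r_gk + 1) / (G + K)
    q_kd  = (sum_g r_gk * rho_gkd + 1) / (sum_g r_gk + 2)

where r_gk is the class responsibility and rho_gkd the within-class
posterior probability of a_gd = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .moderated import log_densities
from .studydata import TStatMatrix

Q_EPS = 1e-10        # motif entries clamped to [Q_EPS, 1 - Q_EPS]
PI_FLOOR = 1e-12
EMPTY_CLASS_TOL = 1e-6
_EXP_CLIP = 700.0    # exp argument clip; density ratios stay finite


@dataclass
class MotifModel:
    """Mixing proportions pi (K,) and motif matrix q (K, D)."""

    pi: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.pi.shape != (self.q.shape[0],):
            raise ValueError("pi must be a K-vector matching q's K x D shape")
        if abs(self.pi.sum() - 1.0) > 1e-12 or np.any(self.pi <= 0):
            raise ValueError("pi must be strictly positive and sum to 1")
        if np.any(self.q <= 0.0) or np.any(self.q >= 1.0):
            raise ValueError("q entries must lie strictly inside (0, 1)")

    @property
    def n_classes(self) -> int:
        return self.q.shape[0]

    @property
    def n_studies(self) -> int:
        return self.q.shape[1]


@dataclass
class PosteriorSummary:
    """Posterior quantities at fixed (pi, Q).

    ``class_post[g, k]``        = Pr(b_g = k | T)
    ``within_class_diff[g,k,d]``= Pr(a_gd = 1 | T, b_g = k)
    ``diff_post[g, d]``         = Pr(a_gd = 1 | T), the study-specific
                                  differential posterior used for ranking.
    """

    class_post: np.ndarray
    within_class_diff: np.ndarray
    diff_post: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.diff_post = np.einsum(
            "gk,gkd->gd", self.class_post, self.within_class_diff
        )


@dataclass
class FitResult:
    model: MotifModel
    log_posterior: float
    log_likelihood: float
    n_iter: int
    converged: bool
    trace: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# likelihood machinery


def _ratio_exp(logf0: np.ndarray, logf1: np.ndarray) -> np.ndarray:
    """exp(log f1 - log f0); bounded because both densities are Student t."""
    return np.exp(np.clip(logf1 - logf0, -_EXP_CLIP, _EXP_CLIP))


def _class_logliks(
    logf0: np.ndarray, ratio: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene, per-class log-likelihoods with a_g summed out.

    Returns (L, P) where L[g, k] = sum_d log(q_kd f1 + (1-q_kd) f0) and
    P[g, k, d] = q_kd * ratio + (1 - q_kd), the per-study mixture factor
    divided by f0 (reused for the within-class posteriors).
    """
    p = ratio[:, np.newaxis, :] * q[np.newaxis, :, :] + (1.0 - q)[np.newaxis, :, :]
    loglik = np.log(p).sum(axis=2) + logf0.sum(axis=1)[:, np.newaxis]
    return loglik, p


def gene_class_loglik(
    t_row: np.ndarray, q_row: np.ndarray, df: np.ndarray, scale_alt: np.ndarray
) -> float:
    """sum_d log[q_d f_d1(t_d) + (1 - q_d) f_d0(t_d)] for a single gene and
    a single motif."""
    m = TStatMatrix(
        t=np.asarray(t_row, dtype=float)[np.newaxis, :],
        df=np.asarray(df, dtype=float),
        scale_alt=np.asarray(scale_alt, dtype=float),
        gene_ids=["g"],
        study_ids=[f"s{i}" for i in range(len(t_row))],
    )
    logf0, logf1 = log_densities(m)
    loglik, _ = _class_logliks(
        logf0, _ratio_exp(logf0, logf1), np.asarray(q_row)[np.newaxis, :]
    )
    return float(loglik[0, 0])


def _prior_logdensity(model: MotifModel) -> float:
    # Dir(2,...,2) x Beta(2,2) log density, constant of proportionality 0
    return float(
        np.log(model.pi).sum() + (np.log(model.q) + np.log1p(-model.q)).sum()
    )


def log_likelihood(matrix: TStatMatrix, model: MotifModel) -> float:
    """Observed-data log f(T | pi, Q), with both A and B summed out."""
    logf0, logf1 = log_densities(matrix)
    loglik, _ = _class_logliks(logf0, _ratio_exp(logf0, logf1), model.q)
    return float(logsumexp(loglik + np.log(model.pi), axis=1).sum())


def log_posterior(matrix: TStatMatrix, model: MotifModel) -> float:
    """MAP objective: log likelihood plus the Dirichlet/Beta prior terms."""
    return log_likelihood(matrix, model) + _prior_logdensity(model)


def e_step(matrix: TStatMatrix, model: MotifModel) -> PosteriorSummary:
    """Class responsibilities and within-class differential posteriors."""
    logf0, logf1 = log_densities(matrix)
    ratio = _ratio_exp(logf0, logf1)
    loglik, p = _class_logliks(logf0, ratio, model.q)
    logw = loglik + np.log(model.pi)
    class_post = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    within = ratio[:, np.newaxis, :] * model.q[np.newaxis, :, :] / p
    return PosteriorSummary(class_post=class_post, within_class_diff=within)


def m_step(posterior: PosteriorSummary) -> MotifModel:
    """MAP parameter update from posterior summaries."""
    r = posterior.class_post
    g, k = r.shape
    if g == 0:
        d = posterior.within_class_diff.shape[2]
        return MotifModel(pi=np.full(k, 1.0 / k), q=np.full((k, d), 0.5))
    n_k = r.sum(axis=0)
    num = np.einsum("gk,gkd->kd", r, posterior.within_class_diff)
    pi = (n_k + 1.0) / (g + k)
    q = (num + 1.0) / (n_k[:, np.newaxis] + 2.0)
    return _clamped_model(pi, q)


def _clamped_model(pi: np.ndarray, q: np.ndarray) -> MotifModel:
    pi = np.maximum(pi, PI_FLOOR)
    pi = pi / pi.sum()
    q = np.clip(q, Q_EPS, 1.0 - Q_EPS)
    return MotifModel(pi=pi, q=q)


# ---------------------------------------------------------------------------
# EM driver


def _init_model(k: int, d: int, rng: np.random.Generator) -> MotifModel:
    pi = rng.dirichlet(np.ones(k))
    q = rng.uniform(0.05, 0.95, size=(k, d))
    return _clamped_model(pi, q)


def _em_chain(
    logf0: np.ndarray,
    ratio: np.ndarray,
    model: MotifModel,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    trace: list[float],
) -> tuple[MotifModel, bool, int]:
    """Run MAP-EM from ``model``; appends the objective to ``trace``."""
    g = logf0.shape[0]
    k = model.n_classes
    lp_prev = -np.inf
    converged = False
    reinit_used = False
    it = 0
    pi, q = model.pi, model.q
    for it in range(1, max_iter + 1):
        loglik, p = _class_logliks(logf0, ratio, q)
        logw = loglik + np.log(pi)
        lse = logsumexp(logw, axis=1, keepdims=True)
        lp = float(lse.sum()) + float(
            np.log(pi).sum() + (np.log(q) + np.log1p(-q)).sum()
        )
        trace.append(lp)
        if lp - lp_prev <= tol * (abs(lp_prev) + 1e-3) and it > 1:
            converged = True
            break
        lp_prev = lp
        r = np.exp(logw - lse)
        n_k = r.sum(axis=0)
        if not reinit_used and np.any(n_k < EMPTY_CLASS_TOL):
            # one-shot rescue of empty classes with fresh random motifs;
            # the trace restarts because this is effectively a new start
            empty = n_k < EMPTY_CLASS_TOL
            q = q.copy()
            q[empty] = rng.uniform(0.05, 0.95, size=(int(empty.sum()), q.shape[1]))
            pi = np.where(empty, 1.0 / k, pi)
            pi = pi / pi.sum()
            reinit_used = True
            lp_prev = -np.inf
            trace.clear()
            continue
        num = np.einsum(
            "gk,gkd->kd", r, ratio[:, np.newaxis, :] * q[np.newaxis, :, :] / p
        )
        pi = (n_k + 1.0) / (g + k)
        q = np.clip((num + 1.0) / (n_k[:, np.newaxis] + 2.0), Q_EPS, 1.0 - Q_EPS)
        pi = np.maximum(pi, PI_FLOOR)
        pi = pi / pi.sum()
    return _clamped_model(pi, q), converged, it


def _sort_motifs(model: MotifModel) -> MotifModel:
    """Canonical reporting order: descending pi, ties by lexicographic Q row."""
    keys = [model.q[:, d] for d in range(model.q.shape[1] - 1, -1, -1)]
    order = np.lexsort(keys + [-model.pi])
    return MotifModel(pi=model.pi[order], q=model.q[order])


def fit_motifs(
    matrix: TStatMatrix,
    k: int,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    short_run_iter: int | None = 100,
) -> FitResult:
    """Fit a K-motif model by multi-start MAP-EM.

    Every chain c draws its initial model from a generator seeded with
    ``seed + c``.  When ``short_run_iter`` is set (the default) all chains
    first run for that many iterations, and only the chain with the
    highest objective is continued to convergence; with ``None`` every
    chain runs to convergence and the best final objective wins.
    """
    g, d = matrix.t.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > g:
        raise ValueError(f"k = {k} exceeds the number of genes ({g})")
    logf0, logf1 = log_densities(matrix)
    ratio = _ratio_exp(logf0, logf1)

    chains = []
    for c in range(n_starts):
        rng = np.random.default_rng(seed + c)
        model = _init_model(k, d, rng)
        trace: list[float] = []
        burn = max_iter if short_run_iter is None else min(short_run_iter, max_iter)
        model, converged, n_it = _em_chain(
            logf0, ratio, model, rng, tol, burn, trace
        )
        chains.append([model, converged, n_it, trace, rng])

    best = int(np.argmax([c[3][-1] for c in chains]))
    model, converged, n_it, trace, rng = chains[best]
    if short_run_iter is not None and not converged:
        model, converged, n_more = _em_chain(
            logf0, ratio, model, rng, tol, max_iter - n_it, trace
        )
        n_it += n_more

    model = _sort_motifs(model)
    loglik, _ = _class_logliks(logf0, ratio, model.q)
    ll = float(logsumexp(loglik + np.log(model.pi), axis=1).sum())
    return FitResult(
        model=model,
        log_posterior=ll + _prior_logdensity(model),
        log_likelihood=ll,
        n_iter=n_it,
        converged=converged,
        trace=np.asarray(trace),
        seed=seed,
    )
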