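"""Per-study empirical-Bayes moderated t-statistics and their densities.

Each study compares case vs. control replicates.  Per gene g the observed
summaries are the mean difference y_g and the pooled sample variance s_g^2
on n - 2 residual degrees of freedom.  The hierarchical model shrinks the
gene variances toward a prior value:

    y_g | mu_g, sigma_g^2   ~  N(mu_g, v sigma_g^2),   v = 1/n1 + 1/n2
    mu_g = 0                       when the gene is non-differential
    mu_g | sigma_g^2        ~  N(0, w sigma_g^2)       when differential
    s_g^2 | sigma_g^2       ~  sigma_g^2 chi2_{n-2} / (n-2)
    1 / sigma_g^2           ~  chi2_{n0} / (n0 s0^2)

With posterior variance  s~_g^2 = (n0 s0^2 + (n-2) s_g^2) / (n0 + n - 2)
the moderated statistic  t_g = y_g / sqrt(v s~_g^2)  follows a Student t
with df = n0 + n - 2 under the null, and a scaled Student t with scale
c = sqrt(1 + w/v) under the alternative.  Those two densities are the sole
interface between the raw data and every mixture model downstream.

Hyperparameters n0 and s0^2 are estimated by moment matching on log s^2
(Smyth's procedure); the alternative-effect variance ratio w is estimated
by a one-dimensional two-component scale-mixture EM on the t-statistics,
or supplied directly when known (e.g. in simulation studies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .studydata import MultiStudySet, StudyDataset, TStatMatrix

#: df above this value is treated as effectively infinite (normal regime)
MAX_DF = 1e6

#: floor applied to pooled variances before taking logs
VAR_FLOOR = 1e-12


@dataclass
class PooledStats:
    """Per-gene two-group summaries for one study."""

    y: np.ndarray          # mean difference, case minus control
    s2: np.ndarray         # pooled sample variance on df_resid
    v: float               # 1/n_case + 1/n_control
    df_resid: float        # n - 2

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if np.any(self.s2 < 0):
            raise ValueError("pooled variances must be non-negative")
        if self.v <= 0 or self.df_resid < 2:
            raise ValueError("invalid v or residual df")


@dataclass
class ModerationParams:
    """Empirical-Bayes hyperparameters for one study."""

    n0: float              # prior df, may be inf
    s0_sq: float           # prior variance
    w: float               # alternative-effect variance ratio, >= 0
    v: float
    df_resid: float

    def __post_init__(self) -> None:
        # n0 = 0 is the no-shrinkage limit (ordinary pooled t)
        if self.s0_sq <= 0 or self.n0 < 0:
            raise ValueError("prior variance must be positive, prior df >= 0")
        if self.w < 0:
            raise ValueError("w must be non-negative")

    @property
    def df_total(self) -> float:
        return self.n0 + self.df_resid

    @property
    def scale_alt(self) -> float:
        return float(np.sqrt(1.0 + self.w / self.v))


def pooled_stats(study: StudyDataset) -> PooledStats:
    """Mean differences and pooled variances for one study."""
    case = study.case_values
    ctrl = study.control_values
    n1, n2 = study.n_case, study.n_control
    y = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid
    if np.all(s2 == 0):
        raise ValueError(f"study {study.study_id!r}: all pooled variances are zero")
    return PooledStats(y=y, s2=s2, v=1.0 / n1 + 1.0 / n2, df_resid=float(df_resid))


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on x -> trigamma(x); monotone decreasing, convex.
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match the scaled-inverse-chi2 variance prior on log s^2.

    Returns (n0, s0_sq).  When the spread of log s^2 does not exceed the
    chi2 sampling noise the prior df is infinite and every shrunken
    variance equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("too few genes for stable hyperparameter estimation")
    z = np.log(np.maximum(s2, VAR_FLOOR))
    d2 = df_resid / 2.0
    e = z - special.digamma(d2) + np.log(d2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, d2))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    n0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(emean + special.digamma(n0 / 2.0) - np.log(n0 / 2.0)))
    return float(n0), s0_sq


def moderated_t(pstats: PooledStats, params: ModerationParams) -> np.ndarray:
    """Moderated t-statistics t_g = y_g / sqrt(v * s~_g^2)."""
    if np.isinf(params.n0):
        s2_post = np.full_like(pstats.s2, params.s0_sq)
    else:
        s2_post = (params.n0 * params.s0_sq + pstats.df_resid * pstats.s2) / (
            params.n0 + pstats.df_resid
        )
    return pstats.y / np.sqrt(params.v * s2_post)


# ---------------------------------------------------------------------------
# densities

def _capped(df: float | np.ndarray) -> np.ndarray:
    return np.minimum(df, MAX_DF)


def null_logdensity(t, df_total) -> np.ndarray:
    """log f0(t): Student t with the total (prior + residual) df."""
    return stats.t.logpdf(t, _capped(df_total))


def alt_logdensity(t, df_total, scale_alt) -> np.ndarray:
    """log f1(t): Student t scaled by c = sqrt(1 + w/v)."""
    c = np.asarray(scale_alt, dtype=float)
    return stats.t.logpdf(np.asarray(t) / c, _capped(df_total)) - np.log(c)


def log_densities(matrix: TStatMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(log f0, log f1) evaluated at every entry of a TStatMatrix, G x D."""
    logf0 = null_logdensity(matrix.t, matrix.df[np.newaxis, :])
    logf1 = alt_logdensity(
        matrix.t, matrix.df[np.newaxis, :], matrix.scale_alt[np.newaxis, :]
    )
    return logf0, logf1


# ---------------------------------------------------------------------------
# estimation of the alternative-effect variance ratio w

@dataclass
class WEstimate:
    w: float
    scale: float           # c = sqrt(1 + w/v)
    p0: float              # null mixture weight
    n_iter: int
    converged: bool


def estimate_w(
    t: np.ndarray,
    df_total: float,
    v: float,
    max_iter: int = 200,
    tol: float = 1e-7,
    max_scale: float = 100.0,
) -> WEstimate:
    """Estimate w from a study's t-statistics by a two-component
    scale-mixture EM:  t ~ p0 * t_df + (1 - p0) * c * t_df  with c >= 1.

    Returns w = (c^2 - 1) * v.  The M-step for c has no closed form and is
    solved by bounded one-dimensional optimisation of the weighted
    log-likelihood.
    """
    t = np.asarray(t, dtype=float)
    df = float(_capped(df_total))
    log_null = stats.t.logpdf(t, df)
    p0, c = 0.9, 2.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_alt = stats.t.logpdf(t / c, df) - np.log(c)
        a = np.log(p0) + log_null
        b = np.log1p(-p0) + log_alt
        m = np.maximum(a, b)
        denom = m + np.log(np.exp(a - m) + np.exp(b - m))
        r = np.exp(b - denom)          # responsibility of the scaled component
        p0_new = float(np.clip(1.0 - r.mean(), 1e-6, 1.0 - 1e-6))

        def neg_q(log_c: float) -> float:
            cc = np.exp(log_c)
            return -float(np.sum(r * (stats.t.logpdf(t / cc, df) - log_c)))

        res = optimize.minimize_scalar(
            neg_q, bounds=(0.0, np.log(max_scale)), method="bounded",
            options={"xatol": 1e-8},
        )
        c_new = float(np.exp(res.x))
        if abs(p0_new - p0) < tol and abs(c_new - c) < tol * max(1.0, c):
            p0, c = p0_new, c_new
            converged = True
            break
        p0, c = p0_new, c_new
    c = max(c, 1.0)
    return WEstimate(
        w=float((c * c - 1.0) * v), scale=c, p0=p0, n_iter=it, converged=converged
    )


# ---------------------------------------------------------------------------
# whole-dataset convenience

def moderate_study(
    study: StudyDataset, w: float | None = None
) -> tuple[np.ndarray, ModerationParams]:
    """Full per-study pipeline: pooled stats -> variance prior -> t -> w."""
    ps = pooled_stats(study)
    n0, s0_sq = fit_variance_prior(ps.s2, ps.df_resid)
    params = ModerationParams(n0=n0, s0_sq=s0_sq, w=0.0, v=ps.v, df_resid=ps.df_resid)
    t = moderated_t(ps, params)
    if w is None:
        w = estimate_w(t, params.df_total, ps.v).w
    params = ModerationParams(
        n0=n0, s0_sq=s0_sq, w=float(w), v=ps.v, df_resid=ps.df_resid
    )
    return t, params


def moderate(
    data: MultiStudySet, w: dict[str, float] | float | None = None
) -> TStatMatrix:
    """Compute the moderated t-statistic matrix for a multi-study set.

    ``w`` may be None (estimate per study), a scalar applied to every
    study, or a mapping study id -> value.
    """
    t_cols, dfs, scales = [], [], []
    for study in data.studies:
        if isinstance(w, dict):
            w_d = w.get(study.study_id)
        else:
            w_d = w
        t, params = moderate_study(study, w=w_d)
        t_cols.append(t)
        dfs.append(params.df_total)
        scales.append(params.scale_alt)
    return TStatMatrix(
        t=np.column_stack(t_cols),
        df=np.asarray(dfs),
        scale_alt=np.asarray(scales),
        gene_ids=data.gene_ids,
        study_ids=data.study_ids,
    )
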