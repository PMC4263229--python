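"""BIC-based selection of the motif number K.

BIC = -2 * log-likelihood + p * log(G) with p = (K - 1) + K * D free
parameters (mixing proportions plus motif entries) and the genes as the
independent sampling units.  The log-likelihood is the observed-data
likelihood, never the prior-inclusive MAP objective.  Smaller is better;
ties go to the smaller K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .emfit import FitResult, fit_motifs
from .studydata import TStatMatrix

logger = logging.getLogger(__name__)


def bic(fit: FitResult, n_genes: int) -> float:
    """Bayesian information criterion for a fitted motif model."""
    k = fit.model.n_classes
    d = fit.model.n_studies
    p = (k - 1) + k * d
    return -2.0 * fit.log_likelihood + p * np.log(n_genes)


@dataclass
class ModelScan:
    k_grid: list[int]
    fits: dict[int, FitResult]
    bic: dict[int, float]
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def best_k(self) -> int:
        if not self.bic:
            raise ValueError("no successful fits in scan")
        # min BIC; ties broken toward smaller K by the sort order
        return min(sorted(self.bic), key=lambda k: self.bic[k])

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best_k]


def default_k_grid(n_studies: int, k_max: int = 10) -> list[int]:
    return list(range(1, min(2 ** n_studies, k_max) + 1))


def scan_k(
    matrix: TStatMatrix,
    k_grid: list[int] | None = None,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    short_run_iter: int | None = 100,
) -> ModelScan:
    """Fit every K in the grid and score each fit by BIC.

    All fits share the same seed policy (chain c of any K uses seed + c),
    so a rerun with the same seed reproduces the scan exactly.  A failure
    at one K is recorded and does not abort the other fits.
    """
    if k_grid is None:
        k_grid = default_k_grid(matrix.n_studies)
    if not k_grid or any(k < 1 for k in k_grid):
        raise ValueError("k grid must be non-empty with every K >= 1")
    fits: dict[int, FitResult] = {}
    bics: dict[int, float] = {}
    failures: dict[int, str] = {}
    for k in k_grid:
        try:
            fit = fit_motifs(
                matrix, k, n_starts=n_starts, tol=tol, max_iter=max_iter,
                seed=seed, short_run_iter=short_run_iter,
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            logger.warning("fit failed for K=%d: %s", k, exc)
            failures[k] = str(exc)
            continue
        fits[k] = fit
        bics[k] = bic(fit, matrix.n_genes)
    return ModelScan(k_grid=list(k_grid), fits=fits, bic=bics, failures=failures)
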