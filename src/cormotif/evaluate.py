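"""Posterior-based ranking, differential calls and evaluation statistics.

Genes are ranked within each study by the posterior probability of
differential expression Pr(a_gd = 1 | T); binary calls use a posterior
cutoff (default 0.5, strict).  For simulated data with known truth the
module provides the TP_d(r) ranking curve (true positives among the top r
genes of study d) and a configuration confusion table: true pattern in the
columns, exactly-matched called configuration in the rows, with a final
"other" row collecting call vectors matching none of the true patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emfit import MotifModel


def rank_genes(
    diff_post: np.ndarray, study: int, t: np.ndarray | None = None
) -> np.ndarray:
    """Permutation of gene indices, best first, for one study.

    Descending posterior; ties broken by descending |t| (when supplied),
    then by gene index (stable).
    """
    post = np.asarray(diff_post)[:, study]
    g = post.shape[0]
    if t is not None:
        abst = np.abs(np.asarray(t)[:, study])
        keys = (np.arange(g), -abst, -post)
    else:
        keys = (np.arange(g), -post)
    return np.lexsort(keys)


def call_differential(diff_post: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Binary call matrix: 1 where the posterior strictly exceeds the cutoff."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly inside (0, 1)")
    return (np.asarray(diff_post) > cutoff).astype(int)


def tp_curve(
    ranking: np.ndarray, truth_col: np.ndarray, r_max: int | None = None
) -> np.ndarray:
    """TP(r) for r = 1..r_max: true positives among the top r ranked genes."""
    ranking = np.asarray(ranking)
    truth_col = np.asarray(truth_col).astype(bool)
    if ranking.shape[0] != truth_col.shape[0] or (
        np.sort(ranking) != np.arange(ranking.shape[0])
    ).any():
        raise ValueError("ranking must be a permutation of all gene indices")
    curve = np.cumsum(truth_col[ranking])
    return curve if r_max is None else curve[:r_max]


@dataclass
class ConfusionTable:
    """Cross-tabulation of true pattern (columns) vs. called configuration
    (rows); the last row, "other", collects non-matching call vectors."""

    patterns: list[tuple[int, ...]]
    counts: np.ndarray               # (P + 1, P)

    @property
    def row_labels(self) -> list[str]:
        return [str(list(p)) for p in self.patterns] + ["other"]

    def diagonal_total(self) -> int:
        return int(np.trace(self.counts[: len(self.patterns)]))

    def diagonal(self) -> np.ndarray:
        return np.diag(self.counts[: len(self.patterns)]).copy()


def confusion_table(
    calls: np.ndarray,
    truth_a: np.ndarray,
    patterns: list[tuple[int, ...]],
) -> ConfusionTable:
    """Match every gene's full call vector against the true pattern set."""
    calls = np.asarray(calls, dtype=int)
    truth_a = np.asarray(truth_a, dtype=int)
    if calls.shape != truth_a.shape:
        raise ValueError("calls and truth must have identical shape")
    patterns = [tuple(int(a) for a in p) for p in patterns]
    index = {p: i for i, p in enumerate(patterns)}
    n_p = len(patterns)
    counts = np.zeros((n_p + 1, n_p), dtype=int)
    for call_row, true_row in zip(calls, truth_a):
        col = index.get(tuple(true_row))
        if col is None:
            raise ValueError(f"true pattern {tuple(true_row)} not in pattern list")
        row = index.get(tuple(call_row), n_p)
        counts[row, col] += 1
    return ConfusionTable(patterns=patterns, counts=counts)


def joint_config_prob(model: MotifModel, config) -> float:
    """Marginal prior probability of one differential configuration:
    sum_k pi_k prod_d q_kd^a_d (1 - q_kd)^(1 - a_d)."""
    a = np.asarray(config, dtype=float)
    if a.shape != (model.n_studies,) or not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("config must be a binary D-vector")
    per_class = np.prod(model.q**a * (1.0 - model.q) ** (1.0 - a), axis=1)
    return float(np.dot(model.pi, per_class))
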