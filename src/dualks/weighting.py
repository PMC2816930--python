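"""Rank-based expression weights (the weighted scoring variant).

A gene can be strongly class-biased yet sit low in every sample's overall
expression ranking; such a gene contributes little when new samples are
scored gene-wise by enrichment.  The weighted variant therefore favours
genes that are also highly expressed in absolute terms within the class:
gene *i* gets weight ``w_il = -log(Rbar_il / G)`` where ``Rbar_il`` is the
rank (1 = largest) of its class-*l* mean expression among all ``G`` genes.
The weighted scores are ``u_hat = w * u`` and ``d_hat = (1 - w) * d``.

``1 - w_il`` is negative for top-ranked genes when ``G >= 3`` (``w_il =
log G > 1`` at rank 1); the formula is applied as stated, so highly
expressed genes are actively penalised as down-signature candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .core_scoring import ClassVector, ExpressionMatrix, ScoreTable
from .errors import DualKSError

__all__ = ["WeightTable", "class_mean_ranks", "weights", "weighted_scores", "LOG_BASES"]

LOG_BASES: dict[str, float] = {"e": np.e, "2": 2.0, "10": 10.0}


@dataclass
class WeightTable:
    """Per-gene, per-class weights ``w_il`` and the mean-expression ranks behind them."""

    weights: pd.DataFrame
    mean_ranks: pd.DataFrame
    log_base: str = field(default="e")

    def __post_init__(self) -> None:
        if not self.weights.index.equals(self.mean_ranks.index) or not self.weights.columns.equals(
            self.mean_ranks.columns
        ):
            raise DualKSError("weights and mean_ranks are not aligned")


def class_mean_ranks(X: ExpressionMatrix, Y: ClassVector) -> pd.DataFrame:
    """Rank each gene's class-mean expression within each class.

    Rank 1 is the largest mean.  Ties are broken by gene identifier
    ascending so every column is a permutation of ``1..G``.
    """
    if Y.n_samples != X.n_samples:
        raise DualKSError("label count does not match sample count")
    g = X.n_genes
    ranks = np.empty((g, Y.n_classes), dtype=int)
    for k, c in enumerate(Y.classes):
        means = X.values[:, Y.labels == c].mean(axis=1)
        order = np.lexsort((X.gene_ids, -means))
        col = np.empty(g, dtype=int)
        col[order] = np.arange(1, g + 1)
        ranks[:, k] = col
    return pd.DataFrame(ranks, index=pd.Index(X.gene_ids, name="gene"),
                        columns=pd.Index(Y.classes, name="class"))


def weights(ranks: pd.DataFrame, n_genes: int | None = None, log_base: str = "e") -> WeightTable:
    """Turn mean-expression ranks into weights ``w_il = -log(Rbar_il / G)``.

    The logarithm base (natural by default) rescales all weights by a
    common factor; rankings of the weighted up-scores are base-invariant,
    but the ``1 - w`` factor in the weighted down-scores is not, hence the
    option.
    """
    if log_base not in LOG_BASES:
        raise DualKSError(f"log_base must be one of {sorted(LOG_BASES)}, got {log_base!r}")
    g = int(n_genes) if n_genes is not None else int(ranks.shape[0])
    vals = ranks.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.array_equal(vals, vals.astype(int)):
            raise DualKSError("ranks must be integers")
        vals = vals.astype(int)
    if vals.min() < 1 or vals.max() > g:
        raise DualKSError(f"ranks must lie in 1..{g}")
    w = -np.log(vals / g) / log(LOG_BASES[log_base])
    return WeightTable(
        weights=pd.DataFrame(w, index=ranks.index, columns=ranks.columns),
        mean_ranks=ranks.astype(int),
        log_base=log_base,
    )


def weighted_scores(scores: ScoreTable, W: WeightTable) -> ScoreTable:
    """Apply weights elementwise: ``u_hat = w*u``, ``d_hat = (1-w)*d``."""
    if not scores.up.index.equals(W.weights.index) or not scores.up.columns.equals(W.weights.columns):
        raise DualKSError("score table and weight table are not aligned")
    return ScoreTable(up=W.weights * scores.up, down=(1.0 - W.weights) * scores.down, kind="weighted")
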