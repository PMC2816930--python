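"""Tissue-set enrichment scoring of genes against sample classes.

Classical gene set enrichment analysis orders the genes of one sample by
expression and asks whether a gene set clusters at an extreme of that list.
Here the roles are inverted: for a fixed gene the *samples* are ordered by
that gene's expression, and a Kolmogorov-Smirnov running sum measures how
strongly the samples of one class cluster at the top (up-regulation, ``u``)
or the bottom (down-regulation, ``d``) of the ordered list.

For gene *i*, class *l* and samples ordered by decreasing expression, the
running sum gains ``N/N_l`` at each class-*l* sample and loses
``N/(N - N_l)`` at every other sample; ``u_il`` is its maximum.  ``d_il`` is
the analogous maximum over the increasing order.  Both statistics equal
``N`` times a one-sided two-sample KS distance between the class and
non-class expression distributions.  The score tables ``U`` and ``D`` over
all genes and classes, and the penalised differences ``U - D`` / ``D - U``,
are the raw material for signature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DualKSError

__all__ = [
    "ExpressionMatrix",
    "ClassVector",
    "ScoreTable",
    "ks_increments",
    "running_sum",
    "score_gene_up",
    "score_gene_down",
    "score_all",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression matrix.

    Parameters
    ----------
    values
        ``(G, N)`` float array; every entry must be finite.  The scale is
        arbitrary (the method is rank-based) but NaN/Inf are rejected
        rather than imputed, since silent imputation changes ranks
        invisibly.
    gene_ids, sample_ids
        Unique string identifiers for the ``G`` rows and ``N`` columns.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        if self.values.ndim != 2:
            raise DualKSError("expression values must be a 2-D matrix")
        g, n = self.values.shape
        if g < 1:
            raise DualKSError(f"expression matrix must have at least 1 gene, got {g}x{n}")
        if self.gene_ids.shape != (g,) or self.sample_ids.shape != (n,):
            raise DualKSError("identifier lengths do not match matrix shape")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            uniq, counts = np.unique(ids, return_counts=True)
            dups = uniq[counts > 1]
            if dups.size:
                raise DualKSError(f"duplicate {name} identifiers: {', '.join(dups)}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DualKSError(
                "non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(str), df.columns.to_numpy(str))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids.copy(), columns=self.sample_ids.copy())

    def expression_of(self, gene_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise DualKSError(f"unknown gene {gene_id!r}")
        return self.values[idx[0]]

    def subset_samples(self, indices) -> "ExpressionMatrix":
        """Column subset; repeated indices (bootstrap draws) get suffixed ids."""
        indices = np.asarray(indices, dtype=int)
        ids = self.sample_ids[indices]
        seen: dict[str, int] = {}
        out = []
        for s in ids:
            k = seen.get(s, 0)
            seen[s] = k + 1
            out.append(s if k == 0 else f"{s}#{k + 1}")
        return ExpressionMatrix(self.values[:, indices], self.gene_ids.copy(), np.asarray(out))

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise DualKSError(f"unknown genes: {', '.join(missing)}")
        idx = np.asarray([pos[g] for g in gene_ids], dtype=int)
        return ExpressionMatrix(self.values[idx], self.gene_ids[idx], self.sample_ids.copy())


@dataclass
class ClassVector:
    """Per-sample class labels with a fixed class order.

    ``classes`` fixes the order used everywhere downstream (score-table
    columns, argmax tie-breaking).  Every listed class must occur at least
    once, and no class may hold all samples: the out-of-class increment
    ``-N/(N - N_l)`` is undefined otherwise.
    """

    labels: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=str)
        self.classes = np.asarray(self.classes, dtype=str)
        if self.labels.ndim != 1 or self.labels.size < 2:
            raise DualKSError("need labels for at least 2 samples")
        uniq, counts = np.unique(self.classes, return_counts=True)
        if (counts > 1).any():
            raise DualKSError(f"duplicate classes: {', '.join(uniq[counts > 1])}")
        if self.classes.size < 2:
            raise DualKSError("need at least 2 classes (K >= 2)")
        known = set(self.classes)
        unknown = sorted(set(self.labels) - known)
        if unknown:
            raise DualKSError(f"labels not in class list: {', '.join(unknown)}")
        for c, n_l in zip(self.classes, self.counts):
            if n_l == 0:
                raise DualKSError(f"class {c!r} has no samples (degenerate class)")
            if n_l == self.n_samples:
                raise DualKSError(f"class {c!r} contains every sample (degenerate class)")

    @classmethod
    def from_labels(cls, labels, classes=None) -> "ClassVector":
        labels = np.asarray(labels, dtype=str)
        if classes is None:
            # order of first appearance
            _, first = np.unique(labels, return_index=True)
            classes = labels[np.sort(first)]
        return cls(labels, np.asarray(classes, dtype=str))

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_classes(self) -> int:
        return self.classes.size

    @property
    def counts(self) -> np.ndarray:
        return np.asarray([(self.labels == c).sum() for c in self.classes], dtype=int)

    @property
    def counts_by_class(self) -> dict[str, int]:
        return dict(zip(self.classes.tolist(), self.counts.tolist()))

    @property
    def codes(self) -> np.ndarray:
        """Integer class codes aligned with ``classes``."""
        lookup = {c: k for k, c in enumerate(self.classes)}
        return np.asarray([lookup[y] for y in self.labels], dtype=int)

    def subset(self, indices) -> "ClassVector":
        return ClassVector(self.labels[np.asarray(indices, dtype=int)], self.classes.copy())


@dataclass
class ScoreTable:
    """Per-gene, per-class up/down KS scores.

    ``up``/``down`` are genes x classes frames of ``u_il`` / ``d_il`` (or
    their weighted counterparts when ``kind == "weighted"``).  The penalised
    selection scores are exposed as ``up_delta = up - down`` and
    ``down_delta = down - up``: a gene whose class samples split between both
    ends of the ordered list scores high on both ``u`` and ``d`` and is
    penalised in the difference.
    """

    up: pd.DataFrame
    down: pd.DataFrame
    kind: str = field(default="raw")

    def __post_init__(self) -> None:
        if not self.up.index.equals(self.down.index) or not self.up.columns.equals(self.down.columns):
            raise DualKSError("up and down score tables are not aligned")
        if self.kind not in ("raw", "weighted"):
            raise DualKSError(f"unknown score-table kind {self.kind!r}")

    @property
    def up_delta(self) -> pd.DataFrame:
        return self.up - self.down

    @property
    def down_delta(self) -> pd.DataFrame:
        return self.down - self.up

    @property
    def classes(self) -> np.ndarray:
        return self.up.columns.to_numpy(str)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.up.index.to_numpy(str)


def ks_increments(order, labels: ClassVector, target_class: str) -> np.ndarray:
    """Running-sum increments for one class along an ordered sample list.

    Position ``j`` contributes ``N/N_l`` if the ``j``-th ordered sample
    belongs to ``target_class`` and ``-N/(N - N_l)`` otherwise; the full
    sequence sums to zero.
    """
    order = np.asarray(order, dtype=int)
    n = labels.n_samples
    if order.shape != (n,) or not np.array_equal(np.sort(order), np.arange(n)):
        raise DualKSError("order must be a permutation of 0..N-1")
    if target_class not in labels.classes:
        raise DualKSError(f"unknown class {target_class!r}")
    n_l = int((labels.labels == target_class).sum())
    if n_l in (0, n):
        raise DualKSError(f"class {target_class!r} is degenerate (N_l = {n_l} of N = {n})")
    ordered = labels.labels[order]
    return np.where(ordered == target_class, n / n_l, -n / (n - n_l))


def _sorted_order(expr: np.ndarray, tiebreak: np.ndarray, decreasing: bool) -> np.ndarray:
    # stable, deterministic: expression first, then identifier ascending
    key = -expr if decreasing else expr
    return np.lexsort((tiebreak, key))


def running_sum(
    expr,
    labels: ClassVector,
    target_class: str,
    direction: str = "decreasing",
    sample_ids=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Order samples by one gene's expression and accumulate KS increments.

    Returns ``(order, partial_sums)``.  Ties in expression are broken by
    sample identifier ascending (positional index when ``sample_ids`` is
    not given) so results are reproducible.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape != (labels.n_samples,):
        raise DualKSError("expression vector length does not match labels")
    if not np.isfinite(expr).all():
        raise DualKSError("expression vector contains non-finite values")
    if direction not in ("decreasing", "increasing"):
        raise DualKSError(f"direction must be 'decreasing' or 'increasing', got {direction!r}")
    tiebreak = np.arange(expr.size) if sample_ids is None else np.asarray(sample_ids, dtype=str)
    order = _sorted_order(expr, tiebreak, decreasing=(direction == "decreasing"))
    return order, np.cumsum(ks_increments(order, labels, target_class))


def score_gene_up(expr, labels: ClassVector, target_class: str, sample_ids=None) -> float:
    """Up-regulation score ``u_il``: max running sum over decreasing order."""
    _, sums = running_sum(expr, labels, target_class, "decreasing", sample_ids)
    return float(sums.max())


def score_gene_down(expr, labels: ClassVector, target_class: str, sample_ids=None) -> float:
    """Down-regulation score ``d_il``: max running sum over increasing order.

    With distinct expression values this equals minus the minimum of the
    decreasing-order running sum.
    """
    _, sums = running_sum(expr, labels, target_class, "increasing", sample_ids)
    return float(sums.max())


def score_all(X: ExpressionMatrix, Y: ClassVector) -> ScoreTable:
    """Compute ``U``, ``D`` (and their differences) for all genes and classes.

    Vectorised over genes: each row is argsorted once per direction with
    ties broken by sample identifier, then every class's running sum is a
    cumulative sum over the ordered label codes.
    """
    if Y.n_samples != X.n_samples:
        raise DualKSError(
            f"label count ({Y.n_samples}) does not match sample count ({X.n_samples})"
        )
    n = X.n_samples
    counts = Y.counts
    # Pre-permute columns into sample-id ascending order so a stable argsort
    # breaks expression ties by identifier.
    sid_order = np.argsort(X.sample_ids, kind="stable")
    vals = X.values[:, sid_order]
    codes = Y.codes[sid_order]

    up = np.empty((X.n_genes, Y.n_classes))
    down = np.empty((X.n_genes, Y.n_classes))
    for direction, out in (("dec", up), ("inc", down)):
        key = -vals if direction == "dec" else vals
        order = np.argsort(key, axis=1, kind="stable")
        ordered_codes = codes[order]  # (G, N)
        for k in range(Y.n_classes):
            n_l = counts[k]
            inc = np.where(ordered_codes == k, n / n_l, -n / (n - n_l))
            out[:, k] = np.cumsum(inc, axis=1).max(axis=1)

    idx = pd.Index(X.gene_ids, name="gene")
    cols = pd.Index(Y.classes, name="class")
    return ScoreTable(
        up=pd.DataFrame(up, index=idx, columns=cols),
        down=pd.DataFrame(down, index=idx, columns=cols),
    )
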