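"""Synthetic labelled expression data with known class structure.

The generator emulates a log-scale expression matrix: each gene gets a
baseline level drawn once, Gaussian noise is added per sample, and each
class has a reserved block of informative genes shifted up or down by a
fixed multiple of the noise SD in that class's samples only.  Ground truth
(which genes carry which class's signal) is returned so signature-recovery
and error-rate behaviour can be tested without external datasets.

Gene blocks are assigned deterministically from gene order, so two
simulations from the same spec but different seeds share the same truth —
convenient for train/test splits drawn as independent matrices.

Defaults mirror a desk-scale multi-class microarray study: 200 genes,
3 classes, 20 samples per class, 5 informative genes per class per
direction, and a large effect of 5 noise SDs (near-zero Bayes error, so
recovery and accuracy failures indicate algorithmic faults, not noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_scoring import ClassVector, ExpressionMatrix
from .errors import DualKSError

__all__ = ["SimSpec", "simulate", "worked_example", "class_mean_example"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated dataset; fully determines it given ``seed``."""

    n_genes: int = 200
    n_per_class: int = 20
    n_classes: int = 3
    n_informative: int = 5  # per class per direction
    effect_size: float = 5.0  # shift in units of noise SD
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    distribution: str = "normal"  # or "lognormal" (exponentiated at the end)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise DualKSError("need at least 2 classes")
        if self.n_per_class < 1:
            raise DualKSError("need at least 1 sample per class")
        if self.effect_size < 0:
            raise DualKSError("effect size must be >= 0")
        if self.noise_sd <= 0 or self.baseline_sd < 0:
            raise DualKSError("noise_sd must be > 0 and baseline_sd >= 0")
        if self.n_informative < 0:
            raise DualKSError("n_informative must be >= 0")
        if 2 * self.n_informative * self.n_classes > self.n_genes:
            raise DualKSError(
                "infeasible spec: 2 * n_informative * n_classes "
                f"({2 * self.n_informative * self.n_classes}) exceeds n_genes ({self.n_genes})"
            )
        if self.distribution not in ("normal", "lognormal"):
            raise DualKSError(f"unknown distribution {self.distribution!r}")


def _truth(spec: SimSpec, gene_ids: np.ndarray, classes: list[str]) -> dict[str, dict[str, list[str]]]:
    truth: dict[str, dict[str, list[str]]] = {}
    m = spec.n_informative
    for k, c in enumerate(classes):
        lo = 2 * m * k
        truth[c] = {
            "up": gene_ids[lo : lo + m].tolist(),
            "down": gene_ids[lo + m : lo + 2 * m].tolist(),
        }
    return truth


def simulate(spec: SimSpec) -> tuple[ExpressionMatrix, ClassVector, dict]:
    """Draw one dataset; returns ``(X, Y, truth)``.

    ``truth[class]["up"/"down"]`` lists the informative gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.n_genes
    n = spec.n_per_class * spec.n_classes
    width = max(4, len(str(g)))
    gene_ids = np.asarray([f"g{i + 1:0{width}d}" for i in range(g)])
    sample_ids = np.asarray([f"s{j + 1:03d}" for j in range(n)])
    classes = [f"C{k + 1}" for k in range(spec.n_classes)]
    labels = np.repeat(classes, spec.n_per_class)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=g)
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(g, n))
    truth = _truth(spec, gene_ids, classes)
    shift = spec.effect_size * spec.noise_sd
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    for k, c in enumerate(classes):
        cols = np.flatnonzero(labels == c)
        for gid in truth[c]["up"]:
            values[gene_pos[gid], cols] += shift
        for gid in truth[c]["down"]:
            values[gene_pos[gid], cols] -= shift
    if spec.distribution == "lognormal":
        values = np.exp(values * np.log(2) / 4)  # gentle raw-scale spread

    X = ExpressionMatrix(values, gene_ids, sample_ids)
    Y = ClassVector.from_labels(labels, classes=classes)
    return X, Y, truth


def worked_example() -> tuple[ExpressionMatrix, ClassVector]:
    """The hand-checkable 1-gene, 8-sample, 3-class example.

    For class C1 the decreasing-order running sum peaks at u = 16/5 and the
    increasing-order running sum at d = 8/5.
    """
    values = np.asarray([[1088.3, 841.9, 762.8, 681.2, 744.0, 878.7, 660.1, 1163.2]])
    labels = ["C1", "C1", "C2", "C3", "C1", "C2", "C3", "C2"]
    X = ExpressionMatrix(values, ["gene1"], [f"s{j + 1}" for j in range(8)])
    Y = ClassVector.from_labels(labels, classes=["C1", "C2", "C3"])
    return X, Y


def class_mean_example() -> tuple[ExpressionMatrix, ClassVector]:
    """A 3-gene, 3-class matrix of class means (one sample per class).

    Ranking within class C1 puts gene g1 at rank 2, giving weight
    ``w_11 = -log(2/3)``.
    """
    values = np.asarray(
        [
            [823.64, 777.64, 652.38],
            [987.77, 486.87, 878.98],
            [678.98, 123.68, 268.98],
        ]
    )
    X = ExpressionMatrix(values, ["g1", "g2", "g3"], ["s1", "s2", "s3"])
    Y = ClassVector.from_labels(["C1", "C2", "C3"], classes=["C1", "C2", "C3"])
    return X, Y
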