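"""0.632+ bootstrap error estimation and signature-size selection.

The 0.632+ estimator blends the optimistic resubstitution error
``err_train`` with the pessimistic leave-one-out bootstrap error ``err1``
(each sample's error averaged over the replicates in which it is
out-of-bag).  The blend weight depends on the relative overfitting rate

    R = (err1 - err_train) / (gamma - err_train),   clipped to [0, 1],

where ``gamma = sum_l p_l (1 - q_l)`` is the no-information error rate
(``p_l`` the observed class priors, ``q_l`` the full-data classifier's call
proportions), and

    w = 0.632 / (1 - 0.368 R),
    err632+ = (1 - w) * err_train + w * min(err1, gamma).

Every bootstrap replicate refits the complete model — scoring, weighting
ranks, gene selection and rescale factors — on the in-bag samples only, so
out-of-bag samples never leak into training.  Resampling is stratified
within class by default; with plain resampling, replicates that lose an
entire class are redrawn.

``sweep_signature_size`` repeats the estimate over a grid of signature
sizes ``t`` (and scoring variants) with a shared seed so every grid point
sees identical bootstrap draws, and reports the argmin; ties prefer the
smallest ``t`` — parsimonious signatures are the point of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import classify_matrix
from .core_scoring import ClassVector, ExpressionMatrix
from .errors import DualKSError
from .signatures import VARIANTS, SignatureModel, fit_signature_model

__all__ = [
    "ErrorEstimate",
    "SweepResult",
    "fit_replicate",
    "bootstrap_632plus",
    "sweep_signature_size",
    "GRID_PRESETS",
]

GRID_PRESETS: dict[str, tuple[int, ...]] = {
    "coarse": tuple(range(5, 51, 5)),
    "fine": tuple(range(1, 51)),
}


@dataclass
class ErrorEstimate:
    """Components of one 0.632+ bootstrap error estimate."""

    err_632plus: float
    err_train: float
    err_loo_boot: float
    gamma: float
    R: float
    B: int
    seed: int
    n_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "err_632plus": self.err_632plus,
            "err_train": self.err_train,
            "err_loo_boot": self.err_loo_boot,
            "gamma": self.gamma,
            "R": self.R,
            "B": self.B,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
        }


@dataclass
class SweepResult:
    """Error estimates over a (t, variant) grid plus the selected optimum."""

    grid: list[int]
    variants: list[str]
    estimates: dict[tuple[int, str], ErrorEstimate]
    optimum_t: int = field(init=False)
    optimum_variant: str = field(init=False)

    def __post_init__(self) -> None:
        var_order = {v: i for i, v in enumerate(self.variants)}
        key = min(
            self.estimates,
            key=lambda tv: (self.estimates[tv].err_632plus, tv[0], var_order[tv[1]]),
        )
        self.optimum_t, self.optimum_variant = key

    @property
    def optimum_error(self) -> float:
        return self.estimates[(self.optimum_t, self.optimum_variant)].err_632plus

    def table(self) -> pd.DataFrame:
        rows = [
            {"t": t, "variant": v, **self.estimates[(t, v)].to_dict()}
            for t in self.grid
            for v in self.variants
        ]
        return pd.DataFrame(rows)


def _misclassification(X: ExpressionMatrix, labels: np.ndarray, model: SignatureModel) -> np.ndarray:
    calls = np.asarray([r.call for r in classify_matrix(X, model)], dtype=str)
    return (calls != np.asarray(labels, dtype=str)).astype(float)


def fit_replicate(
    X: ExpressionMatrix,
    Y: ClassVector,
    inbag: np.ndarray,
    t: int,
    variant: str = "default",
    mode: str = "both",
    log_base: str = "e",
) -> SignatureModel:
    """Train one bootstrap replicate's model from its in-bag columns only."""
    return fit_signature_model(
        X.subset_samples(inbag), Y.subset(inbag), t, variant=variant, mode=mode, log_base=log_base
    )


def _draw_inbag(
    Y: ClassVector, rng: np.random.Generator, stratified: bool, redraw_budget: list[int]
) -> np.ndarray:
    n = Y.n_samples
    if stratified:
        parts = [
            rng.choice(np.flatnonzero(Y.labels == c), size=int(n_l), replace=True)
            for c, n_l in zip(Y.classes, Y.counts)
        ]
        return np.concatenate(parts)
    while True:
        inbag = rng.choice(n, size=n, replace=True)
        if all((Y.labels[inbag] == c).any() for c in Y.classes):
            return inbag
        redraw_budget[0] -= 1
        if redraw_budget[0] <= 0:
            raise DualKSError(
                "plain bootstrap kept losing entire classes; "
                "use stratified resampling for data this small"
            )


def bootstrap_632plus(
    X: ExpressionMatrix,
    Y: ClassVector,
    t: int,
    variant: str = "default",
    mode: str = "both",
    B: int = 100,
    seed: int = 0,
    stratified: bool = True,
    log_base: str = "e",
    max_redraws: int | None = None,
) -> ErrorEstimate:
    """Estimate the classifier's error rate with the 0.632+ bootstrap."""
    if B < 1:
        raise DualKSError("B must be >= 1")
    n = Y.n_samples
    if X.n_samples != n:
        raise DualKSError("label count does not match sample count")

    full_model = fit_signature_model(X, Y, t, variant=variant, mode=mode, log_base=log_base)
    calls_full = np.asarray([r.call for r in classify_matrix(X, full_model)], dtype=str)
    err_train = float((calls_full != Y.labels).mean())

    p = Y.counts / n
    q = np.asarray([(calls_full == c).mean() for c in Y.classes])
    gamma = float((p * (1.0 - q)).sum())

    rng = np.random.default_rng(seed)
    redraw_budget = [max_redraws if max_redraws is not None else 100 * B]
    start_redraws = redraw_budget[0]
    err_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    for _ in range(B):
        inbag = _draw_inbag(Y, rng, stratified, redraw_budget)
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size == 0:
            continue
        model_b = fit_replicate(X, Y, inbag, t, variant=variant, mode=mode, log_base=log_base)
        errs = _misclassification(X.subset_samples(oob), Y.labels[oob], model_b)
        err_sum[oob] += errs
        oob_count[oob] += 1
    covered = oob_count > 0
    if not covered.any():
        raise DualKSError("no sample was ever out-of-bag; increase B")
    err1 = float((err_sum[covered] / oob_count[covered]).mean())

    denom = gamma - err_train
    r_hat = 0.0 if denom <= 0 else float(np.clip((err1 - err_train) / denom, 0.0, 1.0))
    w_hat = 0.632 / (1.0 - 0.368 * r_hat)
    err632 = float((1.0 - w_hat) * err_train + w_hat * min(err1, gamma))
    return ErrorEstimate(
        err_632plus=err632,
        err_train=err_train,
        err_loo_boot=err1,
        gamma=gamma,
        R=r_hat,
        B=B,
        seed=seed,
        n_redraws=start_redraws - redraw_budget[0],
    )


def sweep_signature_size(
    X: ExpressionMatrix,
    Y: ClassVector,
    grid,
    variants=("default",),
    mode: str = "up",
    B: int = 100,
    seed: int = 0,
    stratified: bool = True,
    log_base: str = "e",
) -> SweepResult:
    """Estimate the error over a grid of signature sizes and pick the optimum.

    Every (t, variant) estimate reuses the same seed, hence identical
    bootstrap draws, so differences across the grid reflect the signature
    size and scoring variant rather than resampling noise.
    """
    grid = [int(t) for t in grid]
    if not grid:
        raise DualKSError("signature-size grid is empty")
    if len(set(grid)) != len(grid):
        raise DualKSError("signature-size grid contains duplicates")
    for t in grid:
        if t > X.n_genes:
            raise DualKSError(f"grid value t={t} exceeds the number of genes ({X.n_genes})")
    variants = list(variants)
    for v in variants:
        if v not in VARIANTS:
            raise DualKSError(f"unknown variant {v!r}")
    estimates = {
        (t, v): bootstrap_632plus(
            X, Y, t, variant=v, mode=mode, B=B, seed=seed,
            stratified=stratified, log_base=log_base,
        )
        for t in sorted(grid)
        for v in variants
    }
    return SweepResult(grid=sorted(grid), variants=variants, estimates=estimates)
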