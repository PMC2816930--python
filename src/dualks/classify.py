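"""Classify samples by KS enrichment of class signatures.

This is the classical gene-set-enrichment direction: the pooled signature
genes of a sample are ordered by that sample's expression and, for each
class, a running sum gains ``n/n_l`` at slots belonging to that class's
signature and loses ``n/(n - n_l)`` elsewhere.  ``u'_l`` is the maximum
over the decreasing order of the pooled up-genes, ``d'_l`` over the
increasing order of the pooled down-genes; the enrichment score is
``E_l = u'_l + d'_l`` (one term in single-direction modes), divided by the
training-derived factor ``r_l`` in the rescaled variant.  The sample is
called as the argmax class.

The pooled list is built from signature *slots*: each class contributes its
``t`` genes as entries tagged with the owning class, so even if two classes
happen to share a gene every class still has exactly ``n_l`` positive slots
and each running sum terminates at zero.  Only expression ranks matter:
any strictly monotone transform of a sample leaves its calls unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_scoring import ExpressionMatrix
from .errors import DualKSError
from .signatures import SignatureModel

__all__ = ["ClassificationResult", "enrichment_scores", "classify_sample", "classify_matrix"]

_TIE_TOL = 1e-12


@dataclass
class ClassificationResult:
    """Per-sample enrichment scores and the resulting class call."""

    sample_id: str
    scores: dict[str, float]
    call: str
    margin: float
    tie: bool = False


def _as_lookup(x) -> Mapping[str, float]:
    if isinstance(x, pd.Series):
        return x.to_dict()
    return x


def _check_genes(x: Mapping[str, float], model: SignatureModel) -> None:
    missing = sorted(g for g in model.signature_genes() if g not in x)
    if missing:
        raise DualKSError(f"sample is missing signature gene(s): {', '.join(missing)}")


def _direction_scores(
    x: Mapping[str, float],
    signatures: dict[str, list[str]],
    classes: list[str],
    decreasing: bool,
) -> dict[str, float]:
    genes: list[str] = []
    owners: list[int] = []
    for k, c in enumerate(classes):
        for g in signatures[c]:
            genes.append(g)
            owners.append(k)
    genes_arr = np.asarray(genes, dtype=str)
    owners_arr = np.asarray(owners, dtype=int)
    vals = np.asarray([x[g] for g in genes], dtype=float)
    if not np.isfinite(vals).all():
        raise DualKSError("sample contains non-finite expression values for signature genes")
    n = genes_arr.size
    key = -vals if decreasing else vals
    order = np.lexsort((owners_arr, genes_arr, key))  # value, gene id, then class order
    ordered_owner = owners_arr[order]
    out: dict[str, float] = {}
    for k, c in enumerate(classes):
        n_l = len(signatures[c])
        if n_l == 0 or n_l == n:
            raise DualKSError(f"signature of class {c!r} is degenerate ({n_l} of {n} slots)")
        inc = np.where(ordered_owner == k, n / n_l, -n / (n - n_l))
        out[c] = float(np.cumsum(inc).max())
    return out


def enrichment_scores(x, model: SignatureModel) -> dict[str, tuple[float, float]]:
    """Raw per-class ``(u'_l, d'_l)`` for one sample (no rescaling applied).

    ``x`` maps gene id to expression and must cover every gene the model's
    mode requires; inactive directions score 0.
    """
    x = _as_lookup(x)
    _check_genes(x, model)
    classes = list(model.classes)
    zeros = {c: 0.0 for c in classes}
    u = (
        _direction_scores(x, model.up_signatures, classes, decreasing=True)
        if model.mode in ("up", "both")
        else zeros
    )
    d = (
        _direction_scores(x, model.down_signatures, classes, decreasing=False)
        if model.mode in ("down", "both")
        else zeros
    )
    return {c: (u[c], d[c]) for c in classes}


def classify_sample(x, model: SignatureModel, sample_id: str = "sample") -> ClassificationResult:
    """Score one sample against every class signature and call the argmax class.

    Exact score ties across classes are broken by the model's class order
    and flagged on the result.
    """
    raw = enrichment_scores(x, model)
    scores: dict[str, float] = {}
    for c, (u, d) in raw.items():
        e = u + d
        if model.variant == "rescaled":
            if not model.rescale_factors or c not in model.rescale_factors:
                raise DualKSError("rescaled model lacks rescale factors")
            e /= model.rescale_factors[c]
        scores[c] = e
    vals = np.asarray([scores[c] for c in model.classes], dtype=float)
    best = int(np.argmax(vals))  # first max wins: class-order tie-break
    top = vals[best]
    rest = np.delete(vals, best)
    runner_up = float(rest.max())
    return ClassificationResult(
        sample_id=sample_id,
        scores=scores,
        call=model.classes[best],
        margin=float(top - runner_up),
        tie=bool(top - runner_up <= _TIE_TOL),
    )


def classify_matrix(
    X_new: ExpressionMatrix,
    model: SignatureModel,
    allow_missing: bool = False,
) -> list[ClassificationResult]:
    """Classify every column of an expression matrix.

    Signature genes absent from ``X_new`` are a hard error unless
    ``allow_missing`` is set, in which case each missing gene is dropped
    from *every* class's signatures symmetrically (asymmetric dropping
    would bias the scores) and the slot counts are recomputed.
    """
    present = set(X_new.gene_ids.tolist())
    missing = sorted(model.signature_genes() - present)
    if missing:
        if not allow_missing:
            raise DualKSError(
                f"matrix is missing signature gene(s): {', '.join(missing)} "
                "(pass allow_missing to drop them from all signatures)"
            )
        model = model.drop_genes(missing)
    gene_ids = X_new.gene_ids.tolist()
    results = []
    for j in range(X_new.n_samples):
        x = dict(zip(gene_ids, X_new.values[:, j]))
        results.append(classify_sample(x, model, sample_id=str(X_new.sample_ids[j])))
    return results
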