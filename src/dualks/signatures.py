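"""Signature selection, rescaling factors, and model (de)serialisation.

For each class the up-signature is the ``t`` genes with the largest
``U - D`` column scores and the down-signature the ``t`` genes with the
largest ``D - U`` scores (weighted tables for the weighted variant).  Equal
signature sizes give every class the same weight at classification time:
the pooled list has ``n = t * K`` slots with ``n_l = t`` per class.

The rescaled variant divides each class's enrichment score by ``r_l``, the
maximum combined score that class's signature attains on the training
samples, so training scores fall in [0, 1] and arbitrary expression-level
differences between signatures cancel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core_scoring import ClassVector, ExpressionMatrix, ScoreTable, score_all
from .errors import DualKSError
from .weighting import LOG_BASES, class_mean_ranks, weighted_scores, weights

__all__ = [
    "SignatureModel",
    "select_signatures",
    "rescale_factors",
    "fit_signature_model",
    "VARIANTS",
    "MODES",
]

VARIANTS = ("default", "weighted", "rescaled")
MODES = ("up", "down", "both")

MODEL_FORMAT_VERSION = 1


@dataclass
class SignatureModel:
    """A trained classifier: per-class gene lists plus scoring options.

    ``up_signatures[c]`` / ``down_signatures[c]`` are ordered by decreasing
    selection score.  ``rescale_factors`` is present iff
    ``variant == "rescaled"``.
    """

    variant: str
    t: int
    mode: str
    classes: list[str]
    up_signatures: dict[str, list[str]]
    down_signatures: dict[str, list[str]]
    rescale_factors: dict[str, float] | None = None
    log_base: str = field(default="e")

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise DualKSError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.mode not in MODES:
            raise DualKSError(f"mode must be one of {MODES}, got {self.mode!r}")
        if len(self.classes) < 2:
            raise DualKSError("a signature model needs at least 2 classes")
        for sigs in (self.up_signatures, self.down_signatures):
            for c, genes in sigs.items():
                if c not in self.classes:
                    raise DualKSError(f"signature for unknown class {c!r}")
                if len(set(genes)) != len(genes):
                    raise DualKSError(f"duplicate genes in the {c!r} signature")
        if self.rescale_factors is not None:
            for c, r in self.rescale_factors.items():
                if r <= 0:
                    raise DualKSError(
                        f"rescale factor for class {c!r} is {r}; must be positive "
                        "(use the default variant instead)"
                    )

    # -- serialisation -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "variant": self.variant,
            "t": self.t,
            "mode": self.mode,
            "log_base": self.log_base,
            "classes": list(self.classes),
            "up_signatures": {c: list(g) for c, g in self.up_signatures.items()},
            "down_signatures": {c: list(g) for c, g in self.down_signatures.items()},
            "rescale_factors": self.rescale_factors,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SignatureModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise DualKSError(f"unsupported model format version {d.get('format_version')!r}")
        return cls(
            variant=d["variant"],
            t=int(d["t"]),
            mode=d["mode"],
            classes=list(d["classes"]),
            up_signatures={c: list(g) for c, g in d["up_signatures"].items()},
            down_signatures={c: list(g) for c, g in d["down_signatures"].items()},
            rescale_factors=(
                None if d.get("rescale_factors") is None
                else {c: float(r) for c, r in d["rescale_factors"].items()}
            ),
            log_base=d.get("log_base", "e"),
        )

    def save(self, path, extra: dict | None = None) -> None:
        doc = self.to_json_dict()
        if extra:
            doc.update(extra)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "SignatureModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))

    # -- GMT interchange ---------------------------------------------------

    def to_gmt(self, path) -> None:
        """Write one ``CLASS_up`` / ``CLASS_down`` gene set per line."""
        desc = f"variant={self.variant};t={self.t};mode={self.mode}"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for c in self.classes:
                fh.write("\t".join([f"{c}_up", desc, *self.up_signatures[c]]) + "\n")
                fh.write("\t".join([f"{c}_down", desc, *self.down_signatures[c]]) + "\n")

    @classmethod
    def from_gmt(cls, path, variant: str = "default", mode: str = "both") -> "SignatureModel":
        """Rebuild a model from GMT sets named ``CLASS_up`` / ``CLASS_down``."""
        up: dict[str, list[str]] = {}
        down: dict[str, list[str]] = {}
        classes: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                name, _desc, *genes = line.split("\t")
                if name.endswith("_up"):
                    c, target = name[:-3], up
                elif name.endswith("_down"):
                    c, target = name[:-5], down
                else:
                    raise DualKSError(f"GMT set name {name!r} lacks an _up/_down suffix")
                if c not in classes:
                    classes.append(c)
                target[c] = genes
        sizes = {len(g) for g in (*up.values(), *down.values())}
        t = max(sizes) if sizes else 0
        return cls(variant=variant, t=t, mode=mode, classes=classes,
                   up_signatures=up, down_signatures=down)

    # -- convenience -------------------------------------------------------

    def signature_genes(self, mode: str | None = None) -> set[str]:
        """All gene ids the model needs for the given (default: own) mode."""
        mode = mode or self.mode
        genes: set[str] = set()
        if mode in ("up", "both"):
            for g in self.up_signatures.values():
                genes.update(g)
        if mode in ("down", "both"):
            for g in self.down_signatures.values():
                genes.update(g)
        return genes

    def drop_genes(self, gene_ids) -> "SignatureModel":
        """Remove genes from every signature symmetrically (missing-gene policy)."""
        drop = set(gene_ids)
        up = {c: [g for g in genes if g not in drop] for c, genes in self.up_signatures.items()}
        down = {c: [g for g in genes if g not in drop] for c, genes in self.down_signatures.items()}
        for sigs, direction in ((up, "up"), (down, "down")):
            if direction == self.mode or self.mode == "both":
                for c, genes in sigs.items():
                    if not genes:
                        raise DualKSError(
                            f"dropping missing genes empties the {direction} signature of class {c!r}"
                        )
        return replace(self, up_signatures=up, down_signatures=down)


def _top_genes(column, t: int) -> list[str]:
    scores = column.to_numpy(dtype=float)
    genes = column.index.to_numpy(str)
    order = np.lexsort((genes, -scores))  # score desc, then gene id asc
    return genes[order[:t]].tolist()


def select_signatures(
    scores: ScoreTable,
    t: int,
    mode: str = "both",
    variant: str = "default",
    log_base: str = "e",
) -> SignatureModel:
    """Pick the ``t`` highest-scoring genes per class and direction.

    Selection uses the penalised difference columns (``up_delta`` /
    ``down_delta``).  Ties at the boundary are broken by gene identifier
    ascending, which also makes the ``t``-gene signature a prefix of the
    ``t+1``-gene signature.
    """
    g = scores.up.shape[0]
    if not 1 <= t <= g:
        raise DualKSError(f"t must lie in 1..{g} (number of genes), got {t}")
    up_delta, down_delta = scores.up_delta, scores.down_delta
    classes = scores.classes.tolist()
    return SignatureModel(
        variant=variant,
        t=int(t),
        mode=mode,
        classes=classes,
        up_signatures={c: _top_genes(up_delta[c], t) for c in classes},
        down_signatures={c: _top_genes(down_delta[c], t) for c in classes},
        log_base=log_base,
    )


def rescale_factors(model: SignatureModel, X_train: ExpressionMatrix) -> dict[str, float]:
    """Per-class maximum training-sample score, used as the normaliser ``r_l``."""
    from . import classify as _classify  # deferred: classify imports SignatureModel

    best: dict[str, float] = {c: -np.inf for c in model.classes}
    for j in range(X_train.n_samples):
        x = dict(zip(X_train.gene_ids.tolist(), X_train.values[:, j]))
        raw = _classify.enrichment_scores(x, model)
        for c, (u, d) in raw.items():
            best[c] = max(best[c], u + d)
    bad = sorted(c for c, r in best.items() if r <= 0)
    if bad:
        raise DualKSError(
            f"non-positive rescale factor for class(es) {', '.join(bad)}; "
            "rescaling is unusable here — use the default variant"
        )
    return {c: float(r) for c, r in best.items()}


def fit_signature_model(
    X: ExpressionMatrix,
    Y: ClassVector,
    t: int,
    variant: str = "default",
    mode: str = "both",
    log_base: str = "e",
) -> SignatureModel:
    """Train a complete model: score, (optionally) weight, select, (optionally) rescale."""
    if variant not in VARIANTS:
        raise DualKSError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if log_base not in LOG_BASES:
        raise DualKSError(f"log_base must be one of {sorted(LOG_BASES)}, got {log_base!r}")
    scores = score_all(X, Y)
    if variant == "weighted":
        scores = weighted_scores(scores, weights(class_mean_ranks(X, Y), log_base=log_base))
    model = select_signatures(scores, t, mode=mode, variant=variant, log_base=log_base)
    if variant == "rescaled":
        model = replace(model, rescale_factors=rescale_factors(model, X))
    return model
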