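"""Independent brute-force oracles used to check the KS running-sum scores.

These scan every expression threshold directly on empirical distribution
functions and never touch the package's ordering/cumsum code path.
"""

import numpy as np


def ks_up_oracle(expr, labels, target) -> float:
    """N * max over thresholds v of [P(class >= v) - P(rest >= v)]."""
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels, dtype=str)
    cls = expr[labels == target]
    rest = expr[labels != target]
    best = max(float((cls >= v).mean() - (rest >= v).mean()) for v in expr)
    return expr.size * best


def ks_down_oracle(expr, labels, target) -> float:
    """N * max over thresholds v of [P(class <= v) - P(rest <= v)]."""
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels, dtype=str)
    cls = expr[labels == target]
    rest = expr[labels != target]
    best = max(float((cls <= v).mean() - (rest <= v).mean()) for v in expr)
    return expr.size * best


def rank_oracle(values, ids) -> np.ndarray:
    """Ranks (1 = largest) by full sort, ties broken by identifier ascending."""
    values = np.asarray(values, dtype=float)
    ids = np.asarray(ids, dtype=str)
    pairs = sorted(range(values.size), key=lambda i: (-values[i], ids[i]))
    ranks = np.empty(values.size, dtype=int)
    for r, i in enumerate(pairs, start=1):
        ranks[i] = r
    return ranks


def enrichment_up_oracle(x, signatures, classes) -> dict:
    """n * one-sided KS D+ of each class's signature slots vs the rest.

    Slots are (gene, owning class) pairs pooled over all classes; for class
    l the two ECDFs compare the expression of l's slots against everyone
    else's, scanning thresholds brute-force.
    """
    genes, owners = [], []
    for c in classes:
        for g in signatures[c]:
            genes.append(g)
            owners.append(c)
    vals = np.asarray([x[g] for g in genes], dtype=float)
    owners = np.asarray(owners, dtype=str)
    n = vals.size
    out = {}
    for c in classes:
        mine = vals[owners == c]
        rest = vals[owners != c]
        best = max(float((mine >= v).mean() - (rest >= v).mean()) for v in vals)
        out[c] = n * best
    return out
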