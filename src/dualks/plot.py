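"""Minimal plotting hook for classification results.

One panel per class: every sample's enrichment score for that class, sorted
decreasing, coloured by the called class.  Requires matplotlib (optional
dependency); imported lazily so the rest of the package has no plotting
requirement.
"""

from __future__ import annotations

from .classify import ClassificationResult

__all__ = ["plot_scores"]


def plot_scores(results: list[ClassificationResult], classes, path=None):
    """Plot per-class score profiles; returns the matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    classes = list(classes)
    cmap = plt.get_cmap("tab10")
    colour = {c: cmap(i % 10) for i, c in enumerate(classes)}
    fig, axes = plt.subplots(1, len(classes), figsize=(4 * len(classes), 3), squeeze=False)
    for ax, c in zip(axes[0], classes):
        ordered = sorted(results, key=lambda r: -r.scores[c])
        ax.bar(
            range(len(ordered)),
            [r.scores[c] for r in ordered],
            color=[colour[r.call] for r in ordered],
        )
        ax.set_title(f"signature {c}")
        ax.set_xlabel("samples (sorted)")
        ax.set_ylabel("enrichment score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
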