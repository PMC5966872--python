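"""Display of coordinate distributions: ECDF overlays, histograms, ellipses."""

from __future__ import annotations

import numpy as np

from .distributions import GeneDistribution, histogram


def _step_xy(ecdf):
    x = np.concatenate(([0.0], ecdf.x, [1.0]))
    y = np.concatenate(([0.0], ecdf.y, [1.0]))
    return x, y


def plot_ecdfs(distributions, coordinate: str, genes=None, ax=None, per_organ=True):
    """ECDF per gene with light grey per-organ curves behind the pooled one."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    items = [
        d for (g, c), d in sorted(distributions.items())
        if c == coordinate and (genes is None or g in genes)
    ]
    for dist in items:
        if per_organ:
            for organ_ecdf in dist.organ_ecdfs().values():
                ax.step(*_step_xy(organ_ecdf), where="post", color="0.8", lw=0.7)
    for dist in items:
        ax.step(*_step_xy(dist.ecdf), where="post", label=dist.gene, lw=1.5)
    ax.set_xlabel(f"relative {coordinate} position")
    ax.set_ylabel("cumulative fraction of cells")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small")
    return ax


def plot_histograms(distributions, coordinate: str, n_bins: int = 20, axes=None):
    """One histogram panel per gene (display only; stats stay unbinned)."""
    import matplotlib.pyplot as plt

    items = [d for (g, c), d in sorted(distributions.items()) if c == coordinate]
    if axes is None:
        _, axes = plt.subplots(1, len(items), figsize=(2.2 * len(items), 2.2),
                               sharey=True, squeeze=False)
        axes = axes[0]
    for ax, dist in zip(axes, items):
        counts, edges = histogram(dist.sample, n_bins)
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge")
        ax.set_title(dist.gene, fontsize="small")
        ax.set_xlim(0, 1)
    return axes


def plot_ellipses(specs, x_coordinate: str, y_coordinate: str, ax=None):
    """Quartile ellipses: center at the medians, axes spanning Q1..Q3."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots()
    cmap = plt.get_cmap("tab10")
    for i, row in specs.iterrows():
        ax.add_patch(Ellipse(
            (row.x_center, row.y_center), row.x_extent, row.y_extent,
            fill=False, edgecolor=cmap(i % 10), lw=1.5, label=row.gene,
        ))
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel(f"relative {x_coordinate} position")
    ax.set_ylabel(f"relative {y_coordinate} position")
    ax.legend(fontsize="small")
    return ax
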