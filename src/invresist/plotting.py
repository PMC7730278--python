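"""Minimal plotting helpers (dose-response curves, PCA, network)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402

__all__ = ["plot_curves", "plot_pca", "plot_network"]

_DIRECTION_COLORS = {"up": "#c0392b", "down": "#2980b9", "nonconsistent": "#95a5a6"}


def plot_curves(curves, ax=None, logx=True):
    """Overlay viability curves with error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.errorbar(c.points["conc"], c.points["mean_viab"], yerr=c.points["sd"],
                    marker="o", capsize=2, label=c.cell_line)
    if logx:
        ax.set_xscale("log")
    unit = curves[0].unit if curves else ""
    ax.set_xlabel(f"concentration ({unit})")
    ax.set_ylabel("% viability")
    ax.axhline(50, color="grey", lw=0.5, ls="--")
    ax.legend(fontsize=8)
    return ax


def plot_pca(result, ax=None, pcs=(1, 2)):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    i, j = pcs[0] - 1, pcs[1] - 1
    xs = result.coordinates.iloc[:, i]
    ys = result.coordinates.iloc[:, j]
    ax.scatter(xs, ys)
    for name, x, y in zip(result.coordinates.index, xs, ys):
        ax.annotate(str(name), (x, y), fontsize=7)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC{pcs[0]} ({100 * evr[i]:.2f}%)")
    ax.set_ylabel(f"PC{pcs[1]} ({100 * evr[j]:.2f}%)")
    return ax


def plot_network(net, ax=None, hub_degree=7, seed=0):
    """Spring-layout network plot, nodes coloured by direction and sized
    by degree."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    g = net.graph
    pos = nx.spring_layout(g, seed=seed)
    colors = [_DIRECTION_COLORS[d] for _, d in g.nodes(data="direction")]
    sizes = [60 + 40 * g.degree[n] for n in g.nodes]
    nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.4)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=colors, node_size=sizes)
    labels = {n: n for n in g.nodes if g.degree[n] >= hub_degree}
    nx.draw_networkx_labels(g, pos, labels=labels, ax=ax, font_size=8)
    ax.axis("off")
    return ax
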