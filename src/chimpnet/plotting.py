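"""Basic network rendering for bond networks (matplotlib + networkx)."""

from __future__ import annotations

import math

import networkx as nx

from .matrix import DyadMatrix


def plot_network(m: DyadMatrix, ax=None, layout_seed: int = 0):
    """Draw a (binary or weighted) dyadic network with a spring layout.

    Returns the matplotlib Axes. Edge width scales with cell value; arrows are drawn
    for directed matrices.
    """
    import matplotlib.pyplot as plt

    g = nx.DiGraph() if m.directed else nx.Graph()
    g.add_nodes_from(m.ids)
    for i, a in enumerate(m.ids):
        for j, b in enumerate(m.ids):
            if i == j or (not m.directed and j < i):
                continue
            v = m.values[i, j]
            if not math.isnan(v) and v > 0:
                g.add_edge(a, b, weight=float(v))
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=layout_seed)
    weights = [g[u][v]["weight"] for u, v in g.edges()]
    wmax = max(weights) if weights else 1.0
    nx.draw_networkx(
        g,
        pos=pos,
        ax=ax,
        node_color="#c6dbef",
        edgecolors="#333333",
        width=[0.5 + 2.5 * w / wmax for w in weights],
        arrows=m.directed,
        font_size=8,
    )
    ax.set_title(m.label)
    ax.set_axis_off()
    return ax
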