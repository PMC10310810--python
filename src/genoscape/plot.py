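"""2-D disconnectivity-graph rendering.

Leaves (local minima) are drawn at their energies, merged by vertical
connectors at barrier heights; leaf markers are scaled by the absolute
case-control frequency difference and colored red (case-majority),
green (control-majority) or gray (balanced).
"""

from __future__ import annotations

import numpy as np

from .landscape import EnergyLandscape


def plot_disconnectivity(scape: EnergyLandscape, ax=None, marker_scale: float = 2000.0):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    tree = scape.tree_
    xpos: dict[int, float] = {}
    counter = [0.0]

    def layout(node_id: int) -> float:
        node = tree.nodes[node_id]
        if node.leaf_state is not None:
            xpos[node_id] = counter[0]
            counter[0] += 1.0
            return xpos[node_id]
        xs = [layout(c) for c in node.children]
        xpos[node_id] = float(np.mean(xs))
        return xpos[node_id]

    layout(tree.root)

    def draw(node_id: int) -> None:
        node = tree.nodes[node_id]
        for c in node.children:
            child = tree.nodes[c]
            ax.plot([xpos[c], xpos[c]], [child.height, node.height],
                    color="black", lw=1)
            draw(c)
        if node.children:
            xs = [xpos[c] for c in node.children]
            ax.plot([min(xs), max(xs)], [node.height, node.height],
                    color="black", lw=1)

    draw(tree.root)
    summary = scape.node_summary_
    for state, leaf_id in tree.leaf_of_state.items():
        color, size = "gray", 20.0
        if summary is not None and state in summary.index:
            color = summary.loc[state, "color"]
            size = max(10.0, marker_scale * abs(summary.loc[state, "freq_diff"]))
        ax.scatter([xpos[leaf_id]], [tree.nodes[leaf_id].height],
                   s=size, c=color, zorder=3, edgecolors="black", linewidths=0.5)
    ax.set_ylabel("energy")
    ax.set_xticks([])
    return ax
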