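"""Color-mapped reference-tree output.

Per-edge values (dispersion, correlation, PCA loadings, factorization
objectives, ...) are turned into colors and written out as a CSV table,
an edge-annotated Newick string, or a simple SVG heat-tree.  Edges whose
value is undefined (e.g. tip edges for imbalance-derived quantities) are
drawn in a neutral gray.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize, TwoSlopeNorm, to_hex

from .metrics import EdgeValues
from .tree import ReferenceTree

__all__ = ["ColorMap", "render_tree"]

NEUTRAL_COLOR = "#aaaaaa"


@dataclass
class ColorMap:
    """Value-to-color mapping with explicit anchors.

    Divergent palettes keep ``center`` (0 for correlations and
    imbalances) pinned to the palette midpoint; sequential palettes
    stretch linearly from ``vmin`` to ``vmax``.
    """

    palette: str = "viridis"
    vmin: float | None = None
    vmax: float | None = None
    center: float | None = None

    @classmethod
    def for_values(cls, edge_values: EdgeValues) -> "ColorMap":
        """Palette choice mirroring the usual visual semantics: divergent
        centered at 0 for signed quantities, sequential otherwise."""
        kind = edge_values.kind.split(":")[0]
        if kind in ("correlation", "imbalance", "pca", "balance"):
            return cls(palette="coolwarm", center=0.0)
        return cls(palette="viridis")

    def colors(self, values: np.ndarray) -> list[str]:
        v = np.asarray(values, dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size == 0:
            return [NEUTRAL_COLOR] * len(v)
        vmin = self.vmin if self.vmin is not None else float(finite.min())
        vmax = self.vmax if self.vmax is not None else float(finite.max())
        if self.center is not None:
            span = max(abs(vmin - self.center), abs(vmax - self.center), 1e-30)
            norm = TwoSlopeNorm(
                vcenter=self.center, vmin=self.center - span, vmax=self.center + span
            )
        else:
            if vmax <= vmin:
                vmax = vmin + 1e-30
            norm = Normalize(vmin=vmin, vmax=vmax)
        cmap = colormaps[self.palette]
        return [
            to_hex(cmap(norm(x))) if np.isfinite(x) else NEUTRAL_COLOR for x in v
        ]


def _tree_layout(tree: ReferenceTree):
    """Rectangular layout: x = distance from root, y = tip order."""
    depth = tree.node_depths()
    y = np.zeros(tree.num_nodes)
    tip_counter = 0
    for v in tree.postorder_nodes():
        if not tree.children[v]:
            y[v] = tip_counter
            tip_counter += 1
        else:
            y[v] = np.mean([y[c] for c in tree.children[v]])
    return depth, y


def render_tree(
    tree: ReferenceTree,
    edge_values: EdgeValues,
    colormap: ColorMap | None = None,
    out_format: str = "csv",
    path=None,
) -> str | None:
    """Write per-edge values and colors in the requested format.

    ``csv`` writes ``edge_num,value,color`` rows for edges with a
    defined value; ``newick`` writes the tree with a ``[&!color=#hex]``
    comment per edge; ``svg`` draws a rectangular heat-tree.  Returns
    the produced text for the text formats.
    """
    if colormap is None:
        colormap = ColorMap.for_values(edge_values)
    disp = edge_values.display_values()
    colors = colormap.colors(disp)
    defined = edge_values.defined_mask()

    if out_format == "csv":
        lines = ["edge_num,value,color"]
        for col, e in enumerate(tree.edge_order):
            if defined[col]:
                lines.append(f"{int(e)},{float(edge_values.values[col])!r},{colors[col]}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    if out_format == "newick":
        comments = {
            int(e): f"&!color={colors[col]}" for col, e in enumerate(tree.edge_order)
        }
        text = tree.to_newick(edge_comments=comments) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    if out_format == "svg":
        if path is None:
            raise ValueError("svg output requires a path")
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        depth, y = _tree_layout(tree)
        fig, ax = plt.subplots(figsize=(8, max(3, tree.num_tips * 0.25)))
        for col in range(tree.num_edges):
            v = tree.edge_child_node(col)
            p = tree.parent[v] if v != 0 else -1
            x1 = depth[v] if v != 0 else 0.0
            x0 = depth[p] if p >= 0 else -tree.root_branch_length
            yy = y[v]
            ax.plot([x0, x1], [yy, yy], color=colors[col], lw=2.5)
            if p >= 0:
                ax.plot([x0, x0], [y[p], yy], color="#cccccc", lw=1.0)
            if not tree.children[v] and tree.labels[v]:
                ax.text(x1, yy, " " + tree.labels[v], va="center", fontsize=7)
        ax.set_axis_off()
        ax.set_title(edge_values.kind)
        fig.savefig(path, format="svg", bbox_inches="tight")
        plt.close(fig)
        return None

    raise ValueError(f"unknown output format {out_format!r}")
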