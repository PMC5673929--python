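"""Result visualizations: the set impact plot and the radial similarity tree.

The impact plot shows one node per significantly altered set, ordered
along the chemical similarity tree (x), with significance as -log10 of
the set KS p-value (y), node area proportional to set size, and color
encoding the proportion of increased members among altered ones (red =
all increased, blue = all decreased, purple = mixed).  The tree plot is
a radial dendrogram with leaves colored by member direction.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import Dendrogram
from .pipeline import RunResult

__all__ = ["impact_plot_spec", "impact_plot", "tree_plot", "wrap_svg_html"]


def _direction_color(fraction_increased: float):
    """Linear red (1.0) <-> blue (0.0) map through purple at 0.5."""
    f = min(max(fraction_increased, 0.0), 1.0)
    return (f, 0.1, 1.0 - f)


def impact_plot_spec(
    rows,
    filter: str = "p",
    cutoff: float = 0.05,
    display_floor: float = 1e-30,
) -> pd.DataFrame:
    """Node table of the impact plot (one row per passing set)."""
    if filter not in ("p", "fdr"):
        raise ValueError("filter must be 'p' or 'fdr'")
    out = []
    for r in rows:
        stat = r.ks_p if filter == "p" else r.fdr
        if stat >= cutoff:
            continue
        frac = r.n_increased / r.n_altered if r.n_altered else 0.5
        out.append(
            {
                "set": r.set_label,
                "x": r.tree_position,
                "y": -math.log10(max(r.ks_p, display_floor)),
                "size": r.size,
                "fraction_increased": frac,
            }
        )
    return pd.DataFrame(
        out, columns=["set", "x", "y", "size", "fraction_increased"]
    )


def impact_plot(
    rows,
    path: str | Path,
    filter: str = "p",
    cutoff: float = 0.05,
    display_floor: float = 1e-30,
) -> pd.DataFrame:
    """Render the set impact plot to SVG; returns the node table."""
    spec = impact_plot_spec(rows, filter, cutoff, display_floor)
    fig, ax = plt.subplots(figsize=(9, 5))
    if spec.empty:
        ax.text(0.5, 0.5, "no significantly altered sets", ha="center", va="center")
        ax.set_axis_off()
    else:
        colors = [_direction_color(f) for f in spec["fraction_increased"]]
        ax.scatter(
            spec["x"],
            spec["y"],
            s=40 * spec["size"],
            c=colors,
            alpha=0.75,
            edgecolors="black",
            linewidths=0.6,
        )
        for _, row in spec.iterrows():
            ax.annotate(
                row["set"], (row["x"], row["y"]), fontsize=7,
                textcoords="offset points", xytext=(4, 4),
            )
        ax.set_xlabel("position on chemical similarity tree")
        ax.set_ylabel("-log10 set p-value (KS)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
    return spec


def _radial_layout(tree: Dendrogram):
    order = tree.canonical_leaf_order()
    angle = {
        label: 2 * math.pi * i / len(order) for i, label in enumerate(order)
    }
    max_h = max(tree.height(2 * tree.n_leaves - 2), 1e-9)

    pos: dict[int, tuple[float, float]] = {}

    def visit(node: int) -> float:
        kids = tree._children(node)
        if kids is None:
            theta = angle[tree.labels[node]]
        else:
            theta = (visit(kids[0]) + visit(kids[1])) / 2
        radius = 1.0 - tree.height(node) / (1.1 * max_h)
        pos[node] = (theta, radius)
        return theta

    visit(2 * tree.n_leaves - 2)
    return pos


def tree_plot(
    result: RunResult,
    study,
    path: str | Path,
    alpha: float | None = None,
) -> None:
    """Radial similarity dendrogram with direction-colored leaves.

    Leaves are red when the member is increased at raw p < alpha, blue
    when decreased, grey otherwise; arcs mark the span of sets whose KS
    p-value is below 0.05.
    """
    tree = result.tree
    alpha = alpha if alpha is not None else result.config.alpha
    pos = _radial_layout(tree)
    fig, ax = plt.subplots(figsize=(8, 8), subplot_kw={"projection": "polar"})
    ax.set_axis_off()

    def draw(node: int) -> None:
        kids = tree._children(node)
        if kids is None:
            return
        t0, r0 = pos[node]
        for kid in kids:
            t1, r1 = pos[kid]
            ts = np.linspace(t0, t1, 16)
            ax.plot(ts, np.full_like(ts, r0), color="0.6", lw=0.6)
            ax.plot([t1, t1], [r0, r1], color="0.6", lw=0.6)
            draw(kid)

    draw(2 * tree.n_leaves - 2)

    by_id = {r.compound_id: r for r in study}
    for i, label in enumerate(tree.labels):
        theta, _ = pos[i]
        rec = by_id[label]
        if rec.effect_p < alpha and rec.fold_change > 1:
            color = "red"
        elif rec.effect_p < alpha and rec.fold_change < 1:
            color = "blue"
        else:
            color = "0.7"
        ax.plot([theta], [1.0], marker="o", ms=3.5, color=color)

    # arc boundaries of significant sets
    angle = {
        label: 2 * math.pi * i / tree.n_leaves
        for i, label in enumerate(tree.canonical_leaf_order())
    }
    for row in result.rows:
        if row.ks_p >= 0.05:
            continue
        members = result.assignment.members(row.set_label)
        thetas = sorted(angle[cid] for cid in members if cid in angle)
        if not thetas:
            continue
        ts = np.linspace(thetas[0], thetas[-1], 32)
        ax.plot(ts, np.full_like(ts, 1.06), color="black", lw=2.0)

    fig.savefig(path, format="svg")
    plt.close(fig)


def wrap_svg_html(svg_path: str | Path, html_path: str | Path, title: str) -> None:
    """Wrap a rendered SVG into a self-contained HTML file."""
    svg = Path(svg_path).read_text()
    Path(html_path).write_text(
        f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{title}</title></head><body>{svg}</body></html>"
    )
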