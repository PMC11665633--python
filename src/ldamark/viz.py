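"""Publication plots: score barplot, per-feature abundance histogram, and
an annotated radial cladogram.

Layout computation is separated from rendering so tests can assert on the
computed structures (bar order, node radii, colors) instead of pixels. The
default two-class palette is a color-blind-safe blue/orange pair from the
Okabe–Ito set, with neutral gray for background cladogram nodes.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .data_model import (
    AbundanceTable,
    LineageTree,
    MarkerResult,
    SampleGroups,
    ValidationError,
)
from .io_formats import parse_lineage

__all__ = [
    "DEFAULT_PALETTE",
    "NEUTRAL_COLOR",
    "bar_layout",
    "plot_bar",
    "histogram_panels",
    "plot_feature_histogram",
    "cladogram_layout",
    "plot_cladogram",
]

#: (negative-score color, positive-score color) — Okabe–Ito blue / orange.
DEFAULT_PALETTE = ("#0072B2", "#E69F00")
NEUTRAL_COLOR = "#999999"
_SUBCLASS_COLORS = ("#0072B2", "#E69F00", "#009E73", "#CC79A7", "#D55E00", "#56B4E9")


def bar_layout(
    result: MarkerResult, palette: Optional[tuple[str, str]] = None
) -> list[dict]:
    """Bar descriptors in display order (one per record, result order)."""
    palette = palette or DEFAULT_PALETTE
    return [
        {
            "feature": rec.feature_id,
            "score": rec.score,
            "color": palette[1] if rec.score > 0 else palette[0],
        }
        for rec in result.records
    ]


def plot_bar(
    result: MarkerResult,
    out_path,
    palette: Optional[tuple[str, str]] = None,
) -> None:
    """Horizontal barplot of signed scores, one bar per selected feature."""
    if len(result) == 0:
        raise ValidationError("cannot plot an empty marker result")
    layout = bar_layout(result, palette)
    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.4 * len(layout) + 1)))
    try:
        ys = np.arange(len(layout))[::-1]  # best score on top
        ax.barh(
            ys,
            [b["score"] for b in layout],
            color=[b["color"] for b in layout],
            edgecolor="none",
        )
        ax.set_yticks(ys)
        ax.set_yticklabels([b["feature"] for b in layout], fontsize=8)
        ax.axvline(0.0, color="black", linewidth=0.8)
        ax.set_xlabel("LDA score (log10)")
        fig.tight_layout()
        fig.savefig(out_path)
    finally:
        plt.close(fig)


def _as_proportions(table: AbundanceTable) -> np.ndarray:
    """Column-normalize back to proportions (undoes any per-sample scaling)."""
    sums = table.values.sum(axis=0)
    if np.any(sums <= 0):
        raise ValidationError("cannot rescale a table with a zero-sum sample")
    return table.values / sums


def histogram_panels(
    table: AbundanceTable, groups: SampleGroups, feature_id: str
) -> dict[str, dict]:
    """Per-class panel data for the feature histogram.

    Each panel holds the proportion-scale values, their mean and median,
    and (when subclass labels exist) the values split by stratum.
    """
    row = _as_proportions(table)[table.feature_index(feature_id)]
    panels: dict[str, dict] = {}
    for level in groups.class_levels:
        mask = groups.class_mask(level)
        values = row[mask]
        panel = {
            "values": values,
            "mean": float(values.mean()),
            "median": float(np.median(values)),
            "by_subclass": None,
        }
        if groups.has_subclass:
            sub = np.array(groups.subclass_labels)[mask]
            panel["by_subclass"] = {
                s: values[sub == s] for s in dict.fromkeys(sub.tolist())
            }
        panels[level] = panel
    return panels


def plot_feature_histogram(
    table: AbundanceTable,
    groups: SampleGroups,
    feature_id: str,
    out_path,
    bins: int = 15,
) -> None:
    """Histogram of one feature's relative abundance, one panel per class.

    Abundances are drawn on the (0, 1) proportion scale regardless of the
    table's internal scaling. Solid vertical lines mark the panel mean and
    dashed lines the median; subclasses, when present, are color-coded.
    """
    panels = histogram_panels(table, groups, feature_id)
    all_values = np.concatenate([p["values"] for p in panels.values()])
    edges = np.histogram_bin_edges(all_values, bins=bins)
    fig, axes = plt.subplots(
        1, len(panels), figsize=(10, 4), sharex=True, sharey=True
    )
    try:
        for ax, (level, panel) in zip(np.atleast_1d(axes), panels.items()):
            if panel["by_subclass"] is not None:
                strata = list(panel["by_subclass"].items())
                ax.hist(
                    [v for _, v in strata],
                    bins=edges,
                    stacked=True,
                    label=[s for s, _ in strata],
                    color=list(_SUBCLASS_COLORS)[: len(strata)],
                )
                ax.legend(fontsize=8, title="subclass")
            else:
                ax.hist(panel["values"], bins=edges, color=DEFAULT_PALETTE[0])
            ax.axvline(panel["mean"], color="black", linestyle="-", linewidth=1.2)
            ax.axvline(panel["median"], color="black", linestyle="--", linewidth=1.2)
            ax.set_title(str(level))
            ax.set_xlabel("relative abundance")
        np.atleast_1d(axes)[0].set_ylabel("samples")
        fig.suptitle(feature_id, fontsize=10)
        fig.tight_layout()
        fig.savefig(out_path)
    finally:
        plt.close(fig)


def _assign_angles(node, a0: float, a1: float, angles: dict) -> None:
    """Equal-angle layout: wedges proportional to subtree leaf counts."""
    if node.is_leaf:
        angles[id(node)] = (a0 + a1) / 2.0
        return
    total = node.leaf_count()
    start = a0
    child_angles = []
    for child in node.children.values():
        span = (a1 - a0) * child.leaf_count() / total
        _assign_angles(child, start, start + span, angles)
        child_angles.append(angles[id(child)])
        start += span
    angles[id(node)] = float(np.mean(child_angles))


def cladogram_layout(
    result: MarkerResult,
    all_feature_ids: Sequence[str],
    separator: str = "|",
    palette: Optional[tuple[str, str]] = None,
    size_scale: str = "linear",
    min_size: float = 10.0,
    size_per_unit: float = 40.0,
) -> tuple[LineageTree, list[dict]]:
    """Build the annotated tree and the per-node layout descriptors.

    The background topology comes from *all* feature lineages; nodes whose
    full path matches a scored lineage are "significant" and get a class
    color and a marker size monotone in |score| (linear by default,
    ``size_scale="log"`` for log1p scaling). Other nodes stay neutral.
    """
    palette = palette or DEFAULT_PALETTE
    if size_scale not in ("linear", "log"):
        raise ValidationError(f"unknown size_scale {size_scale!r}")
    paths = [tuple(parse_lineage(f, separator)) for f in all_feature_ids]
    tree = LineageTree.from_paths(paths)
    for rec in result.records:
        tree.annotate(
            tuple(parse_lineage(rec.feature_id, separator)),
            rec.score,
            enriched_class="positive" if rec.score > 0 else "negative",
        )

    angles: dict[int, float] = {}
    _assign_angles(tree.root, 0.0, 2.0 * math.pi, angles)
    max_depth = max((n.depth for n in tree.iter_nodes()), default=1)

    nodes = []
    for node in tree.iter_nodes():
        angle = angles[id(node)]
        radius = node.depth / max_depth
        if node.score is not None:
            mag = abs(node.score) if size_scale == "linear" else math.log10(1 + abs(node.score))
            size = min_size + size_per_unit * mag
            color = palette[1] if node.score > 0 else palette[0]
            significant = True
        else:
            size, color, significant = min_size, NEUTRAL_COLOR, False
        nodes.append(
            {
                "name": node.name,
                "path": node.path(),
                "depth": node.depth,
                "angle": angle,
                "radius": radius,
                "size": size,
                "color": color,
                "significant": significant,
                "score": node.score,
                "is_leaf": node.is_leaf,
            }
        )
    return tree, nodes


def plot_cladogram(
    result: MarkerResult,
    all_feature_ids: Sequence[str],
    out_path,
    separator: str = "|",
    labels: str = "tips",
    palette: Optional[tuple[str, str]] = None,
    size_scale: str = "linear",
) -> None:
    """Radial cladogram with |score|-sized, class-colored significant nodes.

    ``labels`` is one of ``"tips"``, ``"all"``, ``"none"``.
    """
    if labels not in ("tips", "all", "none"):
        raise ValidationError(f"labels must be 'tips', 'all' or 'none', got {labels!r}")
    tree, nodes = cladogram_layout(
        result, all_feature_ids, separator, palette, size_scale
    )
    by_path = {n["path"]: n for n in nodes}

    fig, ax = plt.subplots(figsize=(8, 8))
    try:
        for node in nodes:  # edges to parents
            path = node["path"]
            if len(path) > 1:
                parent = by_path[path[:-1]]
                xs = [
                    parent["radius"] * math.cos(parent["angle"]),
                    node["radius"] * math.cos(node["angle"]),
                ]
                ys = [
                    parent["radius"] * math.sin(parent["angle"]),
                    node["radius"] * math.sin(node["angle"]),
                ]
                ax.plot(xs, ys, color="#cccccc", linewidth=0.8, zorder=1)
        xs = [n["radius"] * math.cos(n["angle"]) for n in nodes]
        ys = [n["radius"] * math.sin(n["angle"]) for n in nodes]
        ax.scatter(
            xs,
            ys,
            s=[n["size"] for n in nodes],
            c=[n["color"] for n in nodes],
            zorder=2,
            edgecolors="white",
            linewidths=0.4,
        )
        for node, x, y in zip(nodes, xs, ys):
            wanted = labels == "all" or (labels == "tips" and node["is_leaf"])
            if wanted:
                ax.annotate(
                    node["name"],
                    (x, y),
                    fontsize=6,
                    xytext=(2, 2),
                    textcoords="offset points",
                )
        ax.set_aspect("equal")
        ax.axis("off")
        fig.tight_layout()
        fig.savefig(out_path)
    finally:
        plt.close(fig)
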