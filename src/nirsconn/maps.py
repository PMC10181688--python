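"""Directed connectivity maps: significant edges per condition, hemisphere
bookkeeping, and export to CSV / GraphML / JSON.

A map holds the directed edges j -> i whose coefficient passed the
significance threshold, one map for the baseline connectivity (Phi_0) and
one per non-baseline condition.  Condition maps show the *delta* relative to
baseline by default, matching the model's parameterisation; an absolute mode
renders Phi_0 + Phi_k instead.  Nodes are tagged left/right hemisphere by
the sign of their centroid's x coordinate (montage frame; configurable
axis), with exact zero treated as midline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .cdvar import CDVARFit, significant_edges, wald_pvalues
from .errors import ValidationError
from .projection import ClusterAssignment

__all__ = [
    "Edge",
    "ConnectivityMap",
    "roi_names_for_clusters",
    "build_maps",
    "interhemispheric_summary",
    "export_map",
    "plot_map",
]


class Edge(NamedTuple):
    """One significant directed connection source -> target at a given lag."""

    source: int
    target: int
    lag: int
    weight: float
    z: float
    p: float


@dataclass
class ConnectivityMap:
    """Significant-edge set for one condition."""

    condition: str
    edges: list[Edge]
    node_names: list[str]
    node_hemispheres: list[str]
    alpha: float
    kind: str = "delta"  # "baseline", "delta" or "absolute"

    def __post_init__(self) -> None:
        n = len(self.node_names)
        for e in self.edges:
            if not (0 <= e.source < n and 0 <= e.target < n):
                raise ValidationError(f"edge {e} references a nonexistent cluster")
            if e.p > self.alpha:
                raise ValidationError(
                    f"edge {e} has p={e.p} above alpha={self.alpha}"
                )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def cross_edges(self) -> list[Edge]:
        """Edges between distinct regions (self-loops excluded)."""
        return [e for e in self.edges if e.source != e.target]

    def self_loops(self) -> list[Edge]:
        return [e for e in self.edges if e.source == e.target]


def roi_names_for_clusters(
    assignment: ClusterAssignment, channel_rois: Mapping[int, str] | list[str]
) -> list[str]:
    """Label each cluster by the majority ROI among its member channels.

    ``channel_rois`` maps channel index -> ROI name (or is a per-channel
    list).  Ties break toward the ROI seen earliest in channel order.
    """
    if not isinstance(channel_rois, Mapping):
        channel_rois = dict(enumerate(channel_rois))
    names = []
    for m in range(assignment.n_clusters):
        members = assignment.members(m)
        rois = []
        for ch in members:
            if ch not in channel_rois:
                raise ValidationError(f"ROI table is missing channel {ch}")
            rois.append(channel_rois[ch])
        order = {}  # first-appearance rank for tie-breaking
        for r in rois:
            order.setdefault(r, len(order))
        counts: dict[str, int] = {}
        for r in rois:
            counts[r] = counts.get(r, 0) + 1
        best = max(counts, key=lambda r: (counts[r], -order[r]))
        names.append(best)
    return names


def _hemisphere(x: float, tol: float = 0.0) -> str:
    if x > tol:
        return "right"
    if x < -tol:
        return "left"
    return "midline"


def build_maps(
    fit: CDVARFit,
    assignment: ClusterAssignment,
    roi_table: Mapping[int, str] | list[str] | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
    absolute: bool = False,
    midline_axis: int = 0,
) -> list[ConnectivityMap]:
    """One map per condition from a fitted condition-driven VAR.

    The baseline map draws its edges from Phi_0; condition maps show the
    delta coefficients Phi_k (or, with ``absolute=True``, Phi_0 + Phi_k
    thresholded by the delta's p-values, since only the deltas carry
    per-condition inference).  Both directions of a pair are retained, so
    bidirectional relations appear as two edges.
    """
    if fit.M != assignment.n_clusters:
        raise ValidationError(
            f"fit has M={fit.M} but assignment defines "
            f"{assignment.n_clusters} clusters"
        )
    pvals = fit.pvalues if fit.pvalues is not None else wald_pvalues(fit)
    zvals = fit.zvalues
    mask = significant_edges(pvals, alpha=alpha, correction=correction)

    node_names = (
        roi_names_for_clusters(assignment, roi_table)
        if roi_table is not None
        else [assignment.cluster_name(m) for m in range(assignment.n_clusters)]
    )
    hemis = [
        _hemisphere(assignment.centroids[m, midline_axis])
        for m in range(assignment.n_clusters)
    ]

    maps = []
    for k, cond in enumerate(fit.condition_names):
        edges = []
        weights = fit.phi_total(k) if (absolute and k > 0) else fit.phi[k]
        for l in range(fit.p):
            for i in range(fit.M):
                for j in range(fit.M):
                    if mask[k, l, i, j]:
                        edges.append(
                            Edge(
                                source=j,
                                target=i,
                                lag=l + 1,
                                weight=float(weights[l, i, j]),
                                z=float(zvals[k, l, i, j]),
                                p=float(pvals[k, l, i, j]),
                            )
                        )
        kind = "baseline" if k == 0 else ("absolute" if absolute else "delta")
        maps.append(
            ConnectivityMap(
                condition=cond,
                edges=edges,
                node_names=node_names,
                node_hemispheres=hemis,
                alpha=alpha,
                kind=kind,
            )
        )
    return maps


def interhemispheric_summary(cmap: ConnectivityMap) -> dict[str, int]:
    """Count cross-region edges by hemisphere category.

    Returns intra_left / intra_right / inter counts; edges touching a
    midline node are tallied separately under ``midline``.
    """
    counts = {"intra_left": 0, "intra_right": 0, "inter": 0, "midline": 0}
    for e in cmap.cross_edges():
        hs = cmap.node_hemispheres[e.source]
        ht = cmap.node_hemispheres[e.target]
        if "midline" in (hs, ht):
            counts["midline"] += 1
        elif hs == ht:
            counts[f"intra_{hs}"] += 1
        else:
            counts["inter"] += 1
    return counts


def _map_frame(cmap: ConnectivityMap) -> pd.DataFrame:
    rows = [
        dict(
            source=e.source,
            target=e.target,
            source_roi=cmap.node_names[e.source],
            target_roi=cmap.node_names[e.target],
            lag=e.lag,
            weight=e.weight,
            z=e.z,
            p=e.p,
        )
        for e in cmap.edges
    ]
    return pd.DataFrame(
        rows,
        columns=["source", "target", "source_roi", "target_roi",
                 "lag", "weight", "z", "p"],
    )


def export_map(cmap: ConnectivityMap, fmt: str, path) -> None:
    """Lossless edge-list export as ``csv``, ``graphml`` or ``json``."""
    path = Path(path)
    if fmt == "csv":
        _map_frame(cmap).to_csv(path, index=False)
    elif fmt == "json":
        payload = dict(
            condition=cmap.condition,
            kind=cmap.kind,
            alpha=cmap.alpha,
            nodes=[
                dict(id=i, roi=cmap.node_names[i],
                     hemisphere=cmap.node_hemispheres[i])
                for i in range(len(cmap.node_names))
            ],
            edges=[e._asdict() for e in cmap.edges],
        )
        path.write_text(json.dumps(payload, indent=2))
    elif fmt == "graphml":
        g = nx.MultiDiGraph(condition=cmap.condition, alpha=cmap.alpha,
                            kind=cmap.kind)
        for i, name in enumerate(cmap.node_names):
            g.add_node(i, roi=name, hemisphere=cmap.node_hemispheres[i])
        for e in cmap.edges:
            g.add_edge(e.source, e.target, lag=e.lag, weight=e.weight,
                       z=e.z, p=e.p)
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def plot_map(cmap: ConnectivityMap, assignment: ClusterAssignment, path) -> None:
    """Quick-look figure: cluster centroids (top view, x-y plane) with
    arrows for significant directed edges.  Deliberately minimal -- no
    interpolated topography."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = assignment.centroids[:, :2]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xy[:, 0], xy[:, 1], s=80, zorder=3, color="#444")
    for i, name in enumerate(cmap.node_names):
        ax.annotate(name, xy[i], textcoords="offset points", xytext=(6, 6),
                    fontsize=8)
    for e in cmap.cross_edges():
        src, dst = xy[e.source], xy[e.target]
        color = "tab:red" if e.weight > 0 else "tab:blue"
        ax.annotate(
            "", xy=dst, xytext=src,
            arrowprops=dict(arrowstyle="-|>", color=color,
                            lw=1 + 2 * min(abs(e.weight), 1.0),
                            shrinkA=10, shrinkB=10),
        )
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_title(f"{cmap.condition} ({cmap.kind}, alpha={cmap.alpha})")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
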