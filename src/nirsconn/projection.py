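"""Low-rank spatial projection: K-means clustering of channel coordinates
followed by a per-cluster median (or mean) time series.

The projection maps L channels onto M "informative" regional signals.
Channels are clustered purely by their 3D coordinates (Euclidean K-means),
so clusters correspond to spatially contiguous patches of the montage.  Each
cluster is summarised at every time point by the median across its member
channels: the median tolerates a minority of low-quality channels in a
cluster, which the mean does not -- corrupting fewer than half the members
leaves the median within the spread of the clean members, while the mean
shifts proportionally to the corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import ValidationError
from .io import EventMarker
from .preprocess import HbSeries

__all__ = [
    "ClusterAssignment",
    "ProjectedSeries",
    "cluster_channels",
    "project_median",
    "project_mean",
]


@dataclass
class ClusterAssignment:
    """Channel -> cluster labelling (labels are 0..M-1)."""

    labels: np.ndarray
    n_clusters: int
    centroids: np.ndarray
    seed: int | None = None
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D array")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.n_clusters:
            raise ValidationError("labels must lie in 0..n_clusters-1")
        if len(present) != self.n_clusters:
            missing = sorted(set(range(self.n_clusters)) - set(present))
            raise ValidationError(f"clusters {missing} are empty")
        if self.centroids.shape != (self.n_clusters, 3):
            raise ValidationError("centroids must be (M, 3)")
        if self.roi_names is not None and len(self.roi_names) != self.n_clusters:
            raise ValidationError("roi_names must have one entry per cluster")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def cluster_name(self, cluster: int) -> str:
        if self.roi_names is not None:
            return self.roi_names[cluster]
        return f"cluster{cluster}"


@dataclass
class ProjectedSeries:
    """M regional time series g_l(t) produced by the projection."""

    g: np.ndarray
    fs: float
    assignment: ClusterAssignment
    run_condition: str | None = None
    event_markers: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.event_markers = [EventMarker(*m) for m in self.event_markers]
        if self.g.ndim != 2:
            raise ValidationError("g must be an M x T matrix")
        if self.g.shape[0] != self.assignment.n_clusters:
            raise ValidationError("g row count must equal the cluster count")

    @property
    def n_clusters(self) -> int:
        return self.g.shape[0]

    @property
    def n_samples(self) -> int:
        return self.g.shape[1]


def cluster_channels(
    coords: np.ndarray, n_clusters: int, seed: int | None = 0, n_init: int = 10
) -> ClusterAssignment:
    """Cluster channel coordinates with Euclidean K-means.

    Random initialisation with ``n_init`` restarts, all driven by ``seed``;
    the best-inertia solution is kept, so the result is bit-reproducible for
    a fixed seed.  Requires at least ``n_clusters`` distinct coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("coords must be (L, 3)")
    L = coords.shape[0]
    n_distinct = len(np.unique(coords, axis=0))
    if not (1 <= n_clusters <= L):
        raise ValidationError(f"need 1 <= M <= L={L}, got M={n_clusters}")
    if n_clusters > n_distinct:
        raise ValidationError(
            f"M={n_clusters} exceeds the {n_distinct} distinct coordinate points"
        )
    km = KMeans(
        n_clusters=n_clusters,
        init="random",
        n_init=n_init,
        random_state=seed,
    ).fit(coords)
    return ClusterAssignment(
        labels=km.labels_,
        n_clusters=n_clusters,
        centroids=km.cluster_centers_,
        seed=seed,
    )


def _as_matrix(hb) -> tuple[np.ndarray, float | None, str | None, list]:
    if isinstance(hb, HbSeries):
        return hb.hbo, hb.fs, hb.run_condition, list(hb.event_markers)
    x = np.asarray(hb, dtype=float)
    return x, None, None, []


def _project(hb, assignment: ClusterAssignment, reducer, fs, run_condition):
    x, fs_in, rc_in, markers = _as_matrix(hb)
    if x.shape[0] != assignment.n_channels:
        raise ValidationError(
            f"matrix has {x.shape[0]} channels but assignment covers "
            f"{assignment.n_channels}"
        )
    g = np.empty((assignment.n_clusters, x.shape[1]))
    for m in range(assignment.n_clusters):
        g[m] = reducer(x[assignment.members(m)], axis=0)
    return ProjectedSeries(
        g=g,
        fs=fs if fs is not None else (fs_in if fs_in is not None else 1.0),
        assignment=assignment,
        run_condition=run_condition if run_condition is not None else rc_in,
        event_markers=markers,
    )


def project_median(
    hb, assignment: ClusterAssignment, *, fs: float | None = None,
    run_condition: str | None = None,
) -> ProjectedSeries:
    """Median projection: g_l(t) = median over channels c with label l of
    y_c(t).  Even cluster sizes use the mid-pair average.  Accepts an
    :class:`HbSeries` (projects HbO) or a plain channels x time matrix."""
    return _project(hb, assignment, np.median, fs, run_condition)


def project_mean(
    hb, assignment: ClusterAssignment, *, fs: float | None = None,
    run_condition: str | None = None,
) -> ProjectedSeries:
    """Mean projection, the non-robust alternative kept for comparison."""
    return _project(hb, assignment, np.mean, fs, run_condition)
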