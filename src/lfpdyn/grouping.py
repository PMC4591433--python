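"""Dendrogram grouping of phase-aligned trials.

After phase-resetting correction, trials are clustered hierarchically on the
Euclidean distance between whole waveforms. Distances are computed on the
raw (non-normalized) aligned waveforms so that amplitude differences — which
separate the low-amplitude minority class from the main response classes —
contribute to the tree. Cutting the tree at a distance threshold (or at a
target group count) yields the groups whose averages serve as denoised
templates for the embedding stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .timeseries import TimeSeries, TrialEnsemble

__all__ = [
    "pairwise_distances",
    "build_dendrogram",
    "cut_dendrogram",
    "group_average",
    "DendrogramModel",
    "GroupAssignment",
]

_LINKAGES = ("average", "single", "complete", "ward")


def pairwise_distances(ensemble: TrialEnsemble) -> np.ndarray:
    """Symmetric matrix of Euclidean distances between trial waveforms."""
    arr = ensemble.as_array()
    diff = arr[:, None, :] - arr[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


@dataclass(frozen=True)
class DendrogramModel:
    """Agglomerative merge tree over trial waveforms.

    ``merges`` is a scipy-style linkage matrix: row ``m`` merges clusters
    ``merges[m, 0]`` and ``merges[m, 1]`` at height ``merges[m, 2]`` into new
    cluster ``n_leaves + m``.
    """

    merges: np.ndarray
    n_leaves: int
    linkage: str

    @property
    def root_height(self) -> float:
        return float(self.merges[-1, 2])


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of the trials produced by cutting a dendrogram."""

    labels: np.ndarray  # group index per trial, 1-based, ordered by first member
    cutoff: float | None
    k: int

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


def build_dendrogram(distances: np.ndarray, method: str = "average") -> DendrogramModel:
    """Agglomerate a full distance matrix into a merge tree.

    ``method`` is one of average (default), single, complete, ward. The
    agglomeration is deterministic; ties are resolved by scipy's index order.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distances must be a square matrix")
    if n < 2:
        raise ValueError("need at least 2 trials to build a dendrogram")
    if method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    condensed = squareform(distances, checks=False)
    merges = linkage(condensed, method=method)
    return DendrogramModel(merges=merges, n_leaves=n, linkage=method)


def _relabel_by_first_member(raw: np.ndarray) -> np.ndarray:
    """Renumber group labels so group 1 contains the first trial, etc."""
    labels = np.zeros_like(raw)
    next_label = 0
    seen: dict[int, int] = {}
    for i, g in enumerate(raw):
        if g not in seen:
            next_label += 1
            seen[g] = next_label
        labels[i] = seen[g]
    return labels


def cut_dendrogram(
    model: DendrogramModel,
    cutoff: float | None = None,
    k: int | None = None,
) -> GroupAssignment:
    """Cut the tree at a distance ``cutoff`` or into exactly ``k`` groups.

    Exactly one of ``cutoff`` and ``k`` must be given. A cutoff above the root
    height yields a single group; one below every merge yields singletons.
    """
    if (cutoff is None) == (k is None):
        raise ValueError("give exactly one of cutoff or k")
    if k is not None:
        if not (1 <= k <= model.n_leaves):
            raise ValueError(f"k must lie in [1, {model.n_leaves}]")
        raw = fcluster(model.merges, t=k, criterion="maxclust")
    else:
        if not (cutoff > 0):
            raise ValueError("cutoff must be positive")
        raw = fcluster(model.merges, t=cutoff, criterion="distance")
    labels = _relabel_by_first_member(raw)
    return GroupAssignment(
        labels=labels, cutoff=cutoff, k=int(labels.max())
    )


def group_average(
    ensemble: TrialEnsemble, assignment: GroupAssignment
) -> dict[int, TimeSeries]:
    """Pointwise mean waveform for each group, keyed by group label."""
    if assignment.labels.size != len(ensemble):
        raise ValueError("assignment does not match ensemble size")
    arr = ensemble.as_array()
    out: dict[int, TimeSeries] = {}
    t0 = ensemble.trials[0].t0
    for g in range(1, assignment.k + 1):
        members = assignment.labels == g
        if not members.any():
            raise ValueError(f"group {g} is empty")
        out[g] = TimeSeries(values=arr[members].mean(axis=0), dt=ensemble.dt, t0=t0)
    return out
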