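"""Final-state measures: gap-threshold clustering, cluster participation ratio,
media-cluster occupancy, peak distances, entropy and echo-chamber statistics."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "ClusterPartition",
    "EchoChamberStats",
    "detect_clusters",
    "participation_ratio",
    "media_cluster_occupancy",
    "peak_pairwise_distance",
    "mean_pairwise_distance",
    "opinion_entropy",
    "echo_chamber_stats",
    "summarize_opinions",
]

DEFAULT_GAP_THRESHOLD = 0.01
DEFAULT_OCCUPANCY_BAND = 0.01
MAJOR_CLUSTER_FRACTION = 0.02


@dataclass
class ClusterPartition:
    """Gap-threshold partition of a set of opinions.

    ``members`` holds original agent indices per cluster, ordered by increasing
    cluster mean opinion. A new cluster starts wherever two consecutive sorted
    opinions differ by strictly more than ``gap_threshold``.
    """

    members: list
    sizes: np.ndarray
    means: np.ndarray
    gap_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    @property
    def n_agents(self) -> int:
        return int(self.sizes.sum())

    def major_cluster_count(self, min_fraction: float = MAJOR_CLUSTER_FRACTION) -> int:
        """Number of clusters holding at least ``min_fraction`` of the agents."""
        return int(np.sum(self.sizes >= min_fraction * self.n_agents))

    def major_means(self, min_fraction: float = MAJOR_CLUSTER_FRACTION) -> np.ndarray:
        """Mean opinions of the major clusters, in increasing order."""
        return self.means[self.sizes >= min_fraction * self.n_agents]

    def signature(self) -> tuple:
        """Hashable membership fingerprint used by equilibrium detection."""
        return tuple(tuple(sorted(m.tolist())) for m in self.members)


@dataclass
class EchoChamberStats:
    """Per-node (own opinion, mean neighbor opinion) pairs, their joint histogram
    over the unit square, and the linear correlation across pairs. The correlation
    is ``None`` when either marginal is degenerate."""

    pairs: np.ndarray  # shape (n_included, 2)
    histogram: np.ndarray  # shape (grid, grid)
    correlation: float | None


def detect_clusters(
    opinions: Sequence[float], gap_threshold: float = DEFAULT_GAP_THRESHOLD
) -> ClusterPartition:
    """Partition opinions by scanning sorted values for gaps above the threshold.

    A gap exactly equal to the threshold does not split a cluster; singletons are
    clusters. The cluster count is the headline fragmentation measure.
    """
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be positive")
    x = np.asarray(opinions, dtype=np.float64)
    if x.size == 0:
        raise ValueError("opinions must be non-empty")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    # boundaries where the sorted gap strictly exceeds the threshold
    breaks = np.flatnonzero(np.diff(xs) > gap_threshold) + 1
    members = [np.sort(chunk) for chunk in np.split(order, breaks)]
    sizes = np.array([m.size for m in members], dtype=np.int64)
    means = np.array([x[m].mean() for m in members])
    return ClusterPartition(members, sizes, means, float(gap_threshold))


def participation_ratio(partition: ClusterPartition) -> float:
    """Cluster participation ratio ``(Σ c_i)² / Σ c_i²``.

    Equals the cluster count when all clusters share the same size and
    approaches 1 when a single cluster dominates.
    """
    c = partition.sizes.astype(np.float64)
    if c.size == 0:
        raise ValueError("partition has no clusters")
    return float(c.sum() ** 2 / np.sum(c**2))


def media_cluster_occupancy(
    opinions: Sequence[float],
    x_m: float,
    lam: float = DEFAULT_OCCUPANCY_BAND,
) -> float:
    """Percentage of agents inside the closed band ``[x_m - lam, x_m + lam]``."""
    x = np.asarray(opinions, dtype=np.float64)
    inside = (x >= x_m - lam) & (x <= x_m + lam)
    return 100.0 * inside.mean()


def peak_pairwise_distance(partition: ClusterPartition) -> float:
    """Mean absolute distance between cluster mean opinions (peaks); 0 for a
    single cluster."""
    means = partition.means
    if means.size == 0:
        raise ValueError("partition has no clusters")
    if means.size == 1:
        return 0.0
    return float(np.mean([abs(a - b) for a, b in combinations(means, 2)]))


def mean_pairwise_distance(opinions: Sequence[float]) -> float:
    """All-agent-pairs variant of the peak distance (ambiguity fallback)."""
    x = np.sort(np.asarray(opinions, dtype=np.float64))
    n = x.size
    if n < 2:
        return 0.0
    # sum over pairs of |x_a - x_b| via the sorted prefix-sum identity
    ranks = np.arange(n)
    total = np.sum((2 * ranks - n + 1) * x)
    return float(total / (n * (n - 1) / 2))


def opinion_entropy(opinions: Sequence[float], n_bins: int = 100) -> float:
    """Shannon entropy (bits) of the opinion histogram over ``n_bins`` equal bins
    on [0, 1]; 0 for a degenerate distribution, at most ``log2(n_bins)``."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(opinions, dtype=np.float64)
    counts, _ = np.histogram(x, bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def echo_chamber_stats(
    opinions: Sequence[float], graph, grid: int = 20
) -> EchoChamberStats:
    """Correlate each node's opinion with the mean opinion of its neighbors.

    Isolated nodes are excluded. ``graph`` is an
    :class:`~bcmedia.graphs.InteractionGraph` (or anything with ``n_nodes`` and
    ``neighbors``).
    """
    x = np.asarray(opinions, dtype=np.float64)
    pairs = []
    for i in range(graph.n_nodes):
        nbrs = graph.neighbors(i)
        if nbrs.size == 0:
            continue
        pairs.append((x[i], x[nbrs].mean()))
    if not pairs:
        raise ValueError("graph has no edges; echo-chamber statistics undefined")
    pairs = np.asarray(pairs)
    hist, _, _ = np.histogram2d(
        pairs[:, 0], pairs[:, 1], bins=grid, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    if np.ptp(pairs[:, 0]) == 0.0 or np.ptp(pairs[:, 1]) == 0.0:
        corr = None
    else:
        corr = float(np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1])
    return EchoChamberStats(pairs=pairs, histogram=hist, correlation=corr)


def summarize_opinions(
    opinions: Sequence[float],
    media=None,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    lam: float = DEFAULT_OCCUPANCY_BAND,
    major_fraction: float = MAJOR_CLUSTER_FRACTION,
) -> dict:
    """Standard per-run metrics bundle used by the sweep tables.

    Includes one ``occupancy_media{k}`` column per medium when a
    :class:`~bcmedia.core.MediaLandscape` is supplied.
    """
    x = np.asarray(opinions, dtype=np.float64)
    part = detect_clusters(x, gap_threshold)
    largest = int(np.argmax(part.sizes))
    major = part.sizes >= major_fraction * part.n_agents
    out = {
        "n_clusters": part.n_clusters,
        "n_major_clusters": int(major.sum()),
        "participation_ratio": participation_ratio(part),
        "peak_distance": peak_pairwise_distance(part),
        "entropy": opinion_entropy(x),
        "mean_opinion": float(x.mean()),
        "largest_cluster_mean": float(part.means[largest]),
        "lowest_major_cluster_mean": float(part.means[major][0]) if major.any() else np.nan,
        "highest_major_cluster_mean": float(part.means[major][-1]) if major.any() else np.nan,
    }
    if media is not None:
        for k, x_m in enumerate(media.media_opinions):
            out[f"occupancy_media{k}"] = media_cluster_occupancy(x, x_m, lam)
    return out
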