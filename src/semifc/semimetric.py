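"""Semi-metric decomposition of weighted FC networks.

A coherence weight x_ij in (0, 1] maps to a graph distance

    l_ij = 1/x_ij - 1

so perfectly coherent channels are at distance 0 and weak edges are far
apart. In the resulting complete distance graph an edge is *semi-metric*
when some circuitous route is shorter than the direct connection
(l_ij > l'_ij, the all-pairs shortest-path length) — a triangle-inequality
violation interpreted as information flow preferring shared multi-node
paths. Edges lying on their own shortest path (s_ij = l_ij/l'_ij = 1) form
the *metric backbone*, which alone reproduces every shortest-path length.
The semi-metric percentage SMP = #(s_ij > 1)/E summarizes network
redundancy globally or within a region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .coherence import FCMatrix

__all__ = [
    "DistanceGraph",
    "ShortestPathResult",
    "SemiMetricResult",
    "to_distance",
    "all_pairs_shortest",
    "semimetric_ratio",
    "smp",
    "regional_smp",
    "shared_path_histogram",
    "analyze",
]


@dataclass
class DistanceGraph:
    """Symmetric non-negative pairwise distances l_ij (diagonal ignored)."""

    lengths: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        l = np.asarray(self.lengths, dtype=float)
        if l.ndim != 2 or l.shape[0] != l.shape[1]:
            raise ValueError("lengths must be square")
        if np.abs(l - l.T).max() > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        off = ~np.eye(l.shape[0], dtype=bool)
        if np.any(l[off] < 0):
            raise ValueError("distances must be non-negative")
        self.lengths = l
        if self.node_ids is None:
            self.node_ids = [f"n{i}" for i in range(l.shape[0])]

    @property
    def n(self) -> int:
        return self.lengths.shape[0]


@dataclass
class ShortestPathResult:
    """All-pairs shortest-path lengths with deterministic path reconstruction.

    ``hops[i, j]`` is the edge count of the reconstructed shortest path;
    ``predecessors[i, j]`` the node preceding j on that path (ties broken by
    lowest node index, so hop histograms are reproducible).
    """

    dist: np.ndarray
    hops: np.ndarray
    predecessors: np.ndarray
    node_ids: list[str]

    def path(self, i: int, j: int) -> list[int]:
        """Node sequence of the reconstructed shortest path from i to j."""
        if i == j:
            return [i]
        nodes = [j]
        k = j
        while k != i:
            k = int(self.predecessors[i, k])
            nodes.append(k)
            if len(nodes) > self.dist.shape[0]:
                raise RuntimeError("predecessor chain does not terminate")
        return nodes[::-1]


@dataclass
class SemiMetricResult:
    ratio: np.ndarray  # s_ij, NaN on the diagonal
    semi_metric: np.ndarray  # boolean edge labels
    smp_global: float
    smp_regional: dict[str, float]
    shared_path_histogram: dict[int, int]
    n_edges: int  # E in the SMP denominator


def to_distance(fc: FCMatrix, eps: float = 1e-6) -> DistanceGraph:
    """Map coherence weights to distances, l = 1/max(x, eps) - 1.

    Zero weights are clamped to ``eps`` (distance 1/eps - 1) instead of
    deleting the edge, so the edge count E stays that of the complete graph.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = fc.weights
    l = 1.0 / np.maximum(x, eps) - 1.0
    np.fill_diagonal(l, 0.0)
    return DistanceGraph(l, list(fc.channel_ids))


def _reconstruct_predecessors(
    w: np.ndarray, dist: np.ndarray, tree_pred: np.ndarray
) -> np.ndarray:
    """Lowest-index predecessor matrix consistent with the given distances.

    For each (i, j), the predecessor is the smallest k with
    dist[i, k] + w[k, j] == dist[i, j] (within relative float slack),
    restricted to candidates that strictly shorten the remaining distance so
    the chain terminates. When zero-length edges leave no such candidate the
    shortest-path tree's own predecessor is used (still deterministic).
    """
    n = w.shape[0]
    pred = np.asarray(tree_pred, dtype=np.int32).copy()
    tol = 1e-12
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            target = dist[i, j]
            slack = tol * max(1.0, target)
            for k in range(n):
                if k == j:
                    continue
                if dist[i, k] + w[k, j] <= target + slack and (
                    k == i or dist[i, k] < target - slack
                ):
                    pred[i, j] = k
                    break
    return pred


def all_pairs_shortest(dist: DistanceGraph) -> ShortestPathResult:
    """Exact all-pairs shortest paths (Johnson's algorithm) plus one
    deterministically reconstructed path per pair."""
    w = dist.lengths
    off = ~np.eye(dist.n, dtype=bool)
    if np.any(w[off] < 0):
        raise ValueError("negative edge lengths are not allowed")
    # csgraph treats dense zeros as missing edges; encode true zero-length
    # edges (coherence exactly 1) with a negligible positive value instead.
    w_enc = w.copy()
    w_enc[off & (w == 0)] = 1e-300
    d, tree_pred = shortest_path(w_enc, method="J", directed=False, return_predecessors=True)
    d[d < 1e-200] = 0.0
    pred = _reconstruct_predecessors(w, d, tree_pred)
    hops = np.zeros_like(pred)
    for i in range(dist.n):
        for j in range(dist.n):
            if i == j:
                continue
            k, steps = j, 0
            while k != i:
                k = int(pred[i, k])
                steps += 1
            hops[i, j] = steps
    return ShortestPathResult(d, hops, pred, list(dist.node_ids))


def semimetric_ratio(
    dist: DistanceGraph, sp: ShortestPathResult, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge semi-metricity ratio s_ij = l_ij / l'_ij and labels.

    An edge is labeled semi-metric when s_ij > 1 + tol (relative tolerance);
    ties count as metric-backbone edges. Pairs with l = l' = 0 get s = 1.
    """
    l = dist.lengths
    lp = sp.dist
    n = dist.n
    ratio = np.full((n, n), np.nan)
    off = ~np.eye(n, dtype=bool)
    bad = off & (lp == 0) & (l > 0)
    assert not bad.any(), "shortest path of length 0 for an edge of positive length"
    pos = off & (lp > 0)
    ratio[pos] = l[pos] / lp[pos]
    ratio[off & (lp == 0)] = 1.0
    semi = np.zeros((n, n), dtype=bool)
    semi[off] = ratio[off] > 1.0 + tol
    return ratio, semi


def smp(semi: np.ndarray) -> float:
    """Semi-metric percentage: semi-metric edges over all E = N(N-1)/2 edges."""
    n = semi.shape[0]
    e = n * (n - 1) // 2
    if e == 0:
        raise ValueError("network has no edges")
    count = int(np.triu(semi, 1).sum())
    return count / e


def regional_smp(
    semi: np.ndarray,
    node_ids: list[str],
    roi_map: dict[str, str],
    exclusions: set[str] = frozenset(),
) -> dict[str, float]:
    """SMP restricted to intra-ROI edges (both endpoints inside the ROI).

    ``exclusions`` drops channels (e.g. the midline-adjacent ones) before
    the hemispheric comparison; the denominator is the intra-ROI edge count.
    """
    rois: dict[str, list[int]] = {}
    for idx, ch in enumerate(node_ids):
        roi = roi_map.get(ch)
        if roi is None or ch in exclusions:
            continue
        rois.setdefault(roi, []).append(idx)
    out = {}
    for roi, members in rois.items():
        m = len(members)
        if m < 2:
            raise ValueError(f"ROI {roi!r} has fewer than 2 member nodes")
        sub = semi[np.ix_(members, members)]
        out[roi] = int(np.triu(sub, 1).sum()) / (m * (m - 1) // 2)
    return out


def shared_path_histogram(sp: ShortestPathResult) -> dict[int, int]:
    """Histogram of node counts of the reconstructed shortest paths.

    Counts each unordered pair once; a '2' entry is a direct (metric) hop,
    larger entries are shared circuitous routes.
    """
    n = sp.dist.shape[0]
    iu = np.triu_indices(n, 1)
    node_counts = sp.hops[iu] + 1
    vals, counts = np.unique(node_counts, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def analyze(
    fc: FCMatrix,
    eps: float = 1e-6,
    tol: float = 1e-9,
    exclusions: set[str] | None = None,
) -> SemiMetricResult:
    """Full semi-metric analysis of one FC matrix."""
    dist = to_distance(fc, eps)
    sp = all_pairs_shortest(dist)
    ratio, semi = semimetric_ratio(dist, sp, tol)
    regional = {}
    if fc.roi_map is not None:
        regional = regional_smp(
            semi,
            list(fc.channel_ids),
            fc.roi_map,
            exclusions if exclusions is not None else fc.hemisphere_excluded,
        )
    n = fc.n
    return SemiMetricResult(
        ratio=ratio,
        semi_metric=semi,
        smp_global=smp(semi),
        smp_regional=regional,
        shared_path_histogram=shared_path_histogram(sp),
        n_edges=n * (n - 1) // 2,
    )
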