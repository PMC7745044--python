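"""Weighted graph-theory benchmark metrics for FC networks.

These are the conventional indices the semi-metric analysis is compared
against: clustering coefficient CC, characteristic path length lambda,
global efficiency, local efficiency and nodal efficiency, all on the
unthresholded weighted network. Distances reuse the same l = 1/x - 1
conversion as the semi-metric branch so both analyses see one geometry.

The clustering coefficient is the weighted generalization via geometric-mean
triangle intensity on max-normalized weights (the binary formula
2m / (k_i (k_i - 1)) is its special case); on an unthresholded complete
weighted graph the binary formula would be identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coherence import FCMatrix
from .semimetric import ShortestPathResult, all_pairs_shortest, to_distance

__all__ = [
    "GraphMetricsResult",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_efficiency",
    "compute_graph_metrics",
]

# 1/d contributions are capped where d collapses to 0 (coherence exactly 1);
# the floor matches the distance of the eps-clamped zero-coherence edge.
_D_FLOOR = 1e-6


@dataclass
class GraphMetricsResult:
    cc: float
    lam: float
    e_global: float
    e_local: float
    regional: dict[str, dict[str, float]]  # ROI -> {cc, lam, e_nodal}
    per_node: dict[str, dict[str, float]]  # channel -> {strength, degree, cc, e_nodal}


def _inv_d(d: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(d, _D_FLOOR)


def clustering_coefficient(fc: FCMatrix) -> tuple[float, np.ndarray]:
    """Network-mean weighted clustering coefficient and per-node values.

    C_i = sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) / (k_i (k_i - 1)) with
    w' = w / max(w) and k_i the node degree (count of nonzero weights);
    nodes with k_i < 2 contribute 0.
    """
    w = fc.weights.copy()
    np.fill_diagonal(w, 0.0)
    if fc.n < 3:
        raise ValueError("clustering needs at least 3 nodes")
    wmax = w.max()
    per_node = np.zeros(fc.n)
    if wmax > 0:
        cr = np.cbrt(w / wmax)
        triangles = np.diagonal(cr @ cr @ cr)
        k = (w > 0).sum(axis=1)
        ok = k >= 2
        per_node[ok] = triangles[ok] / (k[ok] * (k[ok] - 1))
    return float(per_node.mean()), per_node


def characteristic_path_length(sp: ShortestPathResult) -> float:
    """lambda = mean over nodes of the mean shortest-path length to all others."""
    d = sp.dist
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(~np.isfinite(d[off])):
        pairs = [tuple(p) for p in np.argwhere(off & ~np.isfinite(d))]
        raise ValueError(f"graph is disconnected; infinite distance for pairs {pairs[:5]}")
    return float(d[off].reshape(n, n - 1).mean(axis=1).mean())


def global_efficiency(sp: ShortestPathResult) -> float:
    """E_global = mean over ordered pairs of 1/d_ij (inverse harmonic mean)."""
    d = sp.dist
    n = d.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    return float(_inv_d(d[off]).mean())


def _subgraph_global_efficiency(w_sub: np.ndarray) -> float:
    """E_global of a (possibly incomplete) weighted subgraph.

    Edges with weight 0 are treated as absent; unreachable pairs contribute
    0 efficiency. Weight-1 edges (distance 0) are encoded with a negligible
    positive length because dense csgraph input treats zeros as non-edges.
    """
    from scipy.sparse.csgraph import shortest_path as _sp

    m = w_sub.shape[0]
    if m < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        l = 1.0 / w_sub - 1.0
    l[w_sub <= 0] = 0.0  # dense-csgraph null value: edge absent
    l[(w_sub > 0) & (l == 0.0)] = 1e-300
    np.fill_diagonal(l, 0.0)
    d = _sp(l, method="D", directed=False)
    d[d < 1e-200] = 0.0
    off = ~np.eye(m, dtype=bool)
    vals = d[off]
    inv = np.zeros_like(vals)
    finite = np.isfinite(vals)
    inv[finite] = _inv_d(vals[finite])
    return float(inv.mean())


def local_efficiency(fc: FCMatrix) -> float:
    """Mean over nodes of E_global of the neighbor-induced subgraph.

    Distances inside each subgraph are recomputed from its own weights;
    nodes with fewer than two neighbors contribute 0.
    """
    w = fc.weights.copy()
    np.fill_diagonal(w, 0.0)
    vals = []
    for i in range(fc.n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            vals.append(0.0)
            continue
        vals.append(_subgraph_global_efficiency(w[np.ix_(nb, nb)]))
    return float(np.mean(vals))


def nodal_efficiency(sp: ShortestPathResult) -> np.ndarray:
    """Per-node E_nodal = mean over other nodes of 1/d_ij on the full graph."""
    d = sp.dist
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    inv[off] = _inv_d(d[off])
    return inv.sum(axis=1) / (n - 1)


def compute_graph_metrics(
    fc: FCMatrix,
    eps: float = 1e-6,
    apply_exclusions: bool = True,
) -> GraphMetricsResult:
    """Global and per-ROI weighted graph metrics of one FC matrix.

    Regional CC and lambda are computed on the ROI-induced subgraph (its own
    weights and recomputed distances); regional E_nodal averages full-graph
    nodal efficiencies over ROI members. Hemisphere-contrast exclusion
    channels are dropped from ROI memberships when ``apply_exclusions``.
    """
    dist = to_distance(fc, eps)
    sp = all_pairs_shortest(dist)
    cc, cc_nodes = clustering_coefficient(fc)
    lam = characteristic_path_length(sp)
    eg = global_efficiency(sp)
    el = local_efficiency(fc)
    en = nodal_efficiency(sp)
    strength = fc.weights.sum(axis=1) - np.diagonal(fc.weights)
    degree = (fc.weights > 0).sum(axis=1) - (np.diagonal(fc.weights) > 0)

    regional: dict[str, dict[str, float]] = {}
    if fc.roi_map is not None:
        for roi, members in fc.roi_indices(apply_exclusions=apply_exclusions).items():
            if len(members) < 3:
                raise ValueError(f"ROI {roi!r} too small for regional metrics")
            sub_fc = FCMatrix(
                fc.weights[np.ix_(members, members)],
                [fc.channel_ids[m] for m in members],
            )
            sub_sp = all_pairs_shortest(to_distance(sub_fc, eps))
            regional[roi] = {
                "cc": clustering_coefficient(sub_fc)[0],
                "lam": characteristic_path_length(sub_sp),
                "e_nodal": float(en[members].mean()),
            }

    per_node = {
        ch: {
            "strength": float(strength[i]),
            "degree": int(degree[i]),
            "cc": float(cc_nodes[i]),
            "e_nodal": float(en[i]),
        }
        for i, ch in enumerate(fc.channel_ids)
    }
    return GraphMetricsResult(cc, lam, eg, el, regional, per_node)
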