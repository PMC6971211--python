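"""Complex-network statistics on weighted connectomes.

Five statistics summarise information processing in a weighted graph with
adjacency ``W`` (Fisher-z connectome):

* node strength  k_i = sum_j w_ij  (the weighted "degree");
* characteristic path length  L — mean shortest-path length with edge length
  1/w, averaged over reachable pairs;
* global efficiency  E — mean inverse shortest-path length (zero for
  unreachable pairs), meaningful on disconnected graphs;
* local efficiency  Eloc — efficiency of each node's neighbour subgraph,
  weighted by the cube root of the two spokes and the inverse neighbour
  distance;
* clustering coefficient  C — geometric-mean triangle intensity
  t_i = 1/2 * sum_{j,h} (w_ij w_ih w_jh)^(1/3), normalised by the binary
  degree pair count.

Path- and triangle-based formulas are undefined for negative weights, so by
default negative entries are set to zero for metric computation (the signed
matrix itself is left untouched); ``negative_mode="abs"`` is available as an
alternative convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "StatisticsRecord",
    "processed_weights",
    "node_strength",
    "shortest_paths",
    "char_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "compute_statistics",
    "statistics_table",
    "MEASURES",
]

MEASURES = ("strength", "char_path_length", "global_efficiency", "local_efficiency", "clustering")


@dataclass
class StatisticsRecord:
    """The five network statistics of one connectome (means and per-node vectors)."""

    strength: float
    char_path_length: float
    global_efficiency: float
    local_efficiency: float
    clustering: float
    strength_per_node: np.ndarray
    clustering_per_node: np.ndarray
    triangle_intensity: np.ndarray
    n_rois: int
    meta: dict

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in MEASURES}


def _weights(G) -> np.ndarray:
    return np.asarray(getattr(G, "weights", G), dtype=float)


def processed_weights(G, negative_mode: str = "zero") -> np.ndarray:
    """Non-negative weight matrix used by path/triangle metrics."""
    W = _weights(G).copy()
    np.fill_diagonal(W, 0.0)
    if negative_mode == "zero":
        W[W < 0] = 0.0
    elif negative_mode == "abs":
        W = np.abs(W)
    else:
        raise ValueError(f"unknown negative_mode {negative_mode!r}")
    return W


def node_strength(G, negative_mode: str = "zero") -> np.ndarray:
    """k_i = sum of processed weights incident to each node."""
    return processed_weights(G, negative_mode).sum(axis=1)


def shortest_paths(G, negative_mode: str = "zero") -> np.ndarray:
    """All-pairs shortest-path lengths with edge length 1/weight.

    Zero-weight entries are non-edges; unreachable pairs are ``inf``.
    """
    W = processed_weights(G, negative_mode)
    if (W < 0).any():
        raise AssertionError("processed weights must be non-negative")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def char_path_length(G, negative_mode: str = "zero") -> float:
    """L: mean over nodes of the mean finite distance to the other nodes.

    Unreachable pairs are excluded from the average; isolated nodes (no
    finite distance to anyone) are excluded from the outer mean.  A graph
    with no edges has no defined L.
    """
    d = shortest_paths(G, negative_mode)
    n = d.shape[0]
    if n < 2 or not np.isfinite(d[np.triu_indices(n, 1)]).any():
        raise ValueError("characteristic path length undefined for an edgeless graph")
    off = ~np.eye(n, dtype=bool)
    per_node = []
    for i in range(n):
        finite = np.isfinite(d[i]) & off[i]
        if finite.any():
            per_node.append(d[i, finite].mean())
    return float(np.mean(per_node))


def global_efficiency(G, negative_mode: str = "zero") -> float:
    """E = (1/n) sum_i sum_{j != i} d_ij^-1 / (n-1), with 1/inf = 0."""
    W = processed_weights(G, negative_mode)
    n = W.shape[0]
    if n < 2:
        return 0.0
    d = shortest_paths(W)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(G, negative_mode: str = "zero") -> float:
    """Eloc: neighbourhood efficiency averaged over nodes.

    For each node i with binary degree k_i >= 2, neighbour pairs (j, z)
    contribute (w_ij * w_iz * d_jz(N_i)^-1)^(1/3), where d_jz(N_i) is the
    shortest path between j and z in the subgraph induced by i's neighbours;
    the sum is normalised by k_i (k_i - 1).  Nodes with fewer than two
    neighbours contribute 0.
    """
    W = processed_weights(G, negative_mode)
    n = W.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        dsub = shortest_paths(sub)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(dsub) & (dsub > 0), 1.0 / dsub, 0.0)
        spokes = W[i, nbrs]
        contrib = np.cbrt(np.outer(spokes, spokes) * inv)
        np.fill_diagonal(contrib, 0.0)
        total += contrib.sum() / (k * (k - 1))
    return float(total / n)


def clustering_coefficient(G, negative_mode: str = "zero", per_node: bool = False):
    """C: mean weighted clustering, with geometric-mean triangle intensity.

    t_i = 1/2 * sum_{j,h} (w_ij w_ih w_jh)^(1/3) and
    C_i = 2 t_i / (k_i (k_i - 1)) with k_i the *binary* degree (so that C_i
    stays in [0, 1] for weights in [0, 1]); nodes with binary degree < 2
    contribute 0.
    """
    W = processed_weights(G, negative_mode)
    A = np.cbrt(W)
    t = np.diag(A @ A @ A) / 2.0
    k_bin = (W > 0).sum(axis=1)
    denom = k_bin * (k_bin - 1)
    C_i = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1), 0.0)
    if per_node:
        return C_i, t
    return float(C_i.mean()) if len(C_i) else 0.0


def compute_statistics(G, negative_mode: str = "zero") -> StatisticsRecord:
    """All five statistics of one connectome in a single record."""
    W = processed_weights(G, negative_mode)
    k = W.sum(axis=1)
    C_i, t = clustering_coefficient(W, per_node=True)
    try:
        L = char_path_length(W)
    except ValueError:
        L = float("nan")
    return StatisticsRecord(
        strength=float(k.mean()),
        char_path_length=L,
        global_efficiency=global_efficiency(W),
        local_efficiency=local_efficiency(W),
        clustering=float(C_i.mean()) if len(C_i) else 0.0,
        strength_per_node=k,
        clustering_per_node=C_i,
        triangle_intensity=t,
        n_rois=W.shape[0],
        meta=dict(getattr(G, "meta", {})),
    )


def statistics_table(records: Iterable[StatisticsRecord]) -> pd.DataFrame:
    """Long-format table (subject, run, condition, atlas, measure, value)."""
    rows = []
    for rec in records:
        for measure in MEASURES:
            rows.append(
                {
                    "subject_id": rec.meta.get("subject_id"),
                    "run": rec.meta.get("run"),
                    "condition": rec.meta.get("condition"),
                    "atlas": rec.meta.get("atlas"),
                    "measure": measure,
                    "value": getattr(rec, measure),
                }
            )
    return pd.DataFrame(rows)
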