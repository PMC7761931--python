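"""Weighted graph metrics and feature-vector assembly.

Metrics follow the standard weighted-network conventions for functional
connectivity: the local clustering coefficient uses the geometric-mean
triangle formulation on weights rescaled by the global maximum (Onnela
convention), the global clustering coefficient is the mean of the local
values, and the characteristic path length is the mean shortest-path length
over unordered node pairs with edge length = 1/weight. The classification
feature vector concatenates, for each band, the local clustering
coefficients in node order followed by the global clustering coefficient and
the global path length, giving n_nodes*n_bands + 2*n_bands features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

FeatureKey = tuple[str, str, str | None]  # (band, kind, node label or None)


def _as_weight_matrix(w: np.ndarray | ConnectivityMatrix) -> np.ndarray:
    if isinstance(w, ConnectivityMatrix):
        w = w.values
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def local_clustering(w: np.ndarray | ConnectivityMatrix) -> np.ndarray:
    """Weighted clustering coefficient per node, in [0, 1].

    c_u = (1 / (k_u (k_u - 1))) * sum_{v,w} (w'_uv w'_uw w'_vw)^(1/3),
    with weights w' rescaled by the global maximum and k_u the number of
    nonzero-weight neighbours. Nodes with degree < 2 score 0.
    """
    w = _as_weight_matrix(w)
    wmax = w.max()
    if wmax == 0:
        warnings.warn("all-zero weight matrix: clustering coefficients are 0", stacklevel=2)
        return np.zeros(w.shape[0])
    cbrt = np.cbrt(w / wmax)
    triangles = np.diagonal(cbrt @ cbrt @ cbrt)
    deg = (w > 0).sum(axis=1)
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return cc


def global_clustering(w: np.ndarray | ConnectivityMatrix) -> float:
    """Mean of the local clustering coefficients."""
    return float(local_clustering(w).mean())


def char_path_length(w: np.ndarray | ConnectivityMatrix, mode: str = "mean") -> float:
    """Characteristic path length of a weighted graph with edge length 1/weight.

    ``mode="mean"`` (default) returns the mean shortest-path length over all
    unordered node pairs; ``mode="sum"`` returns the literal sum over pairs.
    Unreachable pairs are excluded with a warning.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    w = _as_weight_matrix(w)
    if w.shape[0] < 2:
        raise ValueError("path length undefined for fewer than 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    iu = np.triu_indices_from(dist, k=1)
    pair_dists = dist[iu]
    finite = np.isfinite(pair_dists)
    if not finite.all():
        warnings.warn(
            "graph is disconnected; path length over reachable pairs only", stacklevel=2
        )
        pair_dists = pair_dists[finite]
        if pair_dists.size == 0:
            raise ValueError("no reachable node pairs")
    return float(pair_dists.sum() if mode == "sum" else pair_dists.mean())


@dataclass
class NetworkFeatureVector:
    """Ordered feature vector with an index describing each entry.

    Order, per band: local clustering coefficients in node order, then the
    global clustering coefficient, then the global path length.
    """

    values: np.ndarray
    index: list[FeatureKey]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.index):
            raise ValueError("values and index must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def names(self) -> list[str]:
        return [
            f"{band}__{kind}" + (f"__{node}" if node is not None else "")
            for band, kind, node in self.index
        ]


def assemble_features(
    per_band_matrices: Sequence[ConnectivityMatrix],
    path_mode: str = "mean",
) -> NetworkFeatureVector:
    """Concatenate graph metrics across bands into one feature vector.

    With n nodes and b bands the vector has length n*b + 2*b.
    """
    if not per_band_matrices:
        raise ValueError("need at least one connectivity matrix")
    n = per_band_matrices[0].n_nodes
    if n < 2:
        raise ValueError("graph metrics are undefined for fewer than 2 nodes")
    labels = per_band_matrices[0].node_labels or [f"node{i:03d}" for i in range(n)]
    values: list[float] = []
    index: list[FeatureKey] = []
    for mat in per_band_matrices:
        if mat.n_nodes != n:
            raise ValueError("all bands must share the same node set")
        band_name = mat.band.name if mat.band is not None else "band"
        cc = local_clustering(mat)
        values.extend(cc.tolist())
        index.extend((band_name, "local_cc", labels[i]) for i in range(n))
        values.append(float(cc.mean()))
        index.append((band_name, "global_cc", None))
        values.append(char_path_length(mat, mode=path_mode))
        index.append((band_name, "path_length", None))
    return NetworkFeatureVector(values=np.asarray(values), index=index)
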