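"""Barabási–Albert information networks and degree-based impact weights.

The information network determines who observes whom.  It is grown by
preferential attachment with two parameters: the final node count ``P`` and
the number of existing nodes each new node attaches to, ``lam``.  The growth
starts from ``lam`` edgeless nodes; the first added node necessarily connects
to all of them, and each subsequent node attaches to ``lam`` distinct
existing nodes sampled proportionally to current degree.  Large ``lam``
(close to ``P``) produces a strongly skewed degree distribution in which the
``P - lam`` *added* nodes become hubs.

Impact weights turn degrees into shares of environmental influence:
``W_i = d_i^nu / sum_j d_j^nu``.  With ``nu = 0`` every agent has the same
impact; larger ``nu`` concentrates impact on hubs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NetworkModel",
    "ImpactWeights",
    "generate_ba",
    "complete_network",
    "degree_skewness",
    "impact_weights",
    "read_edgelist",
    "write_edgelist",
    "node_table",
]


@dataclass
class NetworkModel:
    """Undirected simple graph in CSR form, plus generation metadata.

    ``neighbors(i)`` is ``indices[indptr[i]:indptr[i+1]]`` (sorted node ids).
    ``initial_node_ids`` are the ``lam`` nodes present before attachment
    began; the remaining ``P - lam`` added nodes are flagged as hubs.
    """

    node_count: int
    attachment_count: int
    indptr: np.ndarray
    indices: np.ndarray
    degrees: np.ndarray
    initial_node_ids: np.ndarray
    is_hub: np.ndarray
    generator_seed: int | None = None

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def edge_count(self) -> int:
        return int(self.indices.size) // 2


@dataclass
class ImpactWeights:
    """Normalized per-node environmental impact shares."""

    W: np.ndarray
    nu: float

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)


def _from_nx(
    g: nx.Graph, lam: int, initial_ids: np.ndarray, seed: int | None
) -> NetworkModel:
    P = g.number_of_nodes()
    a = nx.to_scipy_sparse_array(g, nodelist=range(P), format="csr")
    degrees = np.diff(a.indptr).astype(np.int64)
    is_hub = np.ones(P, dtype=bool)
    is_hub[initial_ids] = False
    return NetworkModel(
        node_count=P,
        attachment_count=lam,
        indptr=a.indptr.astype(np.int64),
        indices=a.indices.astype(np.int64),
        degrees=degrees,
        initial_node_ids=initial_ids,
        is_hub=is_hub,
        generator_seed=seed,
    )


def generate_ba(P: int, lam: int, seed: int | None = None) -> NetworkModel:
    """Grow a preferential-attachment network with ``P`` nodes.

    Construction: ``lam`` initial edgeless nodes (ids ``0..lam-1``); then
    ``P - lam`` nodes added sequentially, each connecting to ``lam`` distinct
    existing nodes chosen degree-proportionally (the first added node is
    forced onto all initial nodes, which seeds the urn).  Added nodes (ids
    ``lam..P-1``) are the hubs of the skewed construction.

    The resulting graph always has exactly ``lam * (P - lam)`` edges and is
    deterministic given ``seed``.
    """
    if not (1 <= lam < P):
        raise ValueError(f"attachment count must satisfy 1 <= lam < P, got lam={lam}, P={P}")
    # networkx seeds the process from a star on lam+1 nodes, which is exactly
    # the state after the first (forced) attachment; relabel so the initial
    # edgeless nodes come first and the added nodes (hubs) last.
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(P, lam, seed=int(rng.integers(2**31)))
    mapping = {0: lam, **{k: k - 1 for k in range(1, lam + 1)}}
    g = nx.relabel_nodes(g, mapping, copy=True)
    initial_ids = np.arange(lam, dtype=np.int64)
    return _from_nx(g, lam, initial_ids, seed)


def complete_network(P: int) -> NetworkModel:
    """Complete graph on ``P`` nodes: the full-information control topology."""
    if P < 2:
        raise ValueError("complete network needs at least 2 nodes")
    g = nx.complete_graph(P)
    return _from_nx(g, P - 1, np.arange(P, dtype=np.int64), None)


def degree_skewness(net: NetworkModel) -> float:
    """Fisher–Pearson sample skewness g1 of the degree sequence.

    Returns 0.0 for degree-regular graphs (zero variance) by convention.
    """
    d = np.asarray(net.degrees, dtype=float)
    if d.size < 3:
        raise ValueError("skewness requires at least 3 nodes")
    m2 = np.mean((d - d.mean()) ** 2)
    if m2 == 0.0:
        return 0.0
    m3 = np.mean((d - d.mean()) ** 3)
    return float(m3 / m2**1.5)


def impact_weights(degrees: np.ndarray, nu: float) -> ImpactWeights:
    """Degree-powered impact shares W_i = d_i^nu / sum_j d_j^nu.

    ``nu = 0`` gives uniform weights 1/P regardless of degrees (0^0 := 1).
    Zero-degree nodes receive weight 0 when ``nu > 0``.
    """
    if nu < 0:
        raise ValueError(f"impact exponent nu must be >= 0, got {nu}")
    d = np.asarray(degrees, dtype=float)
    if np.any(d < 0):
        raise ValueError("degrees must be nonnegative")
    if nu == 0:
        w = np.full(d.size, 1.0 / d.size)
    else:
        raw = d**nu
        total = raw.sum()
        if total == 0:
            raise ValueError("all degrees zero: impact weights undefined for nu > 0")
        w = raw / total
    return ImpactWeights(W=w, nu=nu)


def write_edgelist(net: NetworkModel, path: str | os.PathLike) -> None:
    """Write the graph as a two-column whitespace edge list (0-based ids)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(net.node_count):
            for j in net.neighbors(i):
                if i < j:
                    fh.write(f"{i} {j}\n")


def read_edgelist(path: str | os.PathLike, node_count: int | None = None) -> NetworkModel:
    """Read an undirected edge list; isolated trailing ids need ``node_count``."""
    g = nx.read_edgelist(path, nodetype=int)
    P = node_count if node_count is not None else (max(g.nodes) + 1 if g.nodes else 0)
    g.add_nodes_from(range(P))
    return _from_nx(g, 0, np.arange(P, dtype=np.int64), None)


def node_table(net: NetworkModel, weights: ImpactWeights | None = None):
    """Per-node attribute table (id, degree, is_hub[, weight]) as a DataFrame."""
    import pandas as pd

    data = {
        "id": np.arange(net.node_count),
        "degree": net.degrees,
        "is_hub": net.is_hub,
    }
    if weights is not None:
        data["weight"] = weights.W
    return pd.DataFrame(data)
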