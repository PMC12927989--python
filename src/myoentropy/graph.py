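"""Per-sample fiber adjacency network and node-specific average path length.

Each participant sample yields one undirected, unweighted graph: fibers are
nodes, shared segmented boundaries are edges. The node-specific average
path length (APL) of a fiber is the mean hop-count shortest-path distance
to all other fibers reachable within that sample's network — low values
mark topologically central (densely clustered) fibers, high values
peripheral ones. Networks are never pooled across participants.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

__all__ = ["build_graph", "node_average_path_length", "apl_for_samples"]


class GraphDataError(ValueError):
    """Edges reference unknown node ids."""


def build_graph(
    fiber_ids: Iterable[int], edges: Iterable[tuple[int, int]]
) -> nx.Graph:
    """Undirected sample graph over the given fibers.

    Duplicate and reversed edges collapse; self-edges and edges to ids not
    in ``fiber_ids`` raise. Connected components are labeled on nodes
    (attribute ``component``).
    """
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in fiber_ids)
    for a, b in edges:
        a, b = int(a), int(b)
        if a == b:
            raise GraphDataError(f"self-edge on fiber {a}")
        if a not in g or b not in g:
            raise GraphDataError(f"edge ({a}, {b}) references unknown fiber id")
        g.add_edge(a, b)
    for ci, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            g.nodes[n]["component"] = ci
    return g


def node_average_path_length(g: nx.Graph) -> dict[int, float]:
    """Node-specific APL: mean BFS distance to all reachable nodes.

    Averaged over reachable nodes only; isolated nodes (nothing reachable)
    get NaN and are excluded downstream with a logged count. All-pairs
    distances run on a sparse matrix per graph (cheap at per-sample sizes
    of a few hundred fibers).
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    idx = {v: i for i, v in enumerate(nodes)}
    if g.number_of_edges() == 0:
        logger.info("%d isolated fibers: APL undefined", n)
        return {v: float("nan") for v in nodes}
    rows, cols = zip(*((idx[a], idx[b]) for a, b in g.edges))
    adj = coo_matrix(
        (np.ones(len(rows)), (np.array(rows), np.array(cols))), shape=(n, n)
    )
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    np.fill_diagonal(dist, np.inf)
    reachable = np.isfinite(dist)
    counts = reachable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        apl = np.where(
            counts > 0, np.where(reachable, dist, 0.0).sum(axis=1) / counts, np.nan
        )
    n_iso = int((counts == 0).sum())
    if n_iso:
        logger.info("%d isolated fibers: APL undefined", n_iso)
    return {v: float(apl[idx[v]]) for v in nodes}


def apl_for_samples(
    fibers, id_col: str = "fiber_id", group_col: str = "participant_id"
) -> "np.ndarray":
    """Compute APL per fiber for a multi-participant fiber table.

    ``fibers`` must carry a ``neighbors`` column of id collections local to
    each participant. Returns APL values aligned with the table rows.
    """
    out = np.full(len(fibers), np.nan)
    for _, block in fibers.groupby(group_col, sort=False):
        ids = block[id_col].to_numpy()
        edges = set()
        for fid, nbs in zip(ids, block["neighbors"]):
            for nb in nbs:
                edges.add((min(int(fid), int(nb)), max(int(fid), int(nb))))
        g = build_graph(ids, edges)
        apl = node_average_path_length(g)
        out[fibers.index.get_indexer(block.index)] = [apl[int(i)] for i in ids]
    return out
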