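"""Seed-neighborhood subnetwork construction.

Given seed genes (e.g. products of transcripts enriched in inclusion
bodies), the disease-specific subnetwork is built from the embedded full
network: its nodes are the matched seeds plus their first neighbors, and its
edges are exactly the full-network edges incident to at least one seed
(seed-seed and seed-neighbor; neighbor-neighbor edges are excluded).  An
induced-subgraph mode that keeps neighbor-neighbor edges is available behind
a flag.  Coordinates are always those inferred on the full network — the
subnetwork is never re-embedded.
"""

from __future__ import annotations

import logging

import networkx as nx

__all__ = ["seed_neighborhood", "restrict_coordinates"]

logger = logging.getLogger(__name__)


def seed_neighborhood(graph: nx.Graph, seeds, induced: bool = False) -> nx.Graph:
    """Subnetwork of the matched seeds, their neighbors and seed-incident edges.

    Seeds absent from the network are logged with a warning and recorded in
    the result's ``graph["unmatched_seeds"]``; if no seed matches, an error
    listing them is raised.  With ``induced=True`` the full induced subgraph
    on seeds plus neighbors is returned instead (neighbor-neighbor edges
    kept).
    """
    seeds = list(dict.fromkeys(seeds))  # de-duplicate, keep order
    if not seeds:
        raise ValueError("empty seed list")
    matched = [s for s in seeds if s in graph]
    unmatched = [s for s in seeds if s not in graph]
    if not matched:
        raise ValueError(
            "no seed matches a network node; unmatched identifiers: "
            + ", ".join(map(str, unmatched))
        )
    if unmatched:
        logger.warning(
            "%d of %d seeds not found in the network: %s",
            len(unmatched), len(seeds), ", ".join(map(str, unmatched)),
        )

    seed_set = set(matched)
    nodes = set(matched)
    for s in matched:
        nodes.update(graph.neighbors(s))

    sub = nx.Graph()
    sub.add_nodes_from((v, graph.nodes[v]) for v in nodes)
    if induced:
        edges = (
            (u, v, d) for u, v, d in graph.edges(nodes, data=True)
            if u in nodes and v in nodes
        )
    else:
        edges = (
            (u, v, d) for u, v, d in graph.edges(data=True)
            if u in seed_set or v in seed_set
        )
    sub.add_edges_from(edges)
    sub.graph["matched_seeds"] = sorted(matched, key=str)
    sub.graph["unmatched_seeds"] = sorted(unmatched, key=str)
    return sub


def restrict_coordinates(coords: dict, nodes) -> dict:
    """Restrict a full-network coordinate map to a subnetwork's node set.

    The returned values are the very objects from the full embedding (no
    re-embedding, no copying); a node without a coordinate is an error.
    """
    out = {}
    for node in nodes:
        if node not in coords:
            raise KeyError(f"node {node!r} has no coordinate in the full embedding")
        out[node] = coords[node]
    return out
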