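"""LaBNE + HM hyperbolic embedding.

Two-stage inference of polar coordinates for every node of a connected
network under the popularity-similarity model:

1. LaBNE (Laplacian-based network embedding): the eigenvectors of the two
   smallest strictly positive eigenvalues of the symmetric normalized graph
   Laplacian give a planar spectral layout; its polar angle is the initial
   similarity coordinate.  Radii are fixed by degree rank,
   r_i = 2 beta ln i + 2 (1 - beta) ln N, and are never refined.

2. HM refinement: nodes are visited in decreasing degree order and each
   node's angle is moved to the maximum-likelihood position on a
   deterministic candidate grid of width w centred on its current angle,
   scoring its full adjacency row (edges and non-edges) under the
   Fermi-Dirac kernel.  Because the incumbent angle is always a candidate,
   the total network log-likelihood never decreases across sweeps.

The embedding is deterministic: eigenvector signs are canonicalized by
forcing the largest-magnitude entry positive, and all tie-breaks are by
node id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .geometry import (
    TWO_PI,
    HyperbolicPoint,
    ModelParams,
    connection_probability,
    connection_radius,
    coords_to_arrays,
    distances_from_point,
    network_loglikelihood,
    radial_from_degree_rank,
)

__all__ = ["EmbeddedNetwork", "labne", "hm_refine", "embed_labne_hm"]

#: above this node count the spectral step switches from dense eigh to a
#: sparse shift-invert eigensolver
DENSE_EIG_LIMIT = 3000


@dataclass
class EmbeddedNetwork:
    """A network together with inferred hyperbolic coordinates."""

    graph: nx.Graph
    coords: dict
    params: ModelParams
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.coords) != set(self.graph.nodes):
            raise ValueError("coordinate keys must equal the node set")


def _positive_eigenvectors(graph: nx.Graph, nodelist) -> np.ndarray:
    """Eigenvectors of the 2 smallest strictly positive Laplacian eigenvalues.

    Uses the symmetric normalized Laplacian; for a connected graph the
    spectrum is 0 = l1 < l2 <= l3 <= ..., so columns 2 and 3 are returned.
    Signs are canonicalized (largest-|entry| positive).
    """
    n = len(nodelist)
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodelist, weight=None, format="csr")
    adj = adj.astype(float)
    lap = scipy.sparse.csgraph.laplacian(adj, normed=True)
    if n <= DENSE_EIG_LIMIT:
        vals, vecs = scipy.linalg.eigh(lap.toarray())
    else:
        v0 = np.ones(n) / math.sqrt(n)  # fixed start vector for determinism
        vals, vecs = scipy.sparse.linalg.eigsh(lap, k=6, sigma=-1e-6, v0=v0)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    positive = np.flatnonzero(vals > 1e-9)
    if len(positive) < 2:
        raise ValueError("graph Laplacian has fewer than two positive eigenvalues")
    out = vecs[:, positive[:2]].copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def labne(
    graph: nx.Graph,
    gamma: float = 2.97,
    temp: float = 0.83,
    m: int | None = None,
) -> EmbeddedNetwork:
    """Spectral (Laplacian-eigenmaps) stage of the LaBNE + HM embedding.

    Angles come from the planar spectral layout, radii from degree rank with
    beta = 1/(gamma - 1), and the connection radius R from the PS closed
    form.  ``m`` defaults to max(1, round(mean degree / 2)).
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("embedding needs at least 3 nodes")
    if not nx.is_connected(graph):
        raise ValueError(
            "network is disconnected; extract its largest connected component "
            "(extract_lcc) before embedding"
        )
    nodelist = sorted(graph.nodes, key=str)
    plane = _positive_eigenvectors(graph, nodelist)
    theta = np.mod(np.arctan2(plane[:, 1], plane[:, 0]), TWO_PI)

    degrees = dict(graph.degree())
    if m is None:
        mean_deg = 2.0 * graph.number_of_edges() / n
        m = max(1, round(mean_deg / 2.0))
    beta = 1.0 / (gamma - 1.0)
    radii = radial_from_degree_rank(degrees, beta, n)
    radius = connection_radius(n, m, beta, temp)
    params = ModelParams(gamma=gamma, temp=temp, m=m, beta=beta, radius=radius)

    coords = {
        node: HyperbolicPoint(radii[node], float(theta[i]))
        for i, node in enumerate(nodelist)
    }
    trace = [network_loglikelihood(graph, coords, radius, temp)] if temp > 0 else []
    return EmbeddedNetwork(graph, coords, params, trace)


def hm_refine(
    embedded: EmbeddedNetwork,
    temp: float | None = None,
    window: float = TWO_PI,
    n_candidates: int = 360,
    n_sweeps: int = 1,
) -> EmbeddedNetwork:
    """Maximum-likelihood angular refinement (HM stage).

    Visits nodes in decreasing degree order (ties by node id) and moves each
    node's angle to the best of ``n_candidates`` grid angles spanning
    ``window`` around the incumbent, plus the incumbent itself, scoring the
    node's full adjacency row.  Radii are left untouched.  The total
    log-likelihood after each sweep is appended to ``loglik_trace`` and is
    non-decreasing.
    """
    if temp is None:
        temp = embedded.params.temp
    if temp <= 0:
        raise ValueError("HM refinement requires T > 0")
    if not 0 < window <= TWO_PI + 1e-12:
        raise ValueError(f"window must lie in (0, 2pi], got {window}")
    if n_candidates < 2:
        raise ValueError(f"need at least 2 candidate angles, got {n_candidates}")

    graph = embedded.graph
    radius = embedded.params.radius
    nodelist = sorted(graph.nodes, key=str)
    index = {node: i for i, node in enumerate(nodelist)}
    n = len(nodelist)
    r, theta = coords_to_arrays(embedded.coords, nodelist)

    adj_rows = [
        np.fromiter((index[v] for v in graph.neighbors(u)), dtype=np.intp)
        for u in nodelist
    ]
    degrees = dict(graph.degree())
    visit = sorted(range(n), key=lambda i: (-degrees[nodelist[i]], str(nodelist[i])))

    # candidate offsets span [-w/2, w/2); for w = 2pi the grid is global
    offsets = -window / 2.0 + window * np.arange(n_candidates) / n_candidates

    trace = list(embedded.loglik_trace)
    if not trace:
        coords0 = {nodelist[i]: HyperbolicPoint(r[i], theta[i]) for i in range(n)}
        trace.append(network_loglikelihood(graph, coords0, radius, temp))

    mask = np.ones(n, dtype=bool)
    for _ in range(n_sweeps):
        for i in visit:
            mask[:] = True
            mask[i] = False
            others_r = r[mask]
            others_t = theta[mask]
            edge = np.zeros(n, dtype=bool)
            edge[adj_rows[i]] = True
            edge = edge[mask]

            candidates = np.concatenate(([theta[i]], np.mod(theta[i] + offsets, TWO_PI)))
            d = distances_from_point(
                r[i], candidates[:, None], others_r[None, :], others_t[None, :]
            )
            p = connection_probability(d, radius, temp)
            ll = np.where(edge[None, :], np.log(p), np.log1p(-p)).sum(axis=1)
            theta[i] = candidates[int(np.argmax(ll))]  # first max keeps incumbent

        coords_sweep = {nodelist[j]: HyperbolicPoint(r[j], theta[j]) for j in range(n)}
        total = network_loglikelihood(graph, coords_sweep, radius, temp)
        if total < trace[-1] - 1e-6:
            raise AssertionError("HM sweep decreased the log-likelihood")
        trace.append(total)

    coords = {nodelist[i]: HyperbolicPoint(r[i], theta[i]) for i in range(n)}
    return EmbeddedNetwork(graph, coords, embedded.params, trace)


def embed_labne_hm(
    graph: nx.Graph,
    gamma: float = 2.97,
    temp: float = 0.83,
    window: float = TWO_PI,
    m: int | None = None,
    n_candidates: int = 360,
    n_sweeps: int = 1,
) -> EmbeddedNetwork:
    """Full LaBNE + HM embedding: spectral layout then ML angular refinement."""
    return hm_refine(
        labne(graph, gamma=gamma, temp=temp, m=m),
        temp=temp,
        window=window,
        n_candidates=n_candidates,
        n_sweeps=n_sweeps,
    )
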