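"""Hyperbolic-plane mathematics for the popularity-similarity (PS) model.

Nodes of a PS network live in the two-dimensional hyperbolic plane H^2
(curvature -1), described by polar coordinates (r, theta): the radial
coordinate encodes popularity (hubs sit near the origin) and the angular
coordinate encodes similarity.  Edges appear with a Fermi-Dirac probability
that decays with hyperbolic distance around a connection radius R, with a
temperature T controlling how sharp the decay is (T -> 0 gives a hard
distance cutoff and maximal clustering).

All lengths are dimensionless hyperbolic lengths; angles are radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HyperbolicPoint",
    "ModelParams",
    "angular_separation",
    "hyperbolic_distance",
    "pairwise_distance_matrix",
    "distances_from_point",
    "connection_probability",
    "radial_from_degree_rank",
    "connection_radius",
    "network_loglikelihood",
]

TWO_PI = 2.0 * math.pi

#: beyond this value of r_p + r_q the exact arccosh form is replaced by its
#: asymptotic expansion; cosh overflows near 710, and at 40 the two branches
#: agree to well below 1e-6.
ASYMPTOTIC_SWITCH = 40.0

#: Fermi-Dirac probabilities are clipped into [PROB_CLIP, 1 - PROB_CLIP]
#: before entering a log-likelihood, to avoid -inf at negligible cost.
PROB_CLIP = 1e-12


@dataclass(frozen=True)
class HyperbolicPoint:
    """A point of H^2 in polar coordinates; theta is normalized to [0, 2pi)."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.r) or self.r < 0:
            raise ValueError(f"radial coordinate must be finite and >= 0, got {self.r}")
        if not math.isfinite(self.theta):
            raise ValueError(f"angular coordinate must be finite, got {self.theta}")
        object.__setattr__(self, "theta", self.theta % TWO_PI)


@dataclass
class ModelParams:
    """PS-model parameters.

    gamma   degree exponent of the power-law degree distribution (>= 2)
    temp    temperature T of the Fermi-Dirac connection kernel (>= 0)
    window  angular refinement window w in radians (0 < w <= 2pi)
    m       links each new node brings = half the mean degree (>= 1)
    beta    popularity fading, tied to gamma by beta = 1/(gamma - 1)
    radius  connection radius R of the final network (set once known)
    """

    gamma: float = 2.97
    temp: float = 0.83
    window: float = TWO_PI
    m: int = 1
    beta: float = field(default=None)  # type: ignore[assignment]
    radius: float = float("nan")

    def __post_init__(self) -> None:
        if self.gamma < 2:
            raise ValueError(f"gamma must be >= 2, got {self.gamma}")
        if self.temp < 0:
            raise ValueError(f"temperature must be >= 0, got {self.temp}")
        if not 0 < self.window <= TWO_PI + 1e-12:
            raise ValueError(f"window must lie in (0, 2pi], got {self.window}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.beta is None:
            self.beta = 1.0 / (self.gamma - 1.0)
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")


def angular_separation(theta_p, theta_q):
    """Shortest angular distance on the circle, in [0, pi].

    Accepts scalars or numpy arrays.
    """
    diff = np.abs(np.asarray(theta_p) - np.asarray(theta_q)) % TWO_PI
    return np.pi - np.abs(np.pi - diff)


def _distance_arrays(r_p, theta_p, r_q, theta_q):
    """Vectorized hyperbolic distance with overflow-safe branching."""
    r_p = np.asarray(r_p, dtype=float)
    r_q = np.asarray(r_q, dtype=float)
    dtheta = angular_separation(theta_p, theta_q)

    large = r_p + r_q > ASYMPTOTIC_SWITCH
    # exact branch: d = arccosh(cosh r_p cosh r_q - sinh r_p sinh r_q cos dtheta)
    rp_safe = np.where(large, 0.0, r_p)
    rq_safe = np.where(large, 0.0, r_q)
    arg = (
        np.cosh(rp_safe) * np.cosh(rq_safe)
        - np.sinh(rp_safe) * np.sinh(rq_safe) * np.cos(dtheta)
    )
    exact = np.arccosh(np.maximum(arg, 1.0))

    # asymptotic branch: d ~ r_p + r_q + 2 ln sin(dtheta / 2), floored at the
    # radial-geodesic bound |r_p - r_q| (the floor also covers dtheta -> 0).
    with np.errstate(divide="ignore"):
        log_sin = np.log(np.sin(dtheta / 2.0))
    asym = np.maximum(r_p + r_q + 2.0 * log_sin, np.abs(r_p - r_q))

    return np.where(large, asym, exact)


def hyperbolic_distance(p: HyperbolicPoint, q: HyperbolicPoint) -> float:
    """Hyperbolic distance between two points of H^2 (curvature -1)."""
    return float(_distance_arrays(p.r, p.theta, q.r, q.theta))


def pairwise_distance_matrix(r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Full N x N hyperbolic distance matrix (zero diagonal)."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    d = _distance_arrays(r[:, None], theta[:, None], r[None, :], theta[None, :])
    np.fill_diagonal(d, 0.0)
    return d


def distances_from_point(r0, theta0, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Distances from one (or a column of) point(s) to an array of points."""
    return _distance_arrays(r0, theta0, r, theta)


def connection_probability(x, radius: float, temp: float):
    """Fermi-Dirac connection probability p(x) = 1 / (1 + exp((x - R)/(2T))).

    For T = 0 the kernel degenerates to the step function 1{x <= R}.  For
    T > 0 the result is clipped into [1e-12, 1 - 1e-12] so it can enter a
    log-likelihood directly.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if temp < 0:
        raise ValueError(f"temperature must be >= 0, got {temp}")
    if temp == 0:
        p = np.where(x <= radius, 1.0, 0.0)
    else:
        # exp argument clipped to keep exp() finite; the probability clip
        # below dominates anyway.
        z = np.clip((x - radius) / (2.0 * temp), -700, 700)
        p = np.clip(1.0 / (1.0 + np.exp(z)), PROB_CLIP, 1.0 - PROB_CLIP)
    return p if p.ndim else float(p)


def radial_from_degree_rank(degrees: dict, beta: float, n_nodes: int | None = None) -> dict:
    """Assign radii by degree rank: r_i = 2 beta ln(i) + 2 (1 - beta) ln(N).

    Nodes are ranked 1..N by decreasing degree, ties broken by lexicographic
    node id, so hubs receive the smallest radii.  Returns node -> r.
    """
    if not 0 < beta <= 1:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    n = len(degrees) if n_nodes is None else n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes to rank")
    order = sorted(degrees, key=lambda v: (-degrees[v], str(v)))
    log_n = math.log(n)
    return {
        node: 2.0 * beta * math.log(i) + 2.0 * (1.0 - beta) * log_n
        for i, node in enumerate(order, start=1)
    }


def connection_radius(n_nodes: int, m: float, beta: float, temp: float) -> float:
    """PS-model connection radius for a network of n_nodes nodes.

    R = 2 ln N - 2 ln( (2T / sin(pi T)) * (1 - N^-(1-beta)) / (m (1 - beta)) )

    with the T -> 0 limit 2T/sin(pi T) -> 2/pi and the beta -> 1 limit
    (1 - N^-(1-beta))/(1-beta) -> ln N.
    """
    if temp >= 1:
        raise ValueError(f"temperature must be < 1 (kernel undefined), got {temp}")
    if temp < 0:
        raise ValueError(f"temperature must be >= 0, got {temp}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    factor = 2.0 / math.pi if temp == 0 else 2.0 * temp / math.sin(temp * math.pi)
    if beta >= 1.0 - 1e-12:
        shape = math.log(n_nodes)
    else:
        shape = (1.0 - n_nodes ** (-(1.0 - beta))) / (1.0 - beta)
    return 2.0 * math.log(n_nodes) - 2.0 * math.log(factor * shape / m)


def coords_to_arrays(coords: dict, nodelist):
    """Split a node -> HyperbolicPoint map into (r, theta) arrays over nodelist."""
    r = np.empty(len(nodelist))
    theta = np.empty(len(nodelist))
    for i, node in enumerate(nodelist):
        try:
            pt = coords[node]
        except KeyError:
            raise KeyError(f"node {node!r} has no coordinate") from None
        r[i] = pt.r
        theta[i] = pt.theta
    return r, theta


def network_loglikelihood(graph, coords: dict, radius: float, temp: float) -> float:
    """Bernoulli log-likelihood of a graph under the Fermi-Dirac kernel.

    L = sum_{i<j} a_ij ln p(x_ij) + (1 - a_ij) ln(1 - p(x_ij)), with
    probabilities clipped away from {0, 1}.  Deterministic given inputs.
    """
    if temp <= 0:
        raise ValueError("network_loglikelihood requires T > 0")
    nodelist = sorted(graph.nodes, key=str)
    r, theta = coords_to_arrays(coords, nodelist)
    index = {node: i for i, node in enumerate(nodelist)}

    d = pairwise_distance_matrix(r, theta)
    p = connection_probability(d, radius, temp)

    n = len(nodelist)
    iu = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in graph.edges:
        adj[index[u], index[v]] = True
        adj[index[v], index[u]] = True
    a = adj[iu]
    pu = p[iu]
    return float(np.sum(np.where(a, np.log(pu), np.log1p(-pu))))
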