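"""Generators for synthetic inputs with known ground truth.

Every downstream stage of the analysis is exercised on data produced here:

- PS-model networks grown in the hyperbolic plane, returned together with
  their final-time polar coordinates (ground truth for embedding recovery);
- gene-set collections with terms planted on contiguous angular blocks
  (ground truth for per-sector enrichment);
- transcript sets with PWM-sampled motif words written at recorded offsets
  (ground truth for log-odds scanning);
- differential-enrichment tables with a planted fraction of shifted genes
  (ground truth for enriched-gene selection).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import (
    TWO_PI,
    HyperbolicPoint,
    connection_probability,
    connection_radius,
    distances_from_point,
)
from .net_io import RNA_ALPHABET, PWM, GeneSet

__all__ = [
    "PSGroundTruth",
    "generate_ps_network",
    "fit_tail_exponent",
    "generate_sector_gene_sets",
    "generate_planted_motif_sequences",
    "generate_de_table",
]


@dataclass
class PSGroundTruth:
    """Final-time coordinates and parameters of a grown PS network."""

    coords: dict
    n: int
    m: int
    gamma: float
    temp: float
    beta: float
    seed: int
    birth_order: list


def _node_name(t: int) -> str:
    return f"g{t:05d}"


def generate_ps_network(
    n: int, m: int, gamma: float, temp: float, seed: int
) -> tuple[nx.Graph, PSGroundTruth]:
    """Grow a popularity-similarity network of ``n`` nodes in H^2.

    Node t (t = 1..n) appears at angle theta_t ~ U[0, 2pi) and birth radius
    r_t = 2 ln t; every earlier node s fades outward to
    r_s(t) = beta r_s + (1 - beta) r_t with beta = 1/(gamma - 1).  The first
    m + 1 nodes form a clique; each later node connects to m earlier nodes —
    the m hyperbolically nearest when T = 0, otherwise m draws without
    replacement weighted by the Fermi-Dirac probability at the running
    connection radius R_t.  Returns the final graph and the final-time
    coordinates.
    """
    if not n > m >= 1:
        raise ValueError(f"need n > m >= 1, got n={n}, m={m}")
    if gamma < 2:
        raise ValueError(f"gamma must be >= 2, got {gamma}")
    if temp < 0:
        raise ValueError(f"temperature must be >= 0, got {temp}")
    if temp >= 1:
        raise ValueError(f"temperature must be < 1, got {temp}")

    rng = np.random.default_rng(seed)
    beta = 1.0 / (gamma - 1.0)
    thetas = rng.uniform(0.0, TWO_PI, size=n)  # thetas[t-1] for node t
    birth_r = 2.0 * np.log(np.arange(1, n + 1))

    g = nx.Graph()
    names = [_node_name(t) for t in range(1, n + 1)]
    g.add_node(names[0])
    for t in range(2, n + 1):
        i = t - 1
        g.add_node(names[i])
        # radii of earlier nodes at time t (popularity fading)
        r_now = beta * birth_r[:i] + (1.0 - beta) * birth_r[i]
        if t <= m + 1:
            targets = np.arange(i)
        else:
            d = distances_from_point(birth_r[i], thetas[i], r_now, thetas[:i])
            if temp == 0:
                order = np.lexsort((np.arange(i), d))  # stable: birth order ties
                targets = order[:m]
            else:
                radius_t = connection_radius(t, m, beta, temp)
                weights = np.asarray(
                    connection_probability(d, radius_t, temp), dtype=float
                )
                targets = _weighted_sample_without_replacement(weights, m, rng)
        for s in targets:
            g.add_edge(names[i], names[int(s)])

    assert nx.is_connected(g)  # structural: every node attaches to an earlier one
    final_r = beta * birth_r + (1.0 - beta) * birth_r[-1]
    coords = {
        names[i]: HyperbolicPoint(float(final_r[i]), float(thetas[i]))
        for i in range(n)
    }
    truth = PSGroundTruth(
        coords=coords, n=n, m=m, gamma=gamma, temp=temp, beta=beta, seed=seed,
        birth_order=list(names),
    )
    return g, truth


def _weighted_sample_without_replacement(
    weights: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sequential probability-weighted draws without replacement."""
    weights = weights.astype(float).copy()
    chosen = []
    for _ in range(min(size, len(weights))):
        total = weights.sum()
        if total <= 0:
            remaining = np.flatnonzero(weights >= 0)
            remaining = np.setdiff1d(remaining, chosen)
            pick = int(rng.choice(remaining))
        else:
            pick = int(rng.choice(len(weights), p=weights / total))
        chosen.append(pick)
        weights[pick] = 0.0
    return np.array(chosen, dtype=np.intp)


def fit_tail_exponent(degrees, k_min: int | None = None) -> float:
    """Maximum-likelihood power-law tail exponent of a degree sequence.

    Continuous-approximation MLE alpha = 1 + n / sum ln(k / (k_min - 1/2)).
    When ``k_min`` is omitted it is chosen by minimizing the
    Kolmogorov-Smirnov distance between the empirical tail and the fitted
    power law over candidate cutoffs.
    """
    k = np.sort(np.asarray(list(degrees), dtype=float))
    if k_min is not None:
        return _tail_mle(k[k >= k_min], k_min)
    candidates = np.unique(k)
    candidates = candidates[candidates >= max(2, candidates.min())]
    # cap candidates so the tail keeps enough mass to fit
    candidates = [c for c in candidates if (k >= c).sum() >= 25]
    best = (math.inf, math.nan)
    for c in candidates:
        tail = k[k >= c]
        alpha = _tail_mle(tail, c)
        # KS distance between empirical tail CDF and the fitted Pareto CDF
        xs = np.sort(tail)
        emp = np.arange(1, len(xs) + 1) / len(xs)
        model = 1.0 - (xs / (c - 0.5)) ** (1.0 - alpha)
        ks = np.max(np.abs(emp - model))
        if ks < best[0]:
            best = (ks, alpha)
    return best[1]


def _tail_mle(tail: np.ndarray, k_min: float) -> float:
    if len(tail) == 0:
        raise ValueError("no degrees at or above k_min")
    return 1.0 + len(tail) / np.sum(np.log(tail / (k_min - 0.5)))


def generate_sector_gene_sets(
    ground_truth: PSGroundTruth,
    n_terms: int,
    enriched_fraction: float = 0.2,
    seed: int = 0,
    noise_rate: float = 0.0,
    random_set_size: tuple[int, int] = (10, 50),
) -> tuple[dict[str, GeneSet], dict[str, frozenset]]:
    """Gene-set collection with terms planted on contiguous angular blocks.

    A fraction ``enriched_fraction`` of the ``n_terms`` terms are planted:
    the circle is split into that many equal arcs and each planted term's
    membership is the nodes of one arc, plus each outside node independently
    with probability ``noise_rate``.  Remaining terms are uniform random
    draws.  Returns (collection, planted) where ``planted`` maps each
    planted term id to its noise-free block.
    """
    if n_terms < 1:
        raise ValueError(f"need n_terms >= 1, got {n_terms}")
    if not 0 < enriched_fraction <= 1:
        raise ValueError(f"enriched_fraction must lie in (0, 1], got {enriched_fraction}")
    rng = np.random.default_rng(seed)
    nodes = sorted(ground_truth.coords, key=str)
    thetas = np.array([ground_truth.coords[v].theta for v in nodes])

    n_planted = max(1, int(round(n_terms * enriched_fraction)))
    edges = np.linspace(0.0, TWO_PI, n_planted + 1)
    collection: dict[str, GeneSet] = {}
    planted: dict[str, frozenset] = {}
    for b in range(n_planted):
        in_block = (thetas >= edges[b]) & (thetas < edges[b + 1])
        block = [nodes[i] for i in np.flatnonzero(in_block)]
        if not block:  # arcs can be empty at tiny n; steal the nearest node
            centre = (edges[b] + edges[b + 1]) / 2.0
            block = [nodes[int(np.argmin(np.abs(thetas - centre)))]]
        members = set(block)
        if noise_rate > 0:
            outside = [v for v in nodes if v not in members]
            keep = rng.random(len(outside)) < noise_rate
            members.update(v for v, k in zip(outside, keep) if k)
        term = f"planted_{b + 1:03d}"
        collection[term] = GeneSet(term, f"planted block {b + 1}", frozenset(members))
        planted[term] = frozenset(block)
    lo, hi = random_set_size
    for u in range(n_terms - n_planted):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(nodes), size=min(size, len(nodes)), replace=False)
        term = f"random_{u + 1:03d}"
        collection[term] = GeneSet(
            term, f"uniform draw {u + 1}", frozenset(nodes[i] for i in members)
        )
    return collection, planted


def generate_planted_motif_sequences(
    n_seqs: int,
    length: int,
    pwm: PWM,
    plant_rate: float,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, int, str]]]:
    """Random transcripts with PWM-sampled words planted at recorded offsets.

    Background bases are i.i.d. uniform over {A, C, G, U} (matching the
    scanner's default background).  Each sequence is planted independently
    with probability ``plant_rate``; a planted sequence receives one word
    sampled column-wise from the PWM at a uniform random offset.  Returns
    (records, plant_log) with plant_log entries (seq_id, offset, word).
    """
    if length < pwm.width:
        raise ValueError(f"length {length} shorter than PWM width {pwm.width}")
    if not 0 <= plant_rate <= 1:
        raise ValueError(f"plant_rate must lie in [0, 1], got {plant_rate}")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(RNA_ALPHABET))
    records = []
    plant_log = []
    for s in range(n_seqs):
        seq = alphabet[rng.integers(0, 4, size=length)]
        name = f"seq{s + 1:04d}"
        if rng.random() < plant_rate:
            offset = int(rng.integers(0, length - pwm.width + 1))
            word = "".join(
                alphabet[rng.choice(4, p=row)] for row in pwm.probs
            )
            seq[offset : offset + pwm.width] = list(word)
            plant_log.append((name, offset, word))
        records.append((name, "".join(seq)))
    return records, plant_log


def generate_de_table(
    n_genes: int,
    enriched_fraction: float,
    effect_size: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Differential-enrichment table with a planted enriched-gene fraction.

    Null genes draw log2FC ~ N(0, 1); planted genes draw
    log2FC ~ N(effect_size, 1).  p-values are two-sided z-tests of the
    log2FC against the null, adjusted by Benjamini-Hochberg.  Columns:
    gene, log2FC, p, adj_p, planted.
    """
    if not 0 <= enriched_fraction <= 1:
        raise ValueError(f"enriched_fraction must lie in [0, 1], got {enriched_fraction}")
    if effect_size <= 0:
        raise ValueError(f"effect_size must be > 0, got {effect_size}")
    rng = np.random.default_rng(seed)
    n_planted = int(round(n_genes * enriched_fraction))
    planted = np.zeros(n_genes, dtype=bool)
    if n_planted:
        planted[rng.choice(n_genes, size=n_planted, replace=False)] = True
    lfc = rng.normal(0.0, 1.0, size=n_genes)
    lfc[planted] += effect_size
    p = 2.0 * stats.norm.sf(np.abs(lfc))
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": [f"gene{i + 1:05d}" for i in range(n_genes)],
            "log2FC": lfc,
            "p": p,
            "adj_p": adj_p,
            "planted": planted,
        }
    )
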