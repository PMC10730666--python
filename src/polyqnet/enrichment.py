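"""Per-sector over-representation analysis (hypergeometric ORA).

Each angular sector is tested against every gene set it overlaps: with a
universe of N genes of which K belong to the term and a sector of n genes of
which k belong to the term, the upper-tail probability P(X >= k) under
X ~ Hypergeometric(N, K, n) measures over-representation.  Benjamini-
Hochberg correction is applied across terms within each sector (the
analysis reports terms per cluster, so the correction is per-cluster too).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper_tail", "enrich_sectors"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    N is the universe size, K the term size, n the sample (sector) size and
    k the observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    log_terms = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich_sectors(
    partition,
    gene_sets: dict,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric ORA of every sector against every overlapping term.

    ``partition`` is a SectorPartition, ``gene_sets`` a term_id -> GeneSet
    map, ``universe`` the background gene collection (must cover all sector
    members).  Terms with zero overlap with a sector are not tested for it.
    Within each sector, raw p-values are BH-adjusted across its tested
    terms; rows are flagged significant when p < alpha.  The result is
    sorted by (sector_id, p) with columns sector_id, term, term_name, k, K,
    n, N, p, q, significant.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    members_all = [m for s in partition.sectors for m in s.members]
    missing = set(members_all) - universe
    if missing:
        raise ValueError(
            f"{len(missing)} sector member(s) missing from the universe, "
            f"e.g. {sorted(map(str, missing))[:5]}"
        )
    N = len(universe)
    term_members = {
        term: gene_sets[term].genes & universe for term in gene_sets
    }

    rows = []
    for sector in partition.sectors:
        sector_genes = set(sector.members)
        n = len(sector_genes)
        tested = []
        for term in gene_sets:
            K_genes = term_members[term]
            k = len(K_genes & sector_genes)
            if k == 0:
                continue
            p = hypergeom_upper_tail(k, len(K_genes), n, N)
            tested.append((term, k, len(K_genes), p))
        if not tested:
            continue
        q = multipletests([t[3] for t in tested], method="fdr_bh")[1]
        for (term, k, K, p), q_val in zip(tested, q):
            rows.append(
                {
                    "sector_id": sector.sector_id,
                    "term": term,
                    "term_name": gene_sets[term].name,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": p,
                    "q": q_val,
                    "significant": p < alpha,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "sector_id", "term", "term_name", "k", "K", "n", "N", "p", "q",
            "significant",
        ],
    )
    if not df.empty:
        df = df.sort_values(["sector_id", "p", "term"], kind="stable").reset_index(drop=True)
    return df
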