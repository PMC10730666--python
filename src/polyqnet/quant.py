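"""Tabular assay quantifications.

Small, fully specified computations applied to tabular data: selection of
enriched genes from a differential-enrichment table, relative expression
from qPCR cycle thresholds by the 2^-dCt method (target normalized to a
housekeeping gene), generic reporter signal ratios (Firefly/Renilla,
BisANS signal/background, cytoplasmic/total), and a two-group Welch t-test
summarised as mean +/- SD per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_enriched",
    "relative_expression",
    "signal_ratio",
    "GroupComparison",
    "compare_groups",
]


def filter_enriched(
    records: pd.DataFrame,
    p_max: float = 0.05,
    lfc_min: float = 0.0,
    use_adjusted: bool = False,
) -> list[str]:
    """Genes with (adjusted) p < p_max and log2FC > lfc_min, in input order.

    ``records`` needs columns ``gene``, ``log2FC`` and ``p`` (plus ``adj_p``
    when ``use_adjusted`` is set).
    """
    if not 0 < p_max <= 1:
        raise ValueError(f"p_max must lie in (0, 1], got {p_max}")
    p_col = "adj_p" if use_adjusted else "p"
    for col in ("gene", "log2FC", p_col):
        if col not in records.columns:
            raise ValueError(f"DE table is missing required column {col!r}")
    keep = (records[p_col] < p_max) & (records["log2FC"] > lfc_min)
    return records.loc[keep, "gene"].tolist()


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-(dCt) relative expression with dCt = Ct_target - Ct_reference."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))


def signal_ratio(numerator: float, denominator: float) -> float:
    """Plain signal ratio; the denominator must be positive."""
    if denominator <= 0:
        raise ValueError(f"denominator must be > 0, got {denominator}")
    return numerator / denominator


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison: per-group mean +/- SD, t and p."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float


def compare_groups(a, b) -> GroupComparison:
    """Two-sided Welch t-test between two replicate groups.

    SDs are sample standard deviations (ddof = 1).  Each group needs at
    least two values.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicate values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        p=float(p),
    )
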