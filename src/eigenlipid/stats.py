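"""Shared effect-size and testing toolkit.

Cliff's Delta and Cohen's d are implemented here (vectorized but matching
their textbook definitions exactly); rank tests and multiple-testing
correction delegate to scipy and statsmodels. Mann-Whitney U uses the exact
null for small, tie-free samples and the tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: combined sample size at or below which the exact Mann-Whitney null is used
EXACT_MWU_LIMIT = 12


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's Delta: P(x > y) − P(x < y) over all cross pairs, in [−1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires non-empty samples")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with pooled SD; sign convention mean(x) − mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("cohens_d requires ≥ 2 observations per group")
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U statistic and p-value.

    Exact enumeration null for n+m ≤ 12 without ties, tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size + y.size <= EXACT_MWU_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    mask = np.isfinite(p)
    out = np.full(p.shape, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass
class EnrichmentResult:
    """One contrast: effect size, raw and FDR-adjusted p."""

    unit: str  # e.g. the EL or lipid class
    group: str  # province, depth pair or layer contrast
    effect_size: float
    effect_name: str  # "cliffs_delta" or "cohens_d"
    p_value: float
    p_adjusted: Optional[float] = None
    test: str = ""
    sidedness: str = "two-sided"
    note: str = ""
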