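"""Shared statistical primitives: rank tests, Fisher's exact test, BH-FDR, CPM.

The two-group comparisons throughout the pipeline are distribution-free:
single-oocyte group sizes are small (here ~6-12 cells per genotype), so the
Mann-Whitney U (Wilcoxon rank-sum) test is used with its exact null
distribution whenever the data are tie-free and both groups are small, and
the tie-corrected normal approximation otherwise. Multiple testing is
controlled per analysis family with Benjamini-Hochberg.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["mann_whitney_p", "fisher_test", "bh_adjust", "cpm", "log2_ratio"]

EXACT_MAX_N = 12


def mann_whitney_p(x, y, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Mann-Whitney p-value for two independent samples.

    Exact when both samples have at most ``exact_max_n`` observations and the
    pooled data contain no ties (the exact null distribution assumes
    continuity); otherwise the normal approximation with midranks and
    tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return math.nan
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0   # no information against the null; variance degenerates
    ties = np.unique(pooled).size < pooled.size
    if not ties and max(x.size, y.size) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p). A degenerate margin (an all-zero row or column)
    makes the odds ratio undefined (NaN) with p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return math.nan, 1.0
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    mask = np.isfinite(p)
    out = np.full(p.shape, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def cpm(counts: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """Counts-per-million columns, normalized by per-cell total mapped reads."""
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("per-cell totals must be positive")
    return counts / totals * 1e6


def log2_ratio(mean_b: float, mean_a: float, pseudocount: float) -> float:
    """log2((mean_b + pc) / (mean_a + pc)); pc guards against zero means."""
    return math.log2((mean_b + pseudocount) / (mean_a + pseudocount))
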