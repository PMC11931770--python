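"""Temporal and comparative statistics for modification-level time series.

Taylor's power law, V = a*m^b, relates the temporal variance V of a
community member's abundance to its mean m; for human gut microbiomes b
typically falls between 1.5 and 2.  Because each PT dinucleotide class tags
a subset of the community, its level time course should obey the same
scaling — fitting ln V = ln a + b ln m across classes tests whether PT
fluctuations are ordinary community dynamics rather than modulation of PT
density within genomes.

Group comparisons (e.g. male vs female fecal levels, which fail normality
tests) use the Mann-Whitney U test with mid-ranks for ties, reported as
min(U1, U2), with Benjamini-Hochberg adjustment across dinucleotides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TaylorFit:
    slope_b: float
    intercept_ln_a: float
    a: float
    r_squared: float
    n_species: int
    mean_variance_pairs: pd.DataFrame  # columns: species, m, V


def taylor_fit(matrix) -> TaylorFit:
    """OLS fit of ln(V) on ln(m) across species.

    ``matrix`` is a TimeSeriesMatrix or a species-by-timepoint DataFrame.
    Per species, m is the sample mean and V the sample variance (n-1
    denominator) over timepoints; species with m = 0 or V = 0 are excluded
    (log transform undefined) and logged.  Requires >= 3 usable species.
    """
    frame = matrix.frame if hasattr(matrix, "frame") else pd.DataFrame(matrix)
    if frame.shape[1] < 3:
        raise ValueError("need >= 3 timepoints per species")
    m = frame.mean(axis=1)
    v = frame.var(axis=1, ddof=1)
    usable = (m > 0) & (v > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("excluded %d species with zero mean or zero variance", n_dropped)
    m, v = m[usable], v[usable]
    if len(m) < 3:
        raise ValueError("need >= 3 species with positive mean and variance")
    ln_m, ln_v = np.log(m.values), np.log(v.values)
    if np.allclose(ln_m, ln_m[0]):
        raise ValueError("zero variance in ln(m): species means are identical")
    res = stats.linregress(ln_m, ln_v)
    pairs = pd.DataFrame({"species": m.index, "m": m.values, "V": v.values})
    return TaylorFit(
        slope_b=float(res.slope),
        intercept_ln_a=float(res.intercept),
        a=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        n_species=len(m),
        mean_variance_pairs=pairs,
    )


@dataclass
class MannWhitneyResult:
    u: float          # min(U1, U2)
    u1: float
    u2: float
    mean_rank_1: float
    mean_rank_2: float
    mean_rank_difference: float
    p_value: float
    method: str
    q_value: float = float("nan")  # filled by bh_adjust over a test family


def mann_whitney_u(x, y, method: str = "auto") -> MannWhitneyResult:
    """Mann-Whitney U with mid-ranks, reported as min(U1, U2).

    ``method``: "exact" (full enumeration; valid for tie-free data),
    "normal" (asymptotic with tie and continuity correction), or "auto"
    (exact when n1 + n2 <= 20 and there are no ties, else normal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    r1 = float(ranks[:n1].sum())
    r2 = float(ranks[n1:].sum())
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = n1 * n2 - u1
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (n1 + n2 <= 20 and not has_ties) else "normal"
    if method == "exact" and has_ties:
        logger.info("ties present: falling back to normal approximation")
        method = "normal"
    scipy_method = "exact" if method == "exact" else "asymptotic"
    p = float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=scipy_method, use_continuity=True
        ).pvalue
    )
    return MannWhitneyResult(
        u=min(u1, u2),
        u1=u1,
        u2=u2,
        mean_rank_1=r1 / n1,
        mean_rank_2=r2 / n2,
        mean_rank_difference=r1 / n1 - r2 / n2,
        p_value=p,
        method=method,
    )


def u_from_mean_ranks(mean_rank_1: float, mean_rank_2: float, n1: int, n2: int) -> float:
    """Recover U = min(U1, U2) from published per-group mean ranks."""
    N = n1 + n2
    total = n1 * mean_rank_1 + n2 * mean_rank_2
    if abs(total - N * (N + 1) / 2) > 0.5:
        raise ValueError(
            f"inconsistent mean ranks: rank total {total} != N(N+1)/2 = {N * (N + 1) / 2}"
        )
    u1 = n1 * mean_rank_1 - n1 * (n1 + 1) / 2
    u2 = n2 * mean_rank_2 - n2 * (n2 + 1) / 2
    return float(min(u1, u2))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def autocorr(series, max_lag: int, include_lag0: bool = False) -> dict[int, float]:
    """Pearson autocorrelation r at lags 1..max_lag over mean-centered
    overlapping segments; a constant series is an error (zero variance)."""
    x = np.asarray(series, dtype=float)
    if len(x) <= max_lag + 2:
        raise ValueError("series length must exceed max_lag + 2")
    if np.allclose(x, x[0]):
        raise ValueError("constant series has undefined autocorrelation")
    out: dict[int, float] = {}
    if include_lag0:
        out[0] = 1.0
    for lag in range(1, max_lag + 1):
        a, b = x[:-lag], x[lag:]
        if np.allclose(a, a[0]) or np.allclose(b, b[0]):
            out[lag] = float("nan")
            continue
        out[lag] = float(np.corrcoef(a - a.mean(), b - b.mean())[0, 1])
    return out
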