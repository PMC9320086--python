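"""Statistical kernel: Mann-Whitney U, Pearson correlation, BH-FDR.

Thin, explicitly-conventioned wrappers over scipy/statsmodels:

* Mann-Whitney uses midranks for ties; the two-sided p is computed by full
  null enumeration (exact) when n1 + n2 <= 25 and the pooled sample has no
  ties, otherwise by the normal approximation with tie and continuity
  corrections.  Both group statistics U1 and U2 are kept; the reported U is
  min(U1, U2), the convention most statistical packages print.
* Pearson's r carries the two-sided p from the t transform on n-2 df.
* Benjamini-Hochberg adjusted p-values follow the step-up rule with
  monotonicity enforcement, capped at 1, input order preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["UTestResult", "mann_whitney_u", "pearson_r", "bh_fdr"]

EXACT_MAX_N = 25  # largest pooled sample for which the exact null is enumerated


@dataclass(frozen=True)
class UTestResult:
    u1: float
    u2: float
    u_reported: float
    p_two_sided: float
    method: str  # "exact" | "normal_tie_corrected"
    n1: int
    n2: int


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> UTestResult:
    """Two-sided Mann-Whitney U test of x vs y (see module docstring)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (n1 + n2 <= EXACT_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u1 = float(res.statistic)
    u2 = n1 * n2 - u1
    return UTestResult(
        u1=u1,
        u2=u2,
        u_reported=min(u1, u2),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_tie_corrected",
        n1=n1,
        n2=n2,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson's r and its two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate sample: zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj
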