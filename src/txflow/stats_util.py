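"""Shared statistical helpers: BH adjustment and rank-sum wrapper."""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values. NaNs are preserved and do
    not count toward the number of tests."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def rank_sum_one_sided(x, y, alternative: str = "greater",
                       exact_max_n: int = 25) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Uses the exact null distribution when both samples have at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections. Returns
    ``(U statistic, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = ("exact" if no_ties and len(x) <= exact_max_n
              and len(y) <= exact_max_n else "asymptotic")
    res = mannwhitneyu(x, y, alternative=alternative, method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = int(np.isfinite(p).sum())
    return np.minimum(p * m, 1.0)
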