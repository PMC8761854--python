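"""Shared statistical primitives: Spearman correlation with exact small-n
p-values, Benjamini-Hochberg adjustment and significance star levels."""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["spearman", "bh_adjust", "stars"]


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (midranks kept)."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(observed) - 1e-12))


def spearman(x, y, exact_max_n: int = 9):
    """Spearman rank correlation (Pearson on midranks) and two-sided p.

    The p-value is exact (full permutation enumeration) for n <= ``exact_max_n``
    and uses the t-approximation otherwise. Constant inputs are undefined and
    raise ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def stars(p: float) -> str:
    """Significance stars at p < 0.05 / 0.01 / 0.001 / 0.0001."""
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thresh:
            return mark
    return ""
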