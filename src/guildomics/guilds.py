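"""Co-abundance guilds: OTU filtering, SparCC correlation estimation,
hierarchical CAG clustering, per-sample CAG abundances/Z-scores and
between-group CAG tests.

SparCC estimates correlations among compositional components from log-ratio
variances t_ij = var(log x_i/x_j): assuming most pairs are uncorrelated, the
basis variances omega solve a linear system in t, and
rho_ij = (omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j)). Strongly
correlated pairs violate the sparsity assumption and are excluded iteratively.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .containers import CAGPartition, CountTable, SparccResult

__all__ = [
    "filter_otus",
    "sparcc",
    "cluster_cags",
    "cag_abundance_zscores",
    "test_cag_differences",
]


def filter_otus(
    table: CountTable, min_total: int = 1000, min_prevalence: float = 0.2
) -> CountTable:
    """Retain OTUs with cohort-wide total count >= ``min_total`` and
    prevalence (fraction of samples with a positive count) >= ``min_prevalence``.
    OTU order is preserved."""
    totals = table.data.sum(axis=0)
    prevalence = (table.data > 0).mean(axis=0)
    keep = table.otu_ids[(totals >= min_total) & (prevalence >= min_prevalence)]
    if len(keep) == 0:
        raise ValueError(
            "no OTUs pass the abundance/prevalence filter; relax min_total "
            f"(={min_total}) or min_prevalence (={min_prevalence})"
        )
    return table.subset_otus(keep)


def _logratio_variances(frac: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i/x_j)) across samples, via the covariance of logs."""
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2 * cov


def _solve_basis(t: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Solve for basis variances omega assuming t_ij ~ omega_i + omega_j on
    included pairs. ``include`` is a boolean pair mask (diagonal False)."""
    m = include.astype(float)
    a = m.copy()
    np.fill_diagonal(a, m.sum(axis=1))
    b = (t * m).sum(axis=1)
    try:
        omega = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        omega, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(omega, 1e-10, None)


def _sparcc_single(
    frac: np.ndarray, exclusion_threshold: float, exclusion_rounds: int
):
    """One SparCC estimate from a fractions matrix (samples x OTUs)."""
    p = frac.shape[1]
    t = _logratio_variances(frac)
    include = ~np.eye(p, dtype=bool)
    excluded: list[tuple[int, int]] = []
    rho = None
    for _ in range(exclusion_rounds + 1):
        omega = _solve_basis(t, include)
        denom = 2 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # find strongest still-included off-diagonal pair
        masked = np.where(include, np.abs(rho), 0.0)
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold or len(excluded) >= exclusion_rounds:
            break
        include[i, j] = include[j, i] = False
        excluded.append((min(i, j), max(i, j)))
    return rho, omega, excluded


def sparcc(
    table: CountTable,
    n_iter: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    n_bootstraps: int = 100,
    seed: int = 0,
) -> SparccResult:
    """SparCC correlation matrix with Dirichlet-resampled inner iterations
    and bootstrap pseudo p-values.

    Parameters
    ----------
    n_iter : int
        Inner iterations: fractions are resampled from Dirichlet(counts + 0.5)
        and the per-pair median correlation is taken, smoothing the
        pseudocount choice.
    exclusion_threshold, exclusion_rounds : float, int
        Pairs with |rho| above the threshold are excluded from the basis
        system, one per round.
    n_bootstraps : int
        Sample bootstraps for two-sided pseudo p-values (0 disables).
    """
    counts = table.data.to_numpy(dtype=float)
    n, p = counts.shape
    if p < 4:
        raise ValueError("SparCC needs >= 4 OTUs (basis system degenerate)")
    rng = np.random.default_rng(seed)
    pseudo = counts + 0.5

    rhos = np.empty((n_iter, p, p))
    omegas = np.empty((n_iter, p))
    excluded_sets = []
    for k in range(n_iter):
        frac = np.vstack([rng.dirichlet(pseudo[i]) for i in range(n)])
        rho_k, omega_k, excl = _sparcc_single(
            frac, exclusion_threshold, exclusion_rounds
        )
        rhos[k] = rho_k
        omegas[k] = omega_k
        excluded_sets.append(excl)
    rho = np.median(rhos, axis=0)
    np.fill_diagonal(rho, 1.0)
    omega = np.median(omegas, axis=0)

    pvals = None
    if n_bootstraps > 0:
        crossings = np.zeros((p, p))
        sign = np.sign(rho)
        for _ in range(n_bootstraps):
            idx = rng.integers(0, n, size=n)
            frac = (pseudo[idx]) / pseudo[idx].sum(axis=1, keepdims=True)
            rho_b, _, _ = _sparcc_single(frac, exclusion_threshold, exclusion_rounds)
            crossings += (np.sign(rho_b) != sign) | (rho_b == 0)
        pvals_arr = np.minimum(1.0, 2 * (crossings + 1) / (n_bootstraps + 1))
        np.fill_diagonal(pvals_arr, 0.0)
        pvals = pd.DataFrame(pvals_arr, index=table.otu_ids, columns=table.otu_ids)

    ids = table.otu_ids
    return SparccResult(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        omega=pd.Series(omega, index=ids, name="omega"),
        iterations=n_iter,
        excluded_pairs=sorted({e for s in excluded_sets for e in s}),
        converged=True,
        pvalues=pvals,
    )


def cluster_cags(
    sparcc_result: SparccResult,
    n_cags: Optional[int] = 19,
    cut_height: Optional[float] = None,
    method: str = "ward",
) -> pd.Series:
    """Hierarchical clustering of OTUs on distance 1 - rho into CAGs.

    Returns an OTU -> CAG id map (1-based ints). CAG ids are relabelled in
    order of first member appearance so the partition is input-order
    deterministic; OTUs are sorted by id before clustering so the result is
    invariant to input column order.
    """
    ids = sorted(sparcc_result.rho.index)
    rho = sparcc_result.rho.loc[ids, ids].to_numpy()
    p = len(ids)
    if n_cags is not None and n_cags > p:
        raise ValueError(f"n_cags={n_cags} exceeds number of OTUs ({p})")
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    z = linkage(squareform(dist, checks=False), method=method)
    if cut_height is not None:
        raw = fcluster(z, t=cut_height, criterion="distance")
    else:
        raw = fcluster(z, t=n_cags, criterion="maxclust")
    # relabel by order of first appearance over sorted OTU ids
    remap: dict[int, int] = {}
    labels = np.empty(p, dtype=int)
    for k, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[k] = remap[r]
    out = pd.Series(labels, index=pd.Index(ids, name="otu"), name="cag")
    return out.loc[sparcc_result.rho.index]


def cag_abundance_zscores(table: CountTable, labels: pd.Series) -> CAGPartition:
    """Per-sample CAG abundance (sum of member relative abundances) and
    per-CAG Z-score profiles across samples (population sd).

    CAGs with zero variance across samples get a flat zero Z-row and are
    listed in ``degenerate_cags``.
    """
    missing = [o for o in labels.index if o not in table.otu_ids]
    if missing:
        raise ValueError(f"partition references OTUs absent from table: {missing[:5]}")
    rel = table.relative_abundance()[labels.index]
    abundance = rel.T.groupby(labels).sum().T  # samples x cags
    abundance = abundance[sorted(abundance.columns)]
    mu = abundance.mean(axis=0)
    sd = abundance.std(axis=0, ddof=0)
    degenerate = [int(c) for c in abundance.columns[sd == 0]]
    sd_safe = sd.replace(0, 1.0)
    z = ((abundance - mu) / sd_safe).T  # cags x samples
    z.loc[degenerate] = 0.0
    return CAGPartition(
        labels=labels, abundance=abundance, zscores=z, degenerate_cags=degenerate
    )


def wilcoxon_rank_sum(x, y, exact_max_n: int = 25):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact distribution when both groups have <= ``exact_max_n``
    observations and the data are tie-free; otherwise the tie-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and not ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def test_cag_differences(
    abundance: pd.DataFrame, groups: pd.Series, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-CAG two-sided Wilcoxon rank-sum test between two sample groups.

    Direction is the sign of the median difference (group_a - group_b);
    all-tied CAGs get p = 1 and a ``degenerate`` flag.
    """
    groups = groups.loc[abundance.index]
    a_idx = groups[groups == group_a].index
    b_idx = groups[groups == group_b].index
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for cag in abundance.columns:
        xa = abundance.loc[a_idx, cag].to_numpy()
        xb = abundance.loc[b_idx, cag].to_numpy()
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            rows.append(
                {"cag": cag, "statistic": np.nan, "p": 1.0,
                 "median_diff": 0.0, "direction": "none", "degenerate": True}
            )
            continue
        stat, p = wilcoxon_rank_sum(xa, xb)
        md = float(np.median(xa) - np.median(xb))
        direction = "increased" if md > 0 else ("decreased" if md < 0 else "none")
        rows.append(
            {"cag": cag, "statistic": stat, "p": p,
             "median_diff": md, "direction": direction, "degenerate": False}
        )
    return pd.DataFrame(rows).set_index("cag")
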