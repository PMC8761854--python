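"""Community ecology: alpha diversity, unweighted UniFrac, PCoA and
permutation tests of group structure (ANOSIM, PERMANOVA).

Shannon entropy is reported in nats by default; for a community of ~300 OTUs
this puts typical gut samples in the 2.5-3.5 range. Chao1 uses the
bias-corrected estimator so it is defined when no doubletons are observed.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .containers import CountTable

__all__ = [
    "shannon",
    "chao1",
    "alpha_diversity",
    "unweighted_unifrac",
    "pcoa",
    "anosim",
    "permanova",
]


def shannon(counts_row, base: Optional[float] = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive proportions.

    Parameters
    ----------
    counts_row : array-like
        Non-negative counts for one sample.
    base : float, optional
        Logarithm base; natural log (nats) when None.
    """
    x = np.asarray(counts_row, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has undefined diversity")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts_row, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form: S_obs + F1(F1-1)/(2(F2+1)). The classical form
    S_obs + F1^2/(2 F2) is available via ``bias_corrected=False`` (undefined
    at F2=0, where it falls back to the bias-corrected value).
    """
    x = np.asarray(counts_row)
    if not np.allclose(x, np.round(x)):
        raise ValueError("Chao1 requires integer counts")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if not bias_corrected and f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), Chao1, observed richness and depth."""
    rows = {}
    for sid, row in table.data.iterrows():
        x = row.to_numpy()
        rows[sid] = {
            "shannon": shannon(x),
            "chao1": chao1(x),
            "observed": int((x > 0).sum()),
            "depth": int(x.sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def unweighted_unifrac(table: CountTable, tree: Optional[TreeNode] = None) -> DistanceMatrix:
    """Unweighted UniFrac distance matrix (presence/absence, fraction of
    unshared branch length) for all sample pairs.

    Raises a ValueError naming any OTU absent from the tree's tips.
    """
    tree = tree if tree is not None else table.tree
    if tree is None:
        raise ValueError("a rooted tree is required for UniFrac")
    tips = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:10]}")
    return beta_diversity(
        "unweighted_unifrac",
        table.data.to_numpy(),
        ids=list(table.sample_ids),
        taxa=list(table.otu_ids),
        tree=tree,
    )


def pcoa(dm: DistanceMatrix, k: int = 3):
    """Classical scaling (principal coordinates) of a distance matrix.

    Returns ``(coordinates, eigenvalues)``; negative eigenvalues are kept in
    the eigenvalue vector rather than silently dropped. If ``k`` exceeds the
    available rank, the available axes are returned with a warning.
    """
    n = dm.shape[0]
    if n == 1:
        coords = pd.DataFrame(
            np.zeros((1, 1)), index=list(dm.ids), columns=["PC1"]
        )
        return coords, pd.Series([0.0], index=["PC1"])
    d2 = dm.data ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    eigvals = pd.Series(
        w, index=[f"PC{i+1}" for i in range(n)], name="eigenvalue"
    )
    avail = int((w > 1e-10 * max(abs(w[0]), 1.0)).sum())
    if k > avail:
        warnings.warn(
            f"requested {k} axes but only {avail} available; returning {avail}"
        )
        k = avail
    coords = pd.DataFrame(
        v[:, :k] * np.sqrt(w[:k]),
        index=list(dm.ids), columns=[f"PC{i+1}" for i in range(k)],
    )
    return coords, eigvals


def _check_grouping(dm: DistanceMatrix, labels) -> np.ndarray:
    labels = np.asarray(labels)
    if len(labels) != dm.shape[0]:
        raise ValueError("labels length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >=2 groups with >=2 samples each")
    return labels


def _anosim_r(condensed_ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    r_w = condensed_ranks[within_mask].mean()
    r_b = condensed_ranks[~within_mask].mean()
    return (r_b - r_w) / (n * (n - 1) / 4.0)


def anosim(dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0):
    """ANOSIM R statistic with a seeded permutation p-value.

    R contrasts mean between- vs within-group ranks of the pairwise
    distances, scaled to [-1, 1]; p = (1 + #{R* >= R}) / (n_perm + 1).
    """
    labels = _check_grouping(dm, labels)
    from scipy.stats import rankdata
    from scipy.spatial.distance import squareform

    n = dm.shape[0]
    condensed = squareform(dm.data, checks=False)
    ranks = rankdata(condensed)
    iu = np.triu_indices(n, k=1)

    def within(perm_labels):
        return (perm_labels[iu[0]] == perm_labels[iu[1]])

    observed = _anosim_r(ranks, within(labels), n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, within(perm), n) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return observed, p


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    # Anderson's PERMANOVA pseudo-F from squared distances.
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    a = len(groups)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0):
    """PERMANOVA pseudo-F with a seeded permutation p-value."""
    labels = _check_grouping(dm, labels)
    d2 = dm.data ** 2
    observed = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return observed, p
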