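"""Metabolomics: preprocessing, PLS-DA with VIP scores and permutation
validation, co-abundance module detection (soft-threshold adjacency +
topological overlap), and hypergeometric sub-pathway enrichment.

Differential metabolites are selected by the joint rule VIP > 1 (strict) and
two-sided Wilcoxon rank-sum p < 0.05, with raw-scale fold changes; modules
are summarized per sample by their eigen-metabolite (first principal
component of the standardized member profiles).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .containers import MetaboliteTable, PLSDAModel, ModuleSet
from .guilds import wilcoxon_rank_sum
from .stats import bh_adjust

__all__ = [
    "preprocess",
    "plsda_fit",
    "select_differential_metabolites",
    "detect_modules",
    "pathway_enrichment",
]


def preprocess(table: MetaboliteTable, scaling: str = "unit") -> MetaboliteTable:
    """Half-minimum imputation, log10 transform and scaling.

    Missing values (NaN or 0) are imputed per metabolite at half the observed
    minimum; metabolites that are entirely missing or constant are dropped
    (recorded in the transform metadata). ``scaling`` is ``"unit"``
    (autoscale to mean 0, sd 1) or ``"pareto"`` (divide by sqrt(sd)).
    Re-applying to an already-processed table is an error.
    """
    if table.processed:
        raise ValueError("table is already preprocessed (transform metadata present)")
    if scaling not in ("unit", "pareto"):
        raise ValueError(f"unknown scaling {scaling!r}")
    df = table.data.replace(0, np.nan).astype(float)
    dropped_missing = [m for m in df.columns if df[m].isna().all()]
    df = df.drop(columns=dropped_missing)
    too_missing = [m for m in df.columns if df[m].isna().mean() >= 0.5]
    if too_missing:
        raise ValueError(f"metabolites with >=50% missing values: {too_missing[:5]}")
    for m in df.columns[df.isna().any()]:
        df[m] = df[m].fillna(df[m].min() / 2.0)
    logd = np.log10(df)
    sd = logd.std(axis=0, ddof=1)
    dropped_const = [m for m in logd.columns if sd[m] == 0]
    logd = logd.drop(columns=dropped_const)
    sd = sd.drop(dropped_const)
    centered = logd - logd.mean(axis=0)
    scaled = centered / sd if scaling == "unit" else centered / np.sqrt(sd)
    return MetaboliteTable(
        data=scaled,
        compartment=table.compartment,
        transform={
            "imputation": "half-minimum",
            "log": "log10",
            "scaling": scaling,
            "dropped_all_missing": dropped_missing,
            "dropped_constant": dropped_const,
        },
    )


def _one_hot(y: np.ndarray, classes) -> np.ndarray:
    return np.column_stack([(y == c).astype(float) for c in classes])


def _fit_pls(x: np.ndarray, ymat: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x, ymat)
    return pls


def _r2(pls: PLSRegression, x: np.ndarray, ymat: np.ndarray) -> float:
    resid = ymat - pls.predict(x)
    yc = ymat - ymat.mean(axis=0)
    return 1.0 - (resid ** 2).sum() / (yc ** 2).sum()


def _q2(x, y, classes, n_components, cv_folds, rng) -> float:
    """Q2 = 1 - PRESS/TSS via stratified k-fold cross-validation."""
    ymat = _one_hot(y, classes)
    counts = np.array([(y == c).sum() for c in classes])
    folds = min(cv_folds, int(counts.min()))
    if folds < 2:
        raise ValueError("a class has fewer than 2 members; cannot cross-validate")
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(2 ** 31))
    )
    press = 0.0
    for train, test in skf.split(x, y):
        ncomp = min(n_components, len(train) - 1, x.shape[1])
        pls = _fit_pls(x[train], ymat[train], ncomp)
        press += ((ymat[test] - pls.predict(x[test])) ** 2).sum()
    tss = ((ymat - ymat.mean(axis=0)) ** 2).sum()
    return 1.0 - press / tss


def plsda_fit(
    table: MetaboliteTable,
    y: pd.Series,
    n_components: int = 2,
    cv_folds: int = 7,
    n_perm: int = 999,
    seed: int = 0,
) -> PLSDAModel:
    """PLS-DA on a preprocessed table with VIP scores, cross-validated Q2 and
    label-permutation null distributions of R2/Q2.

    VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a) with SSY_a
    the Y-variance explained by component a; mean VIP^2 over metabolites is 1
    by construction.
    """
    if not table.processed:
        raise ValueError("fit PLS-DA on a preprocessed table")
    y = y.loc[table.sample_ids]
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    x = table.data.to_numpy()
    yarr = y.to_numpy()
    ymat = _one_hot(yarr, classes)
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    rng = np.random.default_rng(seed)

    pls = _fit_pls(x, ymat, n_components)
    w = pls.x_weights_                      # p x A
    t = pls.x_scores_                       # n x A
    q = pls.y_loadings_                     # m x A
    ssy = (t ** 2).sum(axis=0) * (q ** 2).sum(axis=0)
    wn = w / np.linalg.norm(w, axis=0, keepdims=True)
    p_feat = x.shape[1]
    vip = np.sqrt(p_feat * (wn ** 2 @ ssy) / ssy.sum())
    r2 = _r2(pls, x, ymat)
    q2 = _q2(x, yarr, classes, n_components, cv_folds, rng)

    perm_r2 = np.empty(n_perm)
    perm_q2 = np.empty(n_perm)
    for k in range(n_perm):
        yp = rng.permutation(yarr)
        ypmat = _one_hot(yp, classes)
        pls_p = _fit_pls(x, ypmat, n_components)
        perm_r2[k] = _r2(pls_p, x, ypmat)
        perm_q2[k] = _q2(x, yp, classes, n_components, cv_folds, rng)

    return PLSDAModel(
        weights=w, scores=t, y_loadings=q, ssy=ssy,
        vip=pd.Series(vip, index=table.metabolite_ids, name="vip"),
        r2=float(r2), q2=float(q2),
        perm_r2=perm_r2, perm_q2=perm_q2,
        n_components=n_components, classes=classes,
    )


def select_differential_metabolites(
    model: PLSDAModel,
    raw: MetaboliteTable,
    y: pd.Series,
    group_a: str,
    group_b: str,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Joint VIP/univariate selection of differential metabolites.

    A metabolite is selected iff VIP > ``vip_threshold`` (strict) and the
    two-sided Wilcoxon rank-sum p < ``p_threshold``. Fold change is the
    raw-scale ratio of group means (group_a / group_b); direction is
    ``elevated`` when the ratio exceeds 1. BH q-values are reported alongside.
    """
    y = y.loc[raw.sample_ids]
    a_idx = y[y == group_a].index
    b_idx = y[y == group_b].index
    rows = []
    for m in raw.metabolite_ids:
        if m not in model.vip.index:
            continue
        xa = raw.data.loc[a_idx, m].to_numpy(dtype=float)
        xb = raw.data.loc[b_idx, m].to_numpy(dtype=float)
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        _, p = wilcoxon_rank_sum(xa, xb)
        fc = xa.mean() / xb.mean() if xb.mean() > 0 else np.inf
        rows.append({"metabolite": m, "vip": model.vip[m], "p": p, "fold_change": fc})
    out = pd.DataFrame(rows).set_index("metabolite")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["fold_change"] > 1, "elevated", "suppressed")
    out["selected"] = (out["vip"] > vip_threshold) & (out["p"] < p_threshold)
    return out


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (WGCNA convention)."""
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    freqs, means = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            freqs.append(mask.mean())
            means.append(k[mask].mean())
    if len(freqs) < 3:
        return 0.0
    lx = np.log10(np.asarray(means))
    ly = np.log10(np.asarray(freqs))
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = ((ly - pred) ** 2).sum()
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def _tom(a: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix from an adjacency with zero diag."""
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    table: MetaboliteTable,
    beta: Optional[int] = None,
    min_module_size: int = 5,
    cut_height: Optional[float] = None,
    scale_free_target: float = 0.8,
    max_beta: int = 20,
) -> ModuleSet:
    """Co-abundance module detection: |cor|^beta adjacency, topological
    overlap, average-linkage clustering on 1-TOM with a static cut.

    ``beta`` defaults to the smallest integer power whose scale-free fit
    reaches ``scale_free_target`` among powers that keep the mean network
    connectivity >= 1 (higher powers disconnect the network and make the
    fit meaningless); if none qualifies, the best-fitting admissible power
    is used and flagged. Modules smaller than ``min_module_size`` become
    module 0 ("unassigned"); surviving modules are renumbered by decreasing
    size. The eigen-metabolite is the unit-variance first principal
    component of the module's standardized members, sign-aligned to a
    positive mean member correlation. When ``cut_height`` is None the tree
    is cut at 99% of the maximum merge height -- a scale-relative rule
    suited to 1-TOM dendrograms, where between-module dissimilarities crowd
    toward the top of the tree while the within-module height range depends
    strongly on the soft-threshold power.
    """
    if not table.processed:
        raise ValueError("detect modules on a preprocessed table")
    ids = sorted(table.metabolite_ids)
    if len(ids) < 2 * min_module_size:
        raise ValueError("too few metabolites for module detection")
    x = table.data[ids].to_numpy()
    cor = np.abs(np.corrcoef(x, rowvar=False))
    np.fill_diagonal(cor, 0.0)

    fallback = False
    if beta is None:
        fits = {}
        for b in range(1, max_beta + 1):
            k = (cor ** b).sum(axis=1)
            if b > 1 and k.mean() < 1.0:
                break
            fits[b] = _scale_free_fit(k)
            if fits[b] >= scale_free_target:
                beta = b
                break
        if beta is None:
            beta = max(fits, key=fits.get)
            fallback = True
        fit_r2 = fits[beta]
    else:
        fit_r2 = _scale_free_fit((cor ** beta).sum(axis=1))

    a = cor ** beta
    tom = _tom(a)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    z = linkage(squareform(dist, checks=False), method="average")
    if cut_height is None:
        cut_height = 0.99 * float(z[-1, 2])
    raw = fcluster(z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series(
        [remap.get(c, 0) for c in raw], index=pd.Index(ids, name="metabolite"),
        name="module",
    )

    eig = {}
    for mod in sorted(set(labels) - {0}):
        members = labels.index[labels == mod]
        sub = table.data[members].to_numpy()
        sub = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
        u, s, _ = np.linalg.svd(sub, full_matrices=False)
        pc = u[:, 0] * s[0]
        pc = pc / pc.std(ddof=1)
        if np.mean([np.corrcoef(pc, sub[:, j])[0, 1] for j in range(sub.shape[1])]) < 0:
            pc = -pc
        eig[f"M{mod}"] = pc
    eigen = pd.DataFrame(eig, index=table.sample_ids)
    return ModuleSet(
        labels=labels.loc[table.metabolite_ids],
        eigenmetabolites=eigen,
        beta=int(beta),
        scale_free_r2=float(fit_r2),
        beta_fallback=fallback,
    )


def pathway_enrichment(
    selected, annotation: pd.Series, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways in the selected set.

    ``annotation`` maps metabolite -> pathway; metabolites in the universe
    without annotation are ignored (count recorded in ``attrs``). p is the
    upper-tail hypergeometric probability of the observed overlap; rich
    factor is hits / pathway size (within the annotated universe).
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected set must be a subset of the universe")
    annotated = {m for m in universe if m in annotation.index}
    n_unannotated = len(universe) - len(annotated)
    sel = selected & annotated
    rows = []
    if sel:
        big_n = len(annotated)
        n_draw = len(sel)
        for pw, members in annotation.loc[sorted(annotated)].groupby(
            annotation.loc[sorted(annotated)]
        ).groups.items():
            k_pw = len(members)
            hits = len(set(members) & sel)
            p = float(hypergeom.sf(hits - 1, big_n, k_pw, n_draw))
            rows.append(
                {"pathway": pw, "hits": hits, "pathway_size": k_pw,
                 "selected_size": n_draw, "universe_size": big_n,
                 "p": p, "rich_factor": hits / k_pw}
            )
    out = pd.DataFrame(
        rows,
        columns=["pathway", "hits", "pathway_size", "selected_size",
                 "universe_size", "p", "rich_factor"],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.set_index("pathway")
    else:
        out["q"] = []
        out = out.set_index("pathway")
        out.attrs["note"] = "empty selected set"
    out.attrs["n_unannotated"] = n_unannotated
    return out
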