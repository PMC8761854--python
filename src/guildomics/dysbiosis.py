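"""Differential abundance (negative-binomial Wald test) and the microbial
dysbiosis index (MD-index).

The NB GLM uses a log link with a group indicator and a log size-factor
offset; dispersion is estimated per feature by Cox-Reid adjusted profile
maximum likelihood with a method-of-moments start (the adjustment removes
the small-sample downward bias of plain ML; no empirical-Bayes shrinkage
across features is applied). The MD-index is the per-sample log10 ratio of summed relative
abundance of disease-increased taxa over disease-decreased taxa.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import t as student_t

from .containers import CountTable, MDIndexResult
from .stats import bh_adjust, spearman

__all__ = [
    "size_factors",
    "nb_wald_test",
    "md_index",
    "md_severity_association",
    "arcsine_sqrt",
]


def arcsine_sqrt(relative_abundance):
    """Arcsine-square-root transform of relative abundances, the
    variance-stabilizing transform conventionally used when plotting summed
    taxon abundances against a severity grade. Monotone on [0, 1]."""
    x = np.asarray(relative_abundance, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("relative abundances must lie in [0, 1]")
    return np.arcsin(np.sqrt(x))

LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (features positive in all samples serve
    as the reference); falls back to depth scaling when no feature is
    everywhere-positive."""
    mat = counts.to_numpy(dtype=float)
    everywhere = (mat > 0).all(axis=0)
    if everywhere.any():
        ref = mat[:, everywhere]
        log_geo = np.log(ref).mean(axis=0)
        sf = np.exp(np.median(np.log(ref) - log_geo, axis=1))
    else:
        depth = mat.sum(axis=1)
        sf = depth / np.exp(np.mean(np.log(depth)))
    return pd.Series(sf, index=counts.index, name="size_factor")


def _nb_loglike(y, x, offset, alpha, cox_reid: bool = False):
    fam = sm.families.NegativeBinomial(alpha=alpha)
    model = sm.GLM(y, x, family=fam, offset=offset)
    try:
        res = model.fit(maxiter=50, tol=1e-8)
    except Exception:
        return -np.inf, None
    ll = float(res.llf)
    if cox_reid:
        # Cox-Reid adjustment: penalize for the estimated mean parameters,
        # removing the downward bias of plain ML dispersion at small n
        w = res.mu / (1.0 + alpha * res.mu)
        info = x.T @ (w[:, None] * x)
        ll -= 0.5 * float(np.linalg.slogdet(info)[1])
    return ll, res

def _fit_feature(y: np.ndarray, x: np.ndarray, offset: np.ndarray):
    """Cox-Reid adjusted profile-likelihood dispersion + NB GLM Wald
    statistics for one feature."""
    # method-of-moments start on offset-normalized counts
    z = y / np.exp(offset)
    mu, var = z.mean(), z.var(ddof=1)
    alpha0 = max((var - mu) / max(mu, 1e-8) ** 2, 1e-6) if var > mu else 1e-6

    def neg_ll(log_alpha):
        ll, _ = _nb_loglike(y, x, offset, np.exp(log_alpha), cox_reid=True)
        return -ll

    lo, hi = np.log(1e-6), np.log(100.0)
    start = np.clip(np.log(alpha0), lo, hi)
    opt = minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-3, "maxiter": 40},
    )
    log_alpha = opt.x if np.isfinite(opt.fun) else start
    _, res = _nb_loglike(y, x, offset, np.exp(log_alpha))
    if res is None:
        return None
    beta = res.params[1]
    se = res.bse[1]
    return beta, se, float(np.exp(log_alpha))


def nb_wald_test(
    table: CountTable,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    lfc_threshold: float = 1.0,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-OTU negative-binomial Wald test of group_a vs group_b.

    Returns a frame with natural-scale coefficients converted to log2 fold
    change (group_a relative to group_b), Wald z, BH q and the significance
    call ``q < fdr`` AND ``|log2fc| >= lfc_threshold``. Features with zero
    counts in both groups are skipped (listed in ``df.attrs['skipped']``).
    """
    groups = groups.loc[table.sample_ids]
    keep = groups.isin([group_a, group_b])
    sub = table.data.loc[keep[keep].index]
    g = (groups[keep] == group_a).astype(float).to_numpy()
    sf = size_factors(sub)
    offset = np.log(sf.to_numpy())
    x = np.column_stack([np.ones_like(g), g])

    rows, skipped = [], []
    for otu in sub.columns:
        y = sub[otu].to_numpy(dtype=float)
        if y.sum() == 0:
            skipped.append(otu)
            continue
        fit = _fit_feature(y, x, offset)
        if fit is None:
            skipped.append(otu)
            continue
        beta, se, alpha = fit
        z = beta / se if se > 0 else np.nan
        # t reference with residual df: less anticonservative than the
        # normal reference at these group sizes
        p = 2 * student_t.sf(abs(z), df=max(len(y) - 2, 1)) if np.isfinite(z) else 1.0
        rows.append(
            {"feature": otu, "log2fc": beta / LN2, "se": se / LN2,
             "wald_z": z, "p": p, "dispersion": alpha}
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["log2fc"] > 0, "increased", "decreased")
    out.loc[out["log2fc"] == 0, "direction"] = "none"
    out["significant"] = (out["q"] < fdr) & (out["log2fc"].abs() >= lfc_threshold)
    out.attrs["skipped"] = skipped
    out.attrs["comparison"] = f"{group_a}_vs_{group_b}"
    return out


def md_index(
    table: CountTable,
    increased: Sequence[str],
    decreased: Sequence[str],
    epsilon: float = 1e-6,
) -> MDIndexResult:
    """Per-sample MD-index: log10 of summed relative abundance of
    disease-increased taxa over disease-decreased taxa (epsilon-guarded)."""
    increased = list(increased)
    decreased = list(decreased)
    if not increased or not decreased:
        raise ValueError("both taxa sets must be non-empty")
    overlap = set(increased) & set(decreased)
    if overlap:
        raise ValueError(f"taxa in both sets: {sorted(overlap)[:5]}")
    missing = [o for o in increased + decreased if o not in table.otu_ids]
    if missing:
        raise ValueError(f"taxa absent from table: {missing[:5]}")
    rel = table.relative_abundance()
    num = rel[increased].sum(axis=1) + epsilon
    den = rel[decreased].sum(axis=1) + epsilon
    idx = np.log10(num / den)
    idx.name = "md_index"
    return MDIndexResult(
        index=idx, increased=increased, decreased=decreased, epsilon=epsilon
    )


def md_severity_association(
    md: MDIndexResult,
    mrs_scores: pd.Series,
    richness: pd.Series,
):
    """Spearman correlations of the MD-index with disease severity (mRS) and
    with observed species richness, over the provided (patient) samples.

    Returns ``{'mrs': (rho, p) or None, 'richness': (rho, p) or None}``;
    a constant covariate yields None (undefined, flagged)."""
    common = md.index.index.intersection(mrs_scores.index).intersection(richness.index)
    vals = md.index.loc[common]
    out = {}
    for name, cov in (("mrs", mrs_scores.loc[common]), ("richness", richness.loc[common])):
        try:
            out[name] = spearman(vals.to_numpy(), cov.to_numpy(dtype=float))
        except ValueError:
            out[name] = None
    return out
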