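"""Cross-omic integration: cytokine group tests, genus-cytokine Spearman
heatmaps and the FDR-controlled correlation network linking CAG abundances,
fecal/serum eigen-metabolites and cytokines.

Benjamini-Hochberg correction is applied within each pair family (e.g.
CAG x serum modules) by default, matching family-wise reporting; a pooled
mode is available.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, spearman, stars

__all__ = [
    "cytokine_group_tests",
    "spearman",
    "genus_cytokine_heatmap",
    "build_integration_network",
    "network_to_graph",
]


def cytokine_group_tests(
    cytokines: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-cytokine Welch two-sided t-test between two groups.

    Concentrations are log10-transformed by default (right-skewed assay
    data); zeros get half the smallest positive value before the log.
    Zero-variance cytokines are flagged with p = NaN.
    """
    groups = groups.loc[cytokines.index]
    a_idx = groups[groups == group_a].index
    b_idx = groups[groups == group_b].index
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs >= 2 samples")
    data = cytokines.astype(float)
    if log_transform:
        pos_min = data[data > 0].min().min()
        data = np.log10(data.where(data > 0, pos_min / 2.0))
    rows = []
    for c in data.columns:
        xa = data.loc[a_idx, c].to_numpy()
        xb = data.loc[b_idx, c].to_numpy()
        if np.all(xa == xa[0]) and np.all(xb == xb[0]):
            rows.append({"cytokine": c, "t": np.nan, "p": np.nan,
                         "direction": "none", "degenerate": True})
            continue
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        diff = xa.mean() - xb.mean()
        rows.append({"cytokine": c, "t": float(t), "p": float(p),
                     "direction": "higher" if diff > 0 else "lower",
                     "degenerate": False})
    return pd.DataFrame(rows).set_index("cytokine")


def genus_cytokine_heatmap(
    genus_abundances: pd.DataFrame,
    cytokines: pd.DataFrame,
    top_n: int = 30,
):
    """All-pairs Spearman correlation between (up to ``top_n``) genera and
    cytokines on the shared samples.

    Returns ``(rho, p, star)`` DataFrames (genera x cytokines); stars mark
    p < 0.05 / 0.01 / 0.001 / 0.0001.
    """
    common = genus_abundances.index.intersection(cytokines.index)
    ga = genus_abundances.loc[common].iloc[:, :top_n]
    cy = cytokines.loc[common]
    rho = pd.DataFrame(index=sorted(ga.columns), columns=cy.columns, dtype=float)
    pmat = rho.copy()
    for g in rho.index:
        for c in rho.columns:
            try:
                r, p = spearman(ga[g].to_numpy(), cy[c].to_numpy())
            except ValueError:
                r, p = np.nan, np.nan
            rho.loc[g, c] = r
            pmat.loc[g, c] = p
    star = pmat.map(lambda p: stars(p) if np.isfinite(p) else "")
    return rho, pmat, star


def _family_edges(x: pd.DataFrame, yv: pd.DataFrame, family: str,
                  type_a: str, type_b: str) -> pd.DataFrame:
    rows = []
    for a in x.columns:
        for b in yv.columns:
            try:
                r, p = spearman(x[a].to_numpy(), yv[b].to_numpy())
            except ValueError:
                continue
            rows.append({"node_a": a, "node_b": b, "type_a": type_a,
                         "type_b": type_b, "family": family, "rho": r, "p": p})
    return pd.DataFrame(rows)


def build_integration_network(
    cag_abundance: pd.DataFrame,
    fecal_eigenmets: Optional[pd.DataFrame] = None,
    serum_eigenmets: Optional[pd.DataFrame] = None,
    cytokines: Optional[pd.DataFrame] = None,
    fdr: float = 0.05,
    include_cag_cytokine: bool = True,
    pooled_correction: bool = False,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Spearman edge list across CAG x module, module x cytokine (and
    optionally CAG x cytokine) pair families, BH-corrected at ``fdr``.

    Tables are inner-joined on samples per family (serum assays may cover a
    subset of the cohort). The returned frame carries all tested pairs with
    q-values and sign; the significant view is ``df[df.significant]``.
    """
    families = []

    def add(xa, xb, name, ta, tb):
        if xa is None or xb is None:
            return
        common = xa.index.intersection(xb.index)
        if len(common) < min_overlap:
            raise ValueError(
                f"family {name}: only {len(common)} shared samples (<{min_overlap})"
            )
        families.append(_family_edges(xa.loc[common], xb.loc[common], name, ta, tb))

    add(cag_abundance, fecal_eigenmets, "cag_fecal_module", "cag", "module")
    add(cag_abundance, serum_eigenmets, "cag_serum_module", "cag", "module")
    add(fecal_eigenmets, cytokines, "fecal_module_cytokine", "module", "cytokine")
    add(serum_eigenmets, cytokines, "serum_module_cytokine", "module", "cytokine")
    if include_cag_cytokine:
        add(cag_abundance, cytokines, "cag_cytokine", "cag", "cytokine")

    edges = pd.concat([f for f in families if len(f)], ignore_index=True)
    if pooled_correction:
        edges["q"] = bh_adjust(edges["p"].to_numpy())
    else:
        edges["q"] = np.nan
        for fam, idx in edges.groupby("family").groups.items():
            edges.loc[idx, "q"] = bh_adjust(edges.loc[idx, "p"].to_numpy())
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    edges["significant"] = edges["q"] < fdr
    return edges


def network_to_graph(edges: pd.DataFrame, significant_only: bool = True):
    """Edge list -> networkx Graph (for GraphML export / plotting)."""
    import networkx as nx

    g = nx.Graph()
    sub = edges[edges["significant"]] if significant_only else edges
    for _, row in sub.iterrows():
        g.add_node(row["node_a"], kind=row["type_a"])
        g.add_node(row["node_b"], kind=row["type_b"])
        g.add_edge(
            row["node_a"], row["node_b"],
            rho=float(row["rho"]), q=float(row["q"]),
            sign=int(row["sign"]), family=row["family"],
        )
    return g
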