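"""Reading and writing the pipeline's canonical on-disk formats.

The canonical dialect is tab-separated UTF-8 with a header row and the id in
the first column; trees are newick. Table orientation (samples as rows vs
columns) is auto-detected from id overlap when reference ids are available
and recorded in ``DataFrame.attrs['orientation']``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import ClinicalTable, CountTable, MetaboliteTable
from .simulate import Cohort

__all__ = [
    "read_table",
    "read_count_table",
    "read_metabolite_table",
    "read_clinical",
    "read_tree",
    "read_annotation",
    "write_cohort",
]


def _read_numeric_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated ids {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated column ids {dupes}")
    bad = []
    for c in df.columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().sum() > df[c].isna().sum():
            bad.append(c)
        df[c] = coerced
    if bad:
        raise ValueError(f"{path}: non-numeric cells in columns {bad[:5]}")
    return df


def _orient(df: pd.DataFrame, sample_ids=None, feature_ids=None) -> pd.DataFrame:
    """Rows-as-samples orientation, decided by id overlap when known."""
    orientation = "rows=samples (assumed)"
    if sample_ids is not None:
        sample_ids = set(sample_ids)
        if len(sample_ids & set(df.columns)) > len(sample_ids & set(df.index)):
            df = df.T
            orientation = "rows=samples (transposed on read)"
        else:
            orientation = "rows=samples (detected)"
    elif feature_ids is not None:
        feature_ids = set(feature_ids)
        if len(feature_ids & set(df.index)) > len(feature_ids & set(df.columns)):
            df = df.T
            orientation = "rows=samples (transposed on read)"
        else:
            orientation = "rows=samples (detected)"
    df.attrs["orientation"] = orientation
    return df


def read_table(path, sample_ids=None, feature_ids=None) -> pd.DataFrame:
    """Generic numeric TSV with orientation auto-detection."""
    return _orient(_read_numeric_tsv(path), sample_ids, feature_ids)


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    unnamed = sum(1 for t in tree.tips() if not t.name)
    if unnamed:
        raise ValueError(f"{path}: {unnamed} unnamed tree leaves")
    return tree


def read_count_table(
    path,
    taxonomy_path=None,
    tree_path=None,
    sample_ids=None,
) -> CountTable:
    """Counts TSV (+ optional taxonomy TSV and newick tree) -> CountTable.

    When a tree is given, any table axis matching the tree tips is treated
    as the OTU axis; orphan tree references are reported by name.
    """
    tree = read_tree(tree_path) if tree_path else None
    feature_ids = [t.name for t in tree.tips()] if tree is not None else None
    df = read_table(path, sample_ids=sample_ids, feature_ids=feature_ids)
    taxonomy = None
    if taxonomy_path:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        taxonomy = tax.iloc[:, 0]
        orphans = [o for o in df.columns if o not in taxonomy.index]
        if orphans:
            raise ValueError(f"OTUs without taxonomy: {orphans[:5]}")
        taxonomy = taxonomy.loc[df.columns]
    table = CountTable(df, taxonomy=taxonomy, tree=tree)
    table.data.attrs = df.attrs
    return table


def read_metabolite_table(path, compartment: str, sample_ids=None) -> MetaboliteTable:
    df = read_table(path, sample_ids=sample_ids)
    return MetaboliteTable(df, compartment=compartment)


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample ids {dupes}")
    return ClinicalTable(df)


def read_annotation(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write all simulated tables + ground truth to ``outdir``; returns the
    path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, sep="\t")
        paths[name] = str(p)

    save(cohort.counts.data, "counts.tsv")
    save(cohort.counts.taxonomy.to_frame(), "taxonomy.tsv")
    save(cohort.fecal.data, "fecal_metabolites.tsv")
    save(cohort.serum.data, "serum_metabolites.tsv")
    save(cohort.annotation["fecal"].to_frame(), "fecal_annotation.tsv")
    save(cohort.annotation["serum"].to_frame(), "serum_annotation.tsv")
    save(cohort.clinical.data, "clinical.tsv")
    save(cohort.cytokines, "cytokines.tsv")
    tree_path = out / "tree.nwk"
    cohort.tree.write(str(tree_path), format="newick")
    paths["tree.nwk"] = str(tree_path)

    truth = cohort.truth
    gt = {
        "otu_guild_labels": truth.otu_guild_labels.to_dict(),
        "affected_guilds": {str(k): v for k, v in truth.affected_guilds.items()},
        "module_labels": {c: s.to_dict() for c, s in truth.module_labels.items()},
        "coupled_pairs": truth.coupled_pairs,
        "disease_modules": {
            c: {str(k): v for k, v in d.items()}
            for c, d in truth.disease_modules.items()
        },
        "enriched_pathways": truth.enriched_pathways,
        "prognostic_otus": truth.prognostic_otus,
        "prognostic_effects": truth.prognostic_effects,
        "true_differential_taxa": truth.true_differential_taxa,
        "true_relapse_groups": (
            truth.true_relapse_groups.to_dict()
            if truth.true_relapse_groups is not None else None
        ),
        "elevated_cytokines": truth.elevated_cytokines,
        "serum_samples": truth.serum_samples,
    }
    gt_path = out / "ground_truth.json"
    gt_path.write_text(json.dumps(gt, indent=1, default=str))
    paths["ground_truth.json"] = str(gt_path)
    return paths
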