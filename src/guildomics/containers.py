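"""Typed containers shared across the pipeline stages.

All tabular data are pandas DataFrames oriented samples x features; the thin
dataclass wrappers below add validation and carry side information (taxonomy,
phylogeny, compartment tags, transform provenance) that plain frames lose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountTable",
    "MetaboliteTable",
    "ClinicalTable",
    "SparccResult",
    "CAGPartition",
    "MDIndexResult",
    "PLSDAModel",
    "ModuleSet",
    "ClassifierReport",
    "SurvivalReport",
]


def _check_rectangular(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {what}: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {what}: {dupes}")


@dataclass
class CountTable:
    """Samples x OTUs integer count matrix with optional taxonomy and tree.

    Parameters
    ----------
    data : DataFrame
        Non-negative integer counts; rows are samples, columns OTUs.
    taxonomy : Series, optional
        OTU id -> taxon label (typically genus).
    tree : skbio.TreeNode, optional
        Rooted phylogeny whose tips cover the OTU ids.
    """

    data: pd.DataFrame
    taxonomy: Optional[pd.Series] = None
    tree: Optional[TreeNode] = None

    def __post_init__(self) -> None:
        _check_rectangular(self.data, "count table")
        vals = self.data.to_numpy()
        if (vals < 0).any():
            raise ValueError("count table contains negative entries")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("count table contains non-integer entries")
        self.data = self.data.astype(np.int64)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.data.columns

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions (closure)."""
        depths = self.depths()
        if (depths == 0).any():
            bad = depths.index[depths == 0].tolist()
            raise ValueError(f"samples with zero total counts: {bad}")
        return self.data.div(depths, axis=0)

    def subset_otus(self, otus) -> "CountTable":
        tax = self.taxonomy.loc[otus] if self.taxonomy is not None else None
        return CountTable(self.data[list(otus)], taxonomy=tax, tree=self.tree)


@dataclass
class MetaboliteTable:
    """Samples x metabolites intensity matrix for one compartment.

    ``transform`` records the preprocessing applied (imputation, log, scaling);
    it is empty for raw intensities and non-empty after :func:`preprocess`.
    """

    data: pd.DataFrame
    compartment: str = "fecal"
    transform: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compartment not in ("fecal", "serum"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        _check_rectangular(self.data, f"{self.compartment} metabolite table")
        if not self.transform and (self.data.to_numpy() < 0).any():
            raise ValueError("raw metabolite intensities must be non-negative")

    @property
    def processed(self) -> bool:
        return bool(self.transform)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.data.columns


#: columns required in a clinical table; ``outcome6m_poor`` etc. may hold NaN
#: for controls (outcomes are defined only for patients).
CLINICAL_COLUMNS = (
    "cohort",
    "mrs_baseline",
    "mrs_6m",
    "outcome6m_poor",
    "neos",
    "age",
    "sex",
    "consciousness",
    "relapse_time",
    "relapse_event",
)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates, outcomes and relapse records."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_rectangular(self.data, "clinical table")
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        bad = set(self.data["cohort"].unique()) - {"patient", "control"}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def patients(self) -> pd.DataFrame:
        return self.data[self.data["cohort"] == "patient"]

    def severity_groups(self) -> pd.Series:
        """Three-level grouping: control / moderate (mRS<=3) / severe (mRS 4-5)."""
        grp = pd.Series("control", index=self.data.index, name="group")
        pat = self.data["cohort"] == "patient"
        grp[pat & (self.data["mrs_baseline"] <= 3)] = "moderate"
        grp[pat & (self.data["mrs_baseline"] >= 4)] = "severe"
        return grp


@dataclass
class SparccResult:
    """Compositionally robust correlation estimate over retained OTUs."""

    rho: pd.DataFrame
    omega: pd.Series
    iterations: int
    excluded_pairs: list
    converged: bool = True
    pvalues: Optional[pd.DataFrame] = None

    def edges(self, threshold: float = 0.4) -> pd.DataFrame:
        """Edge list of OTU pairs with |rho| above the display threshold."""
        rows = []
        ids = self.rho.index
        r = self.rho.to_numpy()
        p = self.pvalues.to_numpy() if self.pvalues is not None else None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if abs(r[i, j]) > threshold:
                    rows.append(
                        {
                            "otu_a": ids[i],
                            "otu_b": ids[j],
                            "rho": r[i, j],
                            "p": p[i, j] if p is not None else np.nan,
                        }
                    )
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p"])


@dataclass
class CAGPartition:
    """OTU -> co-abundance group assignment with per-sample summaries."""

    labels: pd.Series                    # OTU id -> CAG id (int, 1-based)
    abundance: pd.DataFrame              # samples x CAGs, sums of member rel. abundances
    zscores: pd.DataFrame                # CAGs x samples, row-standardized
    degenerate_cags: list = field(default_factory=list)

    @property
    def members(self) -> dict:
        return {int(c): list(idx) for c, idx in self.labels.groupby(self.labels).groups.items()}

    @property
    def n_cags(self) -> int:
        return int(self.labels.nunique())


@dataclass
class MDIndexResult:
    """Per-sample microbial dysbiosis index (log10 increased/decreased ratio)."""

    index: pd.Series
    increased: list
    decreased: list
    epsilon: float


@dataclass
class PLSDAModel:
    """Fitted PLS-DA with VIP scores and permutation validation."""

    weights: np.ndarray            # p x A x-weights
    scores: np.ndarray             # n x A
    y_loadings: np.ndarray         # A
    ssy: np.ndarray                # explained Y-variance per component
    vip: pd.Series                 # per-metabolite VIP
    r2: float
    q2: float
    perm_r2: np.ndarray
    perm_q2: np.ndarray
    n_components: int
    classes: tuple


@dataclass
class ModuleSet:
    """Metabolite co-abundance modules with eigen-metabolite summaries."""

    labels: pd.Series              # metabolite -> module id (0 = unassigned)
    eigenmetabolites: pd.DataFrame  # samples x modules (unit variance columns)
    beta: int
    scale_free_r2: float
    beta_fallback: bool = False

    @property
    def n_modules(self) -> int:
        return int((self.labels.unique() != 0).sum())


@dataclass
class ClassifierReport:
    """Cross-validated classifier summary: importances, ROC, AUC, operating point."""

    auc: float
    auc_ci: tuple
    roc_points: pd.DataFrame       # fpr, tpr, threshold
    importances: Optional[pd.Series]  # mean decrease accuracy, descending
    sensitivity: float
    specificity: float
    scheme: str
    seed: int
    scores: pd.Series              # pooled held-out scores per sample
    labels: pd.Series


@dataclass
class SurvivalReport:
    """Kaplan-Meier curves, log-rank test and Cox HR for a two-stratum split."""

    km_curves: dict                 # stratum -> DataFrame(time, survival)
    logrank_stat: float
    logrank_p: float
    log_hr: float
    hr: float
    hr_ci: tuple
    at_risk: pd.DataFrame           # strata x monthly ticks
    n_events: int
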