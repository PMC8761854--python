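"""End-to-end orchestration: ecology -> guilds -> dysbiosis -> metabolome
(fecal, serum) -> integration -> prognosis, with TSV/JSON outputs stamped
with the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import dysbiosis as dysb
from . import ecology, guilds, integration, metabolome, prognosis
from .containers import CountTable
from .io import (
    read_annotation,
    read_clinical,
    read_count_table,
    read_metabolite_table,
    write_cohort,
)
from .simulate import Cohort, CohortConfig, simulate_cohort

log = logging.getLogger("guildomics")

__all__ = ["RunConfig", "run_all", "analyze_cohort"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either ``simulate=True`` (optionally with ``cohort`` overrides) or the
    input paths must be provided.
    """

    simulate: bool = True
    cohort: dict = field(default_factory=dict)
    counts_path: Optional[str] = None
    taxonomy_path: Optional[str] = None
    tree_path: Optional[str] = None
    fecal_path: Optional[str] = None
    serum_path: Optional[str] = None
    fecal_annotation_path: Optional[str] = None
    serum_annotation_path: Optional[str] = None
    clinical_path: Optional[str] = None
    cytokines_path: Optional[str] = None
    outdir: Optional[str] = None
    seed: int = 0
    min_total: int = 1000
    min_prevalence: float = 0.2
    fdr_differential: float = 0.01
    fdr_network: float = 0.05
    lfc_threshold: float = 1.0
    vip_threshold: float = 1.0
    n_perm: int = 999
    n_cags: int = 19
    n_trees: int = 1000
    sparcc_iter: int = 20
    sparcc_bootstraps: int = 100
    stages: tuple = (
        "ecology", "guilds", "dysbiosis", "metabolome", "integration", "prognosis",
    )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig) -> Cohort:
    if config.simulate:
        cc = CohortConfig(**config.cohort) if config.cohort else CohortConfig()
        return simulate_cohort(cc)
    clinical = read_clinical(config.clinical_path)
    sample_ids = list(clinical.sample_ids)
    counts = read_count_table(
        config.counts_path, taxonomy_path=config.taxonomy_path,
        tree_path=config.tree_path, sample_ids=sample_ids,
    )
    fecal = read_metabolite_table(config.fecal_path, "fecal", sample_ids=sample_ids)
    serum = read_metabolite_table(config.serum_path, "serum", sample_ids=sample_ids)
    annotation = {
        "fecal": read_annotation(config.fecal_annotation_path),
        "serum": read_annotation(config.serum_annotation_path),
    }
    cytokines = pd.read_csv(config.cytokines_path, sep="\t", index_col=0)
    return Cohort(
        config=None, counts=counts, tree=counts.tree, truth=None,
        fecal=fecal, serum=serum, annotation=annotation,
        clinical=clinical, cytokines=cytokines,
    )


def _genus_abundances(counts: CountTable) -> pd.DataFrame:
    if counts.taxonomy is None:
        raise ValueError("taxonomy required for genus-level aggregation")
    rel = counts.relative_abundance()
    return rel.T.groupby(counts.taxonomy).sum().T


def analyze_cohort(cohort: Cohort, config: Optional[RunConfig] = None) -> dict:
    """Run every analysis stage on an in-memory cohort; returns a dict of
    stage results (rich objects) plus a JSON-serializable ``summary``."""
    config = config or RunConfig()
    res: dict = {"summary": {}}
    summary = res["summary"]
    clinical = cohort.clinical
    groups3 = clinical.severity_groups()
    cohort_groups = clinical.data["cohort"]

    if "ecology" in config.stages:
        log.info("ecology: alpha/beta diversity on %d samples", len(cohort.counts.data))
        alpha = ecology.alpha_diversity(cohort.counts)
        dm = ecology.unweighted_unifrac(cohort.counts, cohort.tree)
        coords, eigvals = ecology.pcoa(dm, k=3)
        labels = groups3.loc[list(dm.ids)].to_numpy()
        r_anosim, p_anosim = ecology.anosim(dm, labels, n_perm=config.n_perm,
                                            seed=config.seed)
        f_perm, p_perm = ecology.permanova(dm, labels, n_perm=config.n_perm,
                                           seed=config.seed)
        res["alpha"] = alpha
        res["unifrac"] = dm
        res["pcoa"] = (coords, eigvals)
        sev_idx = groups3[groups3 == "severe"].index
        ctl_idx = groups3[groups3 == "control"].index
        summary["ecology"] = {
            "anosim_R": r_anosim, "anosim_p": p_anosim,
            "permanova_F": f_perm, "permanova_p": p_perm,
            "shannon_severe_mean": float(alpha.loc[sev_idx, "shannon"].mean()),
            "shannon_control_mean": float(alpha.loc[ctl_idx, "shannon"].mean()),
            "chao1_severe_mean": float(alpha.loc[sev_idx, "chao1"].mean()),
            "chao1_control_mean": float(alpha.loc[ctl_idx, "chao1"].mean()),
        }

    filtered = guilds.filter_otus(cohort.counts, config.min_total,
                                  config.min_prevalence)
    log.info("guilds: %d -> %d OTUs after <%d total / <%.0f%% prevalence filter",
             cohort.counts.data.shape[1], filtered.data.shape[1],
             config.min_total, 100 * config.min_prevalence)
    res["filtered"] = filtered

    if "guilds" in config.stages:
        sp = guilds.sparcc(
            filtered, n_iter=config.sparcc_iter,
            n_bootstraps=config.sparcc_bootstraps, seed=config.seed,
        )
        labels = guilds.cluster_cags(sp, n_cags=min(config.n_cags,
                                                    filtered.data.shape[1]))
        partition = guilds.cag_abundance_zscores(filtered, labels)
        cag_tests = guilds.test_cag_differences(
            partition.abundance, groups3, "severe", "control"
        )
        res["sparcc"] = sp
        res["cag_labels"] = labels
        res["cags"] = partition
        res["cag_tests"] = cag_tests
        summary["guilds"] = {
            "n_retained_otus": int(filtered.data.shape[1]),
            "n_cags": int(partition.n_cags),
            "n_significant_cags": int((cag_tests["p"] < 0.05).sum()),
        }

    if "dysbiosis" in config.stages:
        log.info("dysbiosis: NB Wald %s", "patient vs control")
        nb = dysb.nb_wald_test(
            filtered, cohort_groups, "patient", "control",
            lfc_threshold=config.lfc_threshold, fdr=config.fdr_differential,
        )
        sig = nb[nb["significant"]]
        increased = list(sig.index[sig["direction"] == "increased"])
        decreased = list(sig.index[sig["direction"] == "decreased"])
        res["nb_wald"] = nb
        if increased and decreased:
            md = dysb.md_index(filtered, increased, decreased)
            patients = clinical.patients().index
            richness = (filtered.data > 0).sum(axis=1)
            assoc = dysb.md_severity_association(
                md, clinical.data.loc[patients, "mrs_baseline"],
                richness.loc[patients],
            )
            res["md_index"] = md
            res["md_assoc"] = assoc
            summary["dysbiosis"] = {
                "n_differential_taxa": int(len(sig)),
                "n_increased": len(increased), "n_decreased": len(decreased),
                "md_mrs_rho": assoc["mrs"][0] if assoc["mrs"] else None,
                "md_mrs_p": assoc["mrs"][1] if assoc["mrs"] else None,
                "md_richness_rho": assoc["richness"][0] if assoc["richness"] else None,
                "md_richness_p": assoc["richness"][1] if assoc["richness"] else None,
            }
        else:
            summary["dysbiosis"] = {"n_differential_taxa": int(len(sig)),
                                    "note": "one-sided taxa set; MD-index skipped"}

    if "metabolome" in config.stages:
        for comp, raw in (("fecal", cohort.fecal), ("serum", cohort.serum)):
            pre = metabolome.preprocess(raw)
            y = cohort_groups.loc[pre.sample_ids]
            pls = metabolome.plsda_fit(pre, y, n_perm=config.n_perm,
                                       seed=config.seed)
            sel = metabolome.select_differential_metabolites(
                pls, raw, cohort_groups, "patient", "control",
                vip_threshold=config.vip_threshold,
            )
            modules = metabolome.detect_modules(pre)
            selected = set(sel.index[sel["selected"]])
            enr = metabolome.pathway_enrichment(
                selected, cohort.annotation[comp], set(pre.metabolite_ids)
            )
            res[f"{comp}_pre"] = pre
            res[f"{comp}_plsda"] = pls
            res[f"{comp}_selection"] = sel
            res[f"{comp}_modules"] = modules
            res[f"{comp}_enrichment"] = enr
            n_elev = int((sel["selected"] & (sel["direction"] == "elevated")).sum())
            summary[f"metabolome_{comp}"] = {
                "r2": pls.r2, "q2": pls.q2,
                "perm_r2_median": float(np.median(pls.perm_r2)),
                "perm_q2_median": float(np.median(pls.perm_q2)),
                "n_selected": int(sel["selected"].sum()),
                "n_elevated": n_elev,
                "n_suppressed": int(sel["selected"].sum()) - n_elev,
                "n_modules": modules.n_modules,
                "soft_threshold_beta": modules.beta,
                "n_enriched_pathways": int((enr["p"] < 0.05).sum()) if len(enr) else 0,
            }
            log.info("metabolome[%s]: %d selected, %d modules", comp,
                     summary[f"metabolome_{comp}"]["n_selected"],
                     modules.n_modules)

    if "integration" in config.stages:
        cyt = cohort.cytokines
        cyt_groups = cohort_groups.loc[cyt.index]
        cyt_tests = integration.cytokine_group_tests(cyt, cyt_groups,
                                                     "patient", "control")
        res["cytokine_tests"] = cyt_tests
        diff_cyt = list(cyt_tests.index[cyt_tests["p"] < 0.05])
        genus = _genus_abundances(res["filtered"])
        # rank genera by patient-vs-control rank-sum p for the heatmap
        pvals = {}
        pat = cohort_groups[cohort_groups == "patient"].index
        ctl = cohort_groups[cohort_groups == "control"].index
        for g in genus.columns:
            try:
                _, p = guilds.wilcoxon_rank_sum(genus.loc[pat, g], genus.loc[ctl, g])
            except ValueError:
                p = 1.0
            pvals[g] = p
        top_genera = pd.Series(pvals).sort_values().index[:30]
        rho, pmat, star = integration.genus_cytokine_heatmap(
            genus[list(top_genera)], cyt[diff_cyt] if diff_cyt else cyt
        )
        res["genus_cytokine"] = (rho, pmat, star)
        edges = integration.build_integration_network(
            res["cags"].abundance if "cags" in res else genus,
            res.get("fecal_modules").eigenmetabolites if "fecal_modules" in res else None,
            res.get("serum_modules").eigenmetabolites if "serum_modules" in res else None,
            cyt,
            fdr=config.fdr_network,
        )
        res["network"] = edges
        sig_edges = edges[edges["significant"]]
        summary["integration"] = {
            "n_elevated_cytokines": int(
                ((cyt_tests["p"] < 0.05) & (cyt_tests["direction"] == "higher")).sum()
            ),
            "n_significant_edges": int(len(sig_edges)),
            "edges_by_family": sig_edges.groupby("family").size().to_dict(),
        }

    if "prognosis" in config.stages:
        patients = clinical.patients().index
        rel = res["filtered"].relative_abundance().loc[patients]
        outcome = clinical.data.loc[patients, "outcome6m_poor"].astype(int)
        report = prognosis.rf_outcome_model(
            rel, outcome, n_trees=config.n_trees, seed=config.seed
        )
        res["rf_report"] = report
        marker_otu = report.importances.index[0]
        covs = clinical.data.loc[patients, ["age", "neos", "consciousness"]].astype(float)
        covs["sex"] = (clinical.data.loc[patients, "sex"] == "F").astype(float)
        try:
            or_, or_ci, or_p = prognosis.logistic_adjusted_or(
                rel[marker_otu], outcome, covariates=covs
            )
        except ValueError as exc:
            or_, or_ci, or_p = np.nan, (np.nan, np.nan), np.nan
            log.warning("adjusted OR unavailable: %s", exc)
        alpha_div = res["alpha"] if "alpha" in res else ecology.alpha_diversity(res["filtered"])
        shan = alpha_div.loc[patients, "shannon"]
        low = (shan < shan.median()).astype(int)
        surv = prognosis.relapse_survival(
            clinical.data.loc[patients, "relapse_time"],
            clinical.data.loc[patients, "relapse_event"],
            low,
        )
        res["survival"] = surv
        combined = None
        if "serum_selection" in res and "fecal_selection" in res:
            def top2(comp):
                sel = res[f"{comp}_selection"]
                picked = sel[sel["selected"]].sort_values("vip", ascending=False)
                ids = list(picked.index[:2])
                raw = cohort.serum if comp == "serum" else cohort.fecal
                cols = raw.data.reindex(index=patients)[ids]
                return np.log10(cols.where(cols > 0))

            try:
                combined = prognosis.combined_marker_model(
                    clinical.data.loc[patients, "neos"].astype(float),
                    rel[marker_otu],
                    top2("serum"), top2("fecal"),
                    outcome, reference_auc=report.auc,
                    n_trees=config.n_trees, seed=config.seed,
                )
                res["combined_report"] = combined
            except ValueError as exc:
                log.warning("combined model unavailable: %s", exc)
        summary["prognosis"] = {
            "rf_auc": report.auc, "rf_auc_ci": list(report.auc_ci),
            "sensitivity": report.sensitivity, "specificity": report.specificity,
            "top_marker": marker_otu,
            "adjusted_or": or_, "adjusted_or_ci": list(or_ci), "adjusted_or_p": or_p,
            "poor_outcome_fraction": float(outcome.mean()),
            "logrank_p": surv.logrank_p, "hr": surv.hr, "hr_ci": list(surv.hr_ci),
            "combined_auc": combined.auc if combined is not None else None,
        }

    return res


def _write_outputs(res: dict, config: RunConfig, outdir: Path) -> list:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(obj, name):
        p = outdir / name
        obj.to_csv(p, sep="\t")
        written.append(name)

    if "alpha" in res:
        save(res["alpha"], "alpha_diversity.tsv")
        save(pd.DataFrame(res["unifrac"].data, index=list(res["unifrac"].ids),
                          columns=list(res["unifrac"].ids)), "unifrac.tsv")
        save(res["pcoa"][0], "pcoa_coordinates.tsv")
    if "sparcc" in res:
        save(res["sparcc"].rho, "sparcc_rho.tsv")
        save(res["sparcc"].edges(0.4), "sparcc_edges.tsv")
        save(res["cag_labels"].to_frame(), "cag_map.tsv")
        save(res["cags"].abundance, "cag_abundance.tsv")
        save(res["cags"].zscores, "cag_zscores.tsv")
        save(res["cag_tests"], "cag_tests.tsv")
    if "nb_wald" in res:
        save(res["nb_wald"], "differential_taxa.tsv")
        if "md_index" in res:
            save(res["md_index"].index.to_frame(), "md_index.tsv")
    for comp in ("fecal", "serum"):
        if f"{comp}_selection" in res:
            save(res[f"{comp}_selection"], f"{comp}_metabolite_selection.tsv")
            save(res[f"{comp}_modules"].labels.to_frame(), f"{comp}_module_map.tsv")
            save(res[f"{comp}_modules"].eigenmetabolites,
                 f"{comp}_eigenmetabolites.tsv")
            save(res[f"{comp}_enrichment"], f"{comp}_pathway_enrichment.tsv")
    if "cytokine_tests" in res:
        save(res["cytokine_tests"], "cytokine_tests.tsv")
        rho, pmat, star = res["genus_cytokine"]
        save(rho, "genus_cytokine_rho.tsv")
        save(star, "genus_cytokine_stars.tsv")
        save(res["network"], "integration_network.tsv")
    if "rf_report" in res:
        save(res["rf_report"].importances.to_frame(), "rf_importances.tsv")
        save(res["rf_report"].roc_points, "roc_points.tsv")
        save(res["survival"].at_risk, "km_at_risk.tsv")
    return written


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages; write outputs and a provenance-stamped
    report JSON when ``config.outdir`` is set."""
    logging.basicConfig(level=logging.INFO)
    cohort = _load_inputs(config)
    stage = "load"
    try:
        res = analyze_cohort(cohort, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in analysis after stage {stage!r}: {exc}") from exc
    res["summary"]["provenance"] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    if config.outdir:
        outdir = Path(config.outdir)
        if config.simulate:
            write_cohort(cohort, outdir / "cohort")
        written = _write_outputs(res, config, outdir)
        (outdir / "report.json").write_text(
            json.dumps(res["summary"], indent=1, default=str)
        )
        res["summary"]["outputs"] = written
    return res
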