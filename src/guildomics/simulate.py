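"""Synthetic case-control cohort generator with planted ground truth.

Emulates the data structure of a gut microbiome / fecal + serum metabolome /
cytokine / clinical-outcome study of an autoimmune encephalitis cohort:

* 58 patients (22 severe, baseline mRS 4-5; 36 moderate) and 49 controls;
* ~300 OTUs organized in 19 co-abundance guilds driven by per-sample latent
  factors, with a subset of guilds depleted/enriched in severe disease
  (attenuated in moderate disease) and a severity-linked evenness loss;
* fecal (~300) and serum (~380) metabolites organized in 8 co-abundance
  modules per compartment, a subset of whose latents is linearly coupled to
  guild factors and/or shifted with disease;
* a 15-channel cytokine panel with 9 channels elevated in patients and some
  channels coupled to guild factors;
* clinical outcomes: 6-month poor outcome (mRS > 2) from a logistic model on
  planted prognostic OTUs (intercept calibrated to a 36% poor-outcome rate),
  and relapse times that are exponential with a hazard ratio between
  below- and above-median Shannon-diversity patients.

Every random draw flows from ``CohortConfig.seed`` through stage-specific
child generators, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from skbio import TreeNode

from .containers import ClinicalTable, CountTable, MetaboliteTable
from .ecology import shannon

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "simulate_microbiome",
    "simulate_metabolomes",
    "simulate_clinical",
    "simulate_relapse_times",
    "simulate_cohort",
]

GENUS_POOL = [
    "Bacteroides", "Eubacterium_hallii_group", "Anaerostipes", "Megamonas",
    "Ruminococcus", "Butyricicoccus", "Faecalibacterium", "Enterococcus",
    "Oscillospirales", "Fusicatenibacter", "Sellimonas", "Bifidobacterium",
    "Clostridium_innocuum_group", "Roseburia", "Lachnospiraceae_NC2004_group",
    "Lachnospiraceae_NK4A136_group", "Prevotella", "Blautia", "Dorea",
    "Streptococcus", "Veillonella", "Akkermansia", "Alistipes",
    "Parabacteroides", "Coprococcus", "Dialister", "Phascolarctobacterium",
    "Sutterella", "Collinsella", "Granulicatella",
]

CYTOKINE_PANEL = [
    "CCL4", "IFN-a", "IFN-g", "IL-1b", "IL-7", "IFN-b", "IL-1ra", "IL-10",
    "IL-4", "IL-6", "IL-8", "IL-12p40", "IL-18", "IL-17", "TNF-a",
]

ELEVATED_CYTOKINES = [
    "IFN-b", "IFN-g", "IL-6", "IL-1b", "IL-7", "IL-18", "TNF-a", "IL-17", "IL-8",
]

PATHWAY_POOL = [
    "beta-alanine metabolism", "phenylpropanoid biosynthesis",
    "choline metabolism", "aminobenzoate degradation", "bile secretion",
    "pentose and glucuronate interconversions", "tryptophan metabolism",
    "d-glutamine and d-glutamate metabolism", "purine metabolism",
    "glycerophospholipid metabolism", "ABC transporters",
    "arginine and proline metabolism", "fatty acid biosynthesis",
    "primary bile acid biosynthesis", "glycolysis and gluconeogenesis",
    "citrate cycle", "sphingolipid metabolism", "histidine metabolism",
    "steroid hormone biosynthesis", "lysine degradation",
]


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    ``guild_effect`` is the |log2 fold change| applied to affected guilds in
    severe patients (halved in moderate patients); ``prognostic_otu_effect``
    is the log-odds of poor outcome per SD of the primary marker's
    log-abundance (negative = protective); ``relapse_hr`` is the hazard
    ratio of relapse for below- vs above-median Shannon diversity.
    """

    n_patients: int = 58
    n_severe: int = 22
    n_controls: int = 49
    n_otus: int = 300
    n_guilds: int = 19
    guild_effect: float = 2.0
    n_depleted_guilds: int = 2
    n_enriched_guilds: int = 1
    n_fecal_mets: int = 300
    n_serum_mets: int = 380
    n_modules: int = 8
    n_cytokines: int = 15
    cytokine_names: list = field(default_factory=lambda: list(CYTOKINE_PANEL))
    elevated_cytokines: list = field(default_factory=lambda: list(ELEVATED_CYTOKINES))
    cytokine_elevation: float = 0.5        # log10 units per severity unit
    cytokine_guild_coupling: float = 0.25
    prognostic_otu_effect: float = -3.0
    n_prognostic_otus: int = 5
    secondary_prognostic_effect: float = 1.5
    relapse_hr: float = 2.7
    base_relapse_rate: float = 0.03        # events / month in high-diversity group
    followup_months: float = 6.0
    poor_outcome_rate: float = 0.36
    depth_mean: float = 50_000.0
    depth_log_sd: float = 0.3
    moderate_attenuation: float = 0.5
    evenness_exponent: float = 0.35        # composition sharpening per severity unit
    module_coupling: float = 0.8
    n_coupled_modules: int = 6
    n_disease_modules: int = 3
    disease_module_shift: float = 0.8
    n_pathways: int = 18
    n_enriched_pathways: int = 3
    missing_rate: float = 0.02
    n_serum_patients: int = 39
    n_serum_controls: int = 31
    seed: int = 42

    def __post_init__(self) -> None:
        counts = [self.n_patients, self.n_severe, self.n_controls, self.n_otus,
                  self.n_guilds, self.n_fecal_mets, self.n_serum_mets,
                  self.n_modules, self.n_cytokines]
        if any(c < 1 for c in counts):
            raise ValueError("all cohort counts must be >= 1")
        if self.n_severe > self.n_patients:
            raise ValueError("n_severe exceeds n_patients")
        if self.relapse_hr <= 0:
            raise ValueError("relapse_hr must be positive")
        if self.n_otus < 3 * self.n_guilds:
            raise ValueError(
                f"{self.n_guilds} guilds over {self.n_otus} OTUs would leave "
                "guild blocks smaller than 3 (undetectable)"
            )
        if self.n_depleted_guilds + self.n_enriched_guilds > self.n_guilds:
            raise ValueError("more affected guilds than guilds")
        if len(self.cytokine_names) != self.n_cytokines:
            raise ValueError("cytokine_names length must equal n_cytokines")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort (for validation only)."""

    otu_guild_labels: pd.Series
    affected_guilds: dict                   # guild id -> +1 (enriched) / -1 (depleted)
    guild_factors: pd.DataFrame             # samples x guilds latent factors
    severity: pd.Series                     # sample -> 0 / 0.5 / 1
    group: pd.Series                        # sample -> control/moderate/severe
    true_differential_taxa: dict            # otu -> direction
    module_labels: dict = field(default_factory=dict)      # compartment -> Series
    module_latents: dict = field(default_factory=dict)     # compartment -> DataFrame
    coupled_pairs: dict = field(default_factory=dict)      # compartment -> [(guild, module, coef)]
    disease_modules: dict = field(default_factory=dict)    # compartment -> {module: shift}
    enriched_pathways: dict = field(default_factory=dict)  # compartment -> [pathway]
    prognostic_otus: list = field(default_factory=list)    # ranked, strongest first
    prognostic_effects: list = field(default_factory=list)
    true_relapse_groups: Optional[pd.Series] = None        # patient -> low/high
    elevated_cytokines: list = field(default_factory=list)
    serum_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.otu_guild_labels.isna().any():
            raise ValueError("every OTU must carry exactly one guild label")
        bad = set(self.affected_guilds) - set(self.otu_guild_labels.unique())
        if bad:
            raise ValueError(f"affected guilds not in guild set: {sorted(bad)}")


@dataclass
class Cohort:
    """Bundle of all simulated tables plus the ground truth."""

    config: CohortConfig
    counts: CountTable
    tree: TreeNode
    truth: GroundTruth
    fecal: MetaboliteTable
    serum: MetaboliteTable
    annotation: dict                       # compartment -> Series metabolite->pathway
    clinical: ClinicalTable
    cytokines: pd.DataFrame


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _sample_frame(config: CohortConfig, rng: np.random.Generator):
    patients = [f"P{i+1:03d}" for i in range(config.n_patients)]
    controls = [f"C{i+1:03d}" for i in range(config.n_controls)]
    severe = rng.choice(config.n_patients, size=config.n_severe, replace=False)
    group = pd.Series("control", index=patients + controls, name="group")
    for i, pid in enumerate(patients):
        group[pid] = "severe" if i in severe else "moderate"
    sev = group.map(
        {"severe": 1.0, "moderate": config.moderate_attenuation, "control": 0.0}
    )
    sev.name = "severity"
    return group, sev


def _build_tree(otu_ids, guild_labels: pd.Series, rng: np.random.Generator) -> TreeNode:
    """Random coalescent-style joins, guild members first; branch lengths Exp(1)."""

    def join_all(nodes):
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            right = nodes.pop(j)
            left = nodes.pop(i)
            parent = TreeNode(children=[left, right])
            left.length = float(rng.exponential(1.0))
            right.length = float(rng.exponential(1.0))
            nodes.append(parent)
        return nodes[0]

    guild_roots = []
    for g in sorted(guild_labels.unique()):
        members = [TreeNode(name=o) for o in otu_ids[guild_labels == g]]
        guild_roots.append(join_all(members))
    root = join_all(guild_roots)
    root.length = None
    return root


def simulate_microbiome(config: CohortConfig):
    """Generate the OTU count table, phylogeny and microbiome ground truth.

    Counts arise from per-guild latent log-normal factors plus OTU noise,
    group effects on affected guilds, severity-linked evenness loss, closure
    to proportions and multinomial sampling at a log-normal depth.
    """
    rng = _rng(config, 1)
    group, sev = _sample_frame(config, rng)
    samples = list(group.index)
    n = len(samples)

    # guild sizes >= 3
    extra = rng.multinomial(
        config.n_otus - 3 * config.n_guilds, np.ones(config.n_guilds) / config.n_guilds
    )
    sizes = 3 + extra
    otu_ids = [f"OTU{i+1:04d}" for i in range(config.n_otus)]
    guild_labels = pd.Series(
        np.repeat(np.arange(1, config.n_guilds + 1), sizes),
        index=pd.Index(otu_ids, name="otu"), name="guild",
    )

    affected = {}
    pool = rng.permutation(np.arange(1, config.n_guilds + 1))
    for g in pool[: config.n_depleted_guilds]:
        affected[int(g)] = -1
    for g in pool[config.n_depleted_guilds:
                  config.n_depleted_guilds + config.n_enriched_guilds]:
        affected[int(g)] = +1

    base = rng.normal(0.0, 2.2, size=config.n_otus)
    loadings = rng.uniform(0.7, 1.1, size=config.n_otus)
    factors = rng.normal(0.0, 0.6, size=(n, config.n_guilds))
    noise = rng.normal(0.0, 0.4, size=(n, config.n_otus))

    # prognostic marker OTUs: moderately abundant, from unaffected guilds,
    # and mostly decoupled from their guild factor so the outcome signal is
    # carried by the taxon itself rather than by correlated guild-mates
    unaffected_mask = ~np.isin(gidx_all := (guild_labels.to_numpy() - 1),
                               [g - 1 for g in affected])
    order = np.argsort(-base)
    pool = [i for i in order if unaffected_mask[i]]
    width = 5 * config.n_prognostic_otus
    start = min(30, max(0, len(pool) - width))
    candidates = pool[start: start + width] or pool
    prognostic_idx = rng.choice(candidates, size=config.n_prognostic_otus,
                                replace=False)
    loadings[prognostic_idx] = 0.15

    gidx = guild_labels.to_numpy() - 1
    log_a = base[None, :] + loadings[None, :] * factors[:, gidx] + noise
    sev_arr = sev.to_numpy()
    for g, direction in affected.items():
        members = gidx == (g - 1)
        log_a[:, members] += (
            direction * config.guild_effect * np.log(2.0) * sev_arr[:, None]
        )

    prop = np.exp(log_a - log_a.max(axis=1, keepdims=True))
    prop /= prop.sum(axis=1, keepdims=True)
    sharp = 1.0 + config.evenness_exponent * sev_arr
    prop = prop ** sharp[:, None]
    prop /= prop.sum(axis=1, keepdims=True)

    depths = np.round(
        rng.lognormal(np.log(config.depth_mean), config.depth_log_sd, size=n)
    ).astype(int)
    counts = np.vstack(
        [rng.multinomial(depths[i], prop[i]) for i in range(n)]
    )

    # taxonomy: a few genera per guild, drawn from a domain-typical pool;
    # the primary prognostic marker gets its own genus label
    guild_genera = {
        g: rng.choice(len(GENUS_POOL) - 1, size=min(3, len(GENUS_POOL) - 1),
                      replace=False)
        for g in range(1, config.n_guilds + 1)
    }
    taxonomy = pd.Series(
        [GENUS_POOL[rng.choice(guild_genera[g])] for g in guild_labels],
        index=guild_labels.index, name="genus",
    )
    taxonomy.iloc[prognostic_idx[0]] = "Granulicatella"

    tree = _build_tree(pd.Index(otu_ids), guild_labels, rng)

    true_diff = {
        otu: ("increased" if affected[g] > 0 else "decreased")
        for otu, g in guild_labels.items() if g in affected
    }
    truth = GroundTruth(
        otu_guild_labels=guild_labels,
        affected_guilds=affected,
        guild_factors=pd.DataFrame(
            factors, index=samples,
            columns=[f"G{g}" for g in range(1, config.n_guilds + 1)],
        ),
        severity=sev,
        group=group,
        true_differential_taxa=true_diff,
        prognostic_otus=[otu_ids[i] for i in prognostic_idx],
    )
    table = CountTable(
        pd.DataFrame(counts, index=samples, columns=otu_ids),
        taxonomy=taxonomy, tree=tree,
    )
    return table, tree, truth


def _simulate_compartment(
    config: CohortConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    n_mets: int,
    samples: list,
    prefix: str,
):
    n = len(samples)
    m = config.n_modules
    # Coupling layout: the first modules pair 1:1 with the severity-affected
    # guilds, are disease-shifted in the guild's direction and coupled with a
    # positive coefficient (so the guild-factor and severity components of
    # the association reinforce rather than cancel); subsequent coupled
    # modules attach to unaffected guilds with alternating-sign couplings
    # and no disease shift; the remainder are pure noise modules.
    affected_order = list(truth.affected_guilds)
    unaffected = [
        g for g in range(1, config.n_guilds + 1) if g not in truth.affected_guilds
    ]
    coupled = []
    latents = np.empty((n, m))
    fac = truth.guild_factors.loc[samples]
    sev = truth.severity.loc[samples].to_numpy()
    disease = {}
    n_paired = min(len(affected_order), config.n_disease_modules,
                   config.n_coupled_modules)
    for j in range(m):
        if j < n_paired:
            g = affected_order[j]
            c = config.module_coupling
            shift = truth.affected_guilds[g] * config.disease_module_shift
        elif j < config.n_coupled_modules:
            g = unaffected[(j - n_paired) % len(unaffected)]
            c = config.module_coupling * (1 if j % 2 == 0 else -1)
            shift = 0.0
        else:
            g, c, shift = None, 0.0, 0.0
        if g is not None:
            f = fac[f"G{g}"].to_numpy()
            f = (f - f.mean()) / f.std()
            latents[:, j] = c * f + np.sqrt(1 - c ** 2) * rng.normal(size=n)
            coupled.append((g, j + 1, c))
        else:
            latents[:, j] = rng.normal(size=n)
        if shift != 0.0:
            latents[:, j] = latents[:, j] + shift * sev
            disease[j + 1] = shift
    for j in range(n_paired, config.n_disease_modules):
        # any disease modules beyond the affected-guild pairing go on the
        # last (uncoupled) modules
        tgt = m - 1 - (j - n_paired)
        if tgt >= config.n_coupled_modules:
            shift = config.disease_module_shift * (1 if j % 2 == 0 else -1)
            latents[:, tgt] = latents[:, tgt] + shift * sev
            disease[tgt + 1] = shift

    n_unassigned = max(0, int(round(0.1 * n_mets)))
    n_in_modules = n_mets - n_unassigned
    extra = rng.multinomial(n_in_modules - 5 * m, np.ones(m) / m)
    sizes = 5 + extra
    labels = np.concatenate(
        [np.repeat(np.arange(1, m + 1), sizes), np.zeros(n_unassigned, dtype=int)]
    )
    met_ids = [f"{prefix}_met{i+1:04d}" for i in range(n_mets)]
    label_s = pd.Series(labels, index=pd.Index(met_ids, name="metabolite"),
                        name="module")

    base = rng.normal(5.0, 0.5, size=n_mets)
    load = rng.uniform(0.6, 0.95, size=n_mets) * np.where(
        rng.random(n_mets) < 0.8, 1.0, -1.0
    )
    logx = base[None, :] + rng.normal(0.0, 0.45, size=(n, n_mets))
    for j in range(m):
        members = labels == j + 1
        logx[:, members] += load[None, members] * latents[:, [j]]
    intensities = 10.0 ** logx
    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities[mask] = 0.0

    # pathway annotation with planted enrichment among disease-module members
    pathways = [PATHWAY_POOL[i % len(PATHWAY_POOL)] for i in range(config.n_pathways)]
    enriched = list(rng.choice(pathways, size=config.n_enriched_pathways,
                               replace=False))
    differential = [met_ids[i] for i in range(n_mets) if labels[i] in disease]
    annotation = {}
    diff_pool = list(rng.permutation(differential))
    for pw in enriched:
        for _ in range(min(12, max(3, len(diff_pool) // config.n_enriched_pathways))):
            if diff_pool:
                annotation[diff_pool.pop()] = pw
    rest = [mid for mid in met_ids if mid not in annotation]
    others = [pw for pw in pathways if pw not in enriched]
    for mid in rest:
        annotation[mid] = others[rng.integers(len(others))]
    ann = pd.Series(annotation, name="pathway").loc[met_ids]
    ann.index.name = "metabolite"

    latent_df = pd.DataFrame(
        latents, index=samples, columns=[f"M{j+1}" for j in range(m)]
    )
    table = pd.DataFrame(intensities, index=samples, columns=met_ids)
    return table, label_s, latent_df, coupled, disease, enriched, ann


def simulate_metabolomes(config: CohortConfig, truth: GroundTruth):
    """Generate raw fecal and serum metabolite tables plus pathway maps.

    Each metabolite is loading x module latent + noise on the log10 scale;
    coupled module latents are linear in (standardized) guild factors;
    disease modules shift with severity, making their members differential
    and their planted pathways enriched. The serum assay covers only a
    subset of the cohort.
    """
    rng = _rng(config, 2)
    samples = list(truth.group.index)
    fecal_x, f_labels, f_latents, f_coupled, f_disease, f_enriched, f_ann = (
        _simulate_compartment(config, truth, rng, config.n_fecal_mets, samples, "F")
    )
    patients = [s for s in samples if truth.group[s] != "control"]
    controls = [s for s in samples if truth.group[s] == "control"]
    serum_samples = sorted(
        list(rng.choice(patients, size=min(config.n_serum_patients, len(patients)),
                        replace=False))
        + list(rng.choice(controls, size=min(config.n_serum_controls, len(controls)),
                          replace=False))
    )
    serum_x, s_labels, s_latents, s_coupled, s_disease, s_enriched, s_ann = (
        _simulate_compartment(config, truth, rng, config.n_serum_mets,
                              serum_samples, "S")
    )
    truth.module_labels = {"fecal": f_labels, "serum": s_labels}
    truth.module_latents = {"fecal": f_latents, "serum": s_latents}
    truth.coupled_pairs = {"fecal": f_coupled, "serum": s_coupled}
    truth.disease_modules = {"fecal": f_disease, "serum": s_disease}
    truth.enriched_pathways = {"fecal": f_enriched, "serum": s_enriched}
    truth.serum_samples = serum_samples
    fecal = MetaboliteTable(fecal_x, compartment="fecal")
    serum = MetaboliteTable(serum_x, compartment="serum")
    return fecal, serum, {"fecal": f_ann, "serum": s_ann}


def simulate_relapse_times(
    low_diversity: np.ndarray,
    hr: float,
    base_rate: float,
    followup: float,
    rng: np.random.Generator,
):
    """Exponential relapse times with rate ``base_rate`` (high-diversity) or
    ``hr * base_rate`` (low-diversity), right-censored at ``followup``."""
    low_diversity = np.asarray(low_diversity, dtype=bool)
    rates = np.where(low_diversity, hr * base_rate, base_rate)
    raw = rng.exponential(1.0 / rates)
    event = (raw <= followup).astype(int)
    time = np.minimum(raw, followup)
    return time, event


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    def f(alpha):
        return expit(alpha + lin).mean() - target

    return brentq(f, -30.0, 30.0)


def simulate_clinical(config: CohortConfig, truth: GroundTruth, counts: CountTable):
    """Generate the clinical table and cytokine panel.

    Poor 6-month outcome follows a logistic model on the planted prognostic
    OTUs' standardized log relative abundances, intercept calibrated so the
    expected poor-outcome fraction matches ``config.poor_outcome_rate``.
    Relapse hazards depend on the realized below/above-median Shannon split.
    Cytokines are log-normal with severity-linked elevation of the
    configured channels and coupling to guild factors.
    """
    rng = _rng(config, 3)
    samples = list(truth.group.index)
    patients = [s for s in samples if truth.group[s] != "control"]
    rel = counts.relative_abundance()

    # prognostic OTUs were designated during microbiome simulation
    chosen = list(truth.prognostic_otus)
    effects = [config.prognostic_otu_effect] + [
        config.secondary_prognostic_effect * (1 if k % 2 == 0 else -1)
        for k in range(config.n_prognostic_otus - 1)
    ]
    truth.prognostic_effects = effects

    logrel = np.log10(rel.loc[patients, chosen] + 1e-6)
    sd = logrel.std(axis=0, ddof=0).replace(0, 1.0)
    z = (logrel - logrel.mean(axis=0)) / sd
    lin = (z.to_numpy() * np.array(effects)[None, :]).sum(axis=1)
    if np.allclose(lin, lin[0]):
        alpha = np.log(config.poor_outcome_rate / (1 - config.poor_outcome_rate))
    else:
        alpha = _calibrate_intercept(lin, config.poor_outcome_rate)
    p_poor = expit(alpha + lin)
    poor = rng.random(len(patients)) < p_poor

    shan = pd.Series(
        {s: shannon(counts.data.loc[s].to_numpy()) for s in patients}, name="shannon"
    )
    if shan.nunique() == 1:
        raise ValueError("patient Shannon diversity is constant; median split undefined")
    low = shan < shan.median()
    time, event = simulate_relapse_times(
        low.to_numpy(), config.relapse_hr, config.base_relapse_rate,
        config.followup_months, rng,
    )
    truth.true_relapse_groups = pd.Series(
        np.where(low, "low", "high"), index=patients, name="relapse_group"
    )
    truth.elevated_cytokines = list(config.elevated_cytokines)

    clin = pd.DataFrame(index=pd.Index(samples, name="sample"))
    clin["cohort"] = ["patient" if truth.group[s] != "control" else "control"
                      for s in samples]
    mrs = {}
    for s in samples:
        if truth.group[s] == "severe":
            mrs[s] = int(rng.choice([4, 5]))
        elif truth.group[s] == "moderate":
            mrs[s] = int(rng.choice([2, 3]))
        else:
            mrs[s] = 0
    clin["mrs_baseline"] = pd.Series(mrs)
    poor_s = pd.Series(poor, index=patients)
    clin["outcome6m_poor"] = poor_s.astype(float).reindex(samples)
    mrs6 = {
        s: int(rng.choice([3, 4, 5]) if poor_s[s] else rng.choice([0, 1, 2]))
        for s in patients
    }
    clin["mrs_6m"] = pd.Series(mrs6).reindex(samples)
    clin["neos"] = [
        int(rng.binomial(5, 0.25 + 0.35 * poor_s[s])) if s in poor_s.index else 0
        for s in samples
    ]
    clin["age"] = np.clip(rng.normal(34, 13, size=len(samples)).round(), 16, 75)
    clin["sex"] = rng.choice(["F", "M"], size=len(samples), p=[0.62, 0.38])
    clin["consciousness"] = [
        int(rng.random() < (0.15 + 0.45 * truth.severity[s])) for s in samples
    ]
    clin["relapse_time"] = pd.Series(time, index=patients).reindex(samples)
    clin["relapse_event"] = pd.Series(event, index=patients).reindex(samples)

    # cytokines on the serum subset (fallback: everyone, if metabolomes not drawn)
    cyt_samples = truth.serum_samples if truth.serum_samples else samples
    ncy = config.n_cytokines
    base_c = rng.normal(1.5, 0.4, size=ncy)
    logc = base_c[None, :] + rng.normal(0.0, 0.3, size=(len(cyt_samples), ncy))
    sev = truth.severity.loc[cyt_samples].to_numpy()
    fac = truth.guild_factors.loc[cyt_samples]
    guild_cols = list(fac.columns)
    for j, name in enumerate(config.cytokine_names):
        if name in config.elevated_cytokines:
            logc[:, j] += config.cytokine_elevation * sev
            g = guild_cols[j % len(guild_cols)]
            logc[:, j] += config.cytokine_guild_coupling * fac[g].to_numpy()
    cytokines = pd.DataFrame(
        10.0 ** logc, index=cyt_samples, columns=config.cytokine_names
    )
    return ClinicalTable(clin), cytokines


def simulate_cohort(config: Optional[CohortConfig] = None) -> Cohort:
    """Full synthetic study: microbiome, metabolomes, cytokines, clinical."""
    config = config or CohortConfig()
    counts, tree, truth = simulate_microbiome(config)
    fecal, serum, annotation = simulate_metabolomes(config, truth)
    clinical, cytokines = simulate_clinical(config, truth, counts)
    return Cohort(
        config=config, counts=counts, tree=tree, truth=truth,
        fecal=fecal, serum=serum, annotation=annotation,
        clinical=clinical, cytokines=cytokines,
    )
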