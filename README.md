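# guildomics

Integrated analysis of gut microbiome, fecal/serum metabolome, cytokine and
clinical-outcome data for severity-stratified case-control cohorts — the
kind of study design used to link intestinal dysbiosis to disease severity
and prognosis in autoimmune encephalitis — together with a ground-truthed
synthetic cohort generator that validates every stage of the pipeline.

It is written for microbiome/multi-omics analysts who need the pieces of
such a study as tested, composable functions rather than a collection of
one-off scripts:

- **ecology** — Shannon (nats) and Chao1 alpha diversity, unweighted
  UniFrac, PCoA (negative eigenvalues reported), seeded ANOSIM and
  PERMANOVA permutation tests;
- **guilds** — abundance/prevalence OTU filtering, SparCC compositional
  correlations (ρ_ij = (ωᵢ + ωⱼ − t_ij)/(2√(ωᵢωⱼ)) from log-ratio
  variances t_ij with iterative strong-pair exclusion), Ward clustering
  into co-abundance groups (CAGs), per-sample CAG abundances/Z-scores and
  Wilcoxon group tests;
- **dysbiosis** — negative-binomial Wald differential abundance (log link,
  median-of-ratios size-factor offsets, Cox-Reid adjusted
  profile-likelihood dispersion, BH q < 0.01 ∧ |log₂FC| ≥ 1 rule) and the
  microbial dysbiosis index MD = log₁₀(Σ increased / Σ decreased) with its
  severity and richness correlations;
- **metabolome** — preprocessing (half-minimum imputation, log₁₀,
  autoscaling), PLS-DA with VIP scores (mean VIP² = 1), cross-validated Q²
  and label-permutation validation, co-abundance module detection
  (soft-threshold |cor|^β adjacency, topological overlap, eigen-metabolites)
  and hypergeometric sub-pathway enrichment with rich factors;
- **integration** — Welch t-tests on log cytokine levels, genus-cytokine
  Spearman heatmaps with star levels, and the FDR-controlled Spearman
  network across CAGs, metabolite modules and cytokines (BH within each
  pair family);
- **prognosis** — cross-validated random-forest outcome prediction with
  honest in-fold feature selection and mean-decrease-accuracy importances,
  Mann-Whitney AUC with bootstrap CI, covariate-adjusted logistic odds
  ratios for a microbial marker, and Kaplan-Meier / log-rank / Cox relapse
  analysis stratified by the Shannon-index median;
- **simulate** — the synthetic cohort: 58 patients (22 severe) + 49
  controls, 300 OTUs in 19 latent-factor guilds with severity effects and
  evenness loss, fecal/serum metabolite modules coupled to guild factors,
  a 15-channel cytokine panel with 9 disease-elevated channels, a planted
  prognostic taxon panel driving 6-month outcome, and diversity-dependent
  relapse hazards — all with the ground truth returned for validation.

## Worked example

```python
from guildomics import simulate_cohort
from guildomics.guilds import filter_otus, sparcc, cluster_cags, cag_abundance_zscores
from guildomics.prognosis import rf_outcome_model

cohort = simulate_cohort()                      # default study design, seed 42
filt = filter_otus(cohort.counts)               # total >= 1000 & prevalence >= 20%
rho = sparcc(filt, seed=0)                      # compositional correlations
cags = cluster_cags(rho, n_cags=19)             # OTU -> guild map
part = cag_abundance_zscores(filt, cags)

patients = cohort.clinical.patients().index
rep = rf_outcome_model(
    filt.relative_abundance().loc[patients],
    cohort.clinical.data.loc[patients, "outcome6m_poor"].astype(int),
    n_trees=500, seed=0,
)
print(f"{filt.data.shape[1]} retained OTUs -> {cags.nunique()} CAGs")
print(f"held-out AUC = {rep.auc:.3f}, top marker = {rep.importances.index[0]}")
```

prints

```
184 retained OTUs -> 19 CAGs
held-out AUC = 0.866, top marker = OTU0171
```

i.e. of the 300 simulated OTUs, 184 pass the abundance/prevalence filter
and cluster into the requested 19 co-abundance groups, and the
cross-validated forest separates poor from favorable 6-month outcomes with
AUC 0.87 — its top-ranked taxon is the planted prognostic marker.

The whole pipeline (ecology → guilds → dysbiosis → metabolome →
integration → prognosis) runs in one call and writes every table plus a
provenance-stamped JSON report:

```bash
guildomics simulate --out cohort/ --seed 42
guildomics run-all --out results/ --seed 0
```

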