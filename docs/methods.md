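# Methods

`guildomics` implements an integrated case-control analysis of gut
microbiome, fecal and serum metabolome, cytokine and clinical-outcome data,
together with a ground-truthed synthetic cohort generator used to validate
every stage. This note records the models, the numerical choices, and what
the validation does and does not establish.

## The analysis pipeline

### Community ecology

Alpha diversity is Shannon entropy H = −Σ pᵢ ln pᵢ (nats by default; a
`base` argument converts) and Chao1 richness in the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)), which is defined when no doubletons are
observed; the classical F₁²/(2F₂) form is available by flag. No rarefaction
is applied before diversity; per-sample depth is reported so users can
rarefy externally if desired.

Beta diversity is unweighted UniFrac (presence/absence; the fraction of
tree branch length leading to taxa found in exactly one of the two
communities), computed with scikit-bio. Ordination is classical scaling
(PCoA) of the Gower-centered squared-distance matrix, implemented directly
so that negative eigenvalues — the signature of non-Euclidean distances —
are reported rather than clamped. Group structure is tested with ANOSIM
(R = (r̄_between − r̄_within)/(n(n−1)/4) on distance ranks) and PERMANOVA
(Anderson's pseudo-F from within/among squared-distance sums); both use
seeded label permutations with p = (1 + #{stat* ≥ stat})/(n_perm + 1) and
default n_perm = 999. Both statistics are cross-checked against scikit-bio
in the test suite.

### Co-abundance guilds (CAGs)

OTUs are first filtered: retained iff cohort-wide total count ≥ 1 000 and
prevalence ≥ 20 %. Correlations among the retained, compositional
abundances are estimated with SparCC: with log-ratio variances
t_ij = var(log xᵢ/xⱼ), and under the assumption that most pairs are
uncorrelated, the basis variances ω solve the linear system
Σ_{j∈inc(i)} t_ij = dᵢωᵢ + Σ_{j∈inc(i)} ωⱼ, and
ρ_ij = (ωᵢ + ωⱼ − t_ij)/(2√(ωᵢωⱼ)), clamped to [−1, 1]. Pairs whose |ρ|
exceeds 0.1 are excluded from the basis system one per round (up to 10
rounds). Fractions are drawn from Dirichlet(counts + 0.5) in each of 20
inner iterations and the per-pair median ρ is reported; pseudo p-values
come from 100 sample bootstraps (two-sided sign-crossing frequency). All
randomness is seeded.

CAGs are obtained by Ward hierarchical clustering on 1 − ρ, cut to a
requested cluster count (default 19) or height; OTUs are sorted by id
before clustering so the partition is input-order invariant. Per-sample
CAG abundance is the sum of member relative abundances; Z-score profiles
standardize each CAG across samples with the population SD. Group
differences per CAG use the two-sided Wilcoxon rank-sum test — exact for
tie-free groups of ≤ 25, tie-corrected normal approximation otherwise —
with direction from the median difference. An edge-list view of the SparCC
network uses the display threshold |ρ| > 0.4.

### Differential abundance and the dysbiosis index

Differential taxa come from a per-feature negative-binomial GLM with log
link, a group indicator, and a log size-factor offset (median-of-ratios
size factors; total-count scaling as fallback when no feature is positive
everywhere). Dispersion is estimated per feature by Cox-Reid adjusted
profile maximum likelihood over log α (bounded search, method-of-moments
start) — the adjustment removes the downward bias of plain ML dispersion
at small n — and the Wald statistic is referred to a t distribution with
residual degrees of freedom rather than the normal, which together center
the empirical type-I error on its nominal level at n = 30/30 in the
calibration simulations. No empirical-Bayes shrinkage across features is
applied — a deliberate simplification validated by the same simulations.
Significance requires BH q < 0.01 and |log₂FC| ≥ 1.

The microbial dysbiosis index (MD-index) of a sample is
log₁₀[(Σ relative abundance of disease-increased taxa + ε)/(Σ over
disease-decreased taxa + ε)] with ε = 10⁻⁶; the increased/decreased sets
default to the NB-Wald-significant taxa of the all-patients-vs-controls
comparison. Associations of the MD-index with baseline severity (mRS) and
observed richness use Spearman correlation (exact permutation p for n ≤ 9).
Because the index depends only on relative abundances it is invariant to
sequencing depth.

### Metabolomics

Raw intensities are preprocessed by half-minimum imputation per metabolite
(NaN and 0 treated as missing), log₁₀ transform, and unit-variance scaling
(Pareto optional); entirely-missing and constant metabolites are dropped
and recorded, and re-preprocessing a processed table is an error.

PLS-DA uses NIPALS partial least squares (scikit-learn) on centered one-hot
class labels. VIPⱼ = √(p Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a), whose mean
square over metabolites is 1 by construction. R² is in-sample explained
class variance; Q² = 1 − PRESS/TSS from stratified 7-fold cross-validation;
permutation validation refits the model on label shuffles (default 999) and
reports the null R²/Q² distributions without enforcing a validity cutoff.
Differential metabolites are selected by VIP > 1 (strict) AND rank-sum
p < 0.05, with raw-scale fold changes and BH q reported alongside.

Co-abundance modules use an unsigned soft-threshold adjacency |cor|^β with
β the smallest power whose scale-free fit R² reaches 0.8 *among powers that
keep mean connectivity ≥ 1* — without that admissibility constraint the
fit criterion alone pushes β so high that the network disconnects and
module recovery collapses; if no admissible power reaches the target the
best-fitting admissible power is used and flagged. The topological overlap
matrix TOM_ij = (ΣₗaᵢₗaⱼₗI + a_ij)/(min(kᵢ,kⱼ) + 1 − a_ij) feeds
average-linkage clustering on 1 − TOM with a static cut. The default cut
is scale-relative — 99 % of the maximum merge height — because on 1 − TOM
dendrograms between-module merges crowd toward the top of the tree while
the within-module height range moves with β; a fixed absolute height that
works at one scale fails at another. Modules smaller than 5 become an
explicit "unassigned" module (id 0). The eigen-metabolite is the
unit-variance first principal component of the module's standardized
members, sign-aligned to positive mean member correlation.

Pathway enrichment is the hypergeometric upper tail of the selected-set /
pathway overlap within the annotated universe, BH-corrected, with rich
factor = hits / pathway size.

### Integration

Cytokine group differences use Welch's t-test on log₁₀ concentrations
(assay data are right-skewed; zeros imputed at half the smallest positive
value). Genus-cytokine heatmaps report all pairwise Spearman correlations
with star levels at p < 0.05/0.01/0.001/0.0001. The cross-omic network
computes Spearman correlations within pair families — CAG × fecal modules,
CAG × serum modules, modules × cytokines, and (by default) CAG ×
cytokines — inner-joining each family on shared samples (serum assays may
cover a subset) and applying BH within each family, matching family-wise
reporting; a pooled-correction mode exists. Edges with q < 0.05 are the
significant view; no effect-size threshold is applied.

### Prognosis

The outcome classifier is a random forest over OTU relative abundances of
patients under repeated stratified 5×5-fold cross-validation, 1 000 trees.
Because a forest over all ~180 retained taxa at n = 58 dilutes a handful of
informative taxa across mtry-sampled splits, each training fold first
ranks taxa with a full-feature forest and refits on the top 10 (mirroring
a top-taxa panel); selection happens strictly inside the fold so pooled
held-out scores remain honest, and `top_k=None` disables it. Feature
importance is mean decrease in held-out accuracy under per-feature
permutation of the held-out block, averaged over folds. The ROC pools
held-out scores; AUC uses the Mann-Whitney formulation (ties 0.5), its CI
a 2 000-replicate sample bootstrap, and the operating point the Youden
maximum. The combined marker panel (NEOS score, microbial marker, two
serum and two fecal metabolite markers) reuses the same machinery and
reports the AUC delta against a reference model.

The covariate-adjusted marker effect is a maximum-likelihood logistic
regression of poor outcome on an above-median marker indicator (continuous
mode by flag) plus age, sex, consciousness disturbance and NEOS score,
with Wald intervals; (quasi-)separation raises an error rather than
returning an unbounded estimate. Relapse analysis stratifies patients at
the median Shannon index and reports Kaplan-Meier curves, the two-group
log-rank test, and a Cox proportional-hazards HR (Efron ties) with Wald
CI and monthly at-risk counts; with zero events the curves are returned
and the tests are flagged undefined.

## The synthetic cohort generator

The generator emulates the structure of a two-arm severity cohort: 58
patients (22 severe, mRS 4-5; 36 moderate, mRS 2-3) and 49 controls.

**Microbiome.** 300 OTUs in 19 guilds (sizes ≥ 3). Per-sample guild
factors F ~ N(0, 0.6²) drive member log-abundances
log aᵢ = μᵢ + λᵢ F_g(i) + ε, with baseline μᵢ ~ N(0, 2.2²) (chosen to put
control-group Shannon near 3.3 nats and roughly 180 of 300 OTUs past the
abundance/prevalence filter at 50 k depth — with a heavy-tailed composition
those two quantities trade off against each other), member loadings
λ ~ U(0.7, 1.1) and OTU noise sd 0.4. Two guilds are depleted and one
enriched in disease: ±guild_effect (default 2) log₂ units in severe
samples, halved in moderate samples. Severity additionally sharpens the
composition (proportions raised to the power 1 + 0.35·severity), the
generator's mechanism for severity-linked evenness and richness loss.
Counts are multinomial at depth ~ LogNormal(ln 50 000, 0.3). The phylogeny
joins guild members first, then guild roots, by random coalescent-style
pairing with Exp(1) branch lengths, making UniFrac sensitive to guild
shifts. Taxonomy draws genus labels from a domain-typical pool.

**Prognostic markers.** Five mid-abundance OTUs from unaffected guilds are
designated prognostic; their guild loading is reduced to 0.15 so the
outcome signal is carried by the taxa themselves rather than by correlated
guild-mates (and so these markers, which cluster arbitrarily, cannot
dominate a guild's CAG abundance). Poor 6-month outcome (mRS > 2) is
Bernoulli from a logistic model on the markers' standardized log relative
abundances with log-odds −3.0 (primary, protective) and ±1.5
(secondaries), the intercept calibrated by root-finding so the expected
poor-outcome fraction is 0.36.

**Metabolomes.** 8 modules per compartment (fecal 300 metabolites, serum
380 on a 70-sample subset), ~10 % unassigned noise metabolites. Each of
the three affected guilds is paired with one disease module whose latent
is shifted by ±0.8·severity in the guild's direction and coupled to the
guild factor with coefficient +0.8; pairing the signs this way keeps the
guild-factor and severity components of the induced CAG-module correlation
from cancelling. Three further modules couple to unaffected guilds with
alternating ±0.8 and no shift; the rest are noise. Metabolite log₁₀
intensity = base + loading × module latent + noise (loadings 0.6-0.95,
20 % negative), with 2 % missingness injected. Pathway annotation plants
three enriched pathways drawn mostly from disease-module members.

**Cytokines and relapse.** 15 log-normal channels on the serum subset;
nine are elevated by 0.5·severity log₁₀ units and coupled to guild factors
(0.25). Relapse times are exponential with rate 0.03/month in the
above-median-Shannon half of patients and 2.7× that below the median,
censored at 6 months. NEOS is binomial with mean tied to the outcome; age,
sex and consciousness disturbance are drawn with severity-linked rates.

All draws descend from `CohortConfig.seed` through stage-specific
`SeedSequence` children, so identical configs are bit-identical.

**What the generator does not emulate.** Raw reads and sequencing error,
chimeras, batch and run-order effects, LC-MS spectral artifacts,
compositional zero-inflation beyond multinomial sampling, diet and
medication covariates, longitudinal remission sampling, and inter-subject
covariance structure beyond the guild/module factors. Passing recovery
tests therefore shows the estimators work when their generative
assumptions hold at realistic sizes and noise levels — not that real
cohorts of this size will yield equally clean recovery.

## Validation design and problem sizes

The acceptance suite checks, in order: exact agreement with brute-force
oracles (UniFrac branch enumeration on 5-leaf trees, exhaustive label
enumeration for ANOSIM/PERMANOVA at n = 6, midrank-Pearson Spearman,
exhaustive hypergeometric overlap enumeration, Mann-Whitney vs trapezoid
AUC, the 2×2 cross-product odds ratio, closed-form BH); seeded estimator
recovery (SparCC ±0.1 at n = 500/50 components; Cox log-HR within 10 % of
log 2.7 at 2 000 per group; PLS-DA null Q² ≤ 0.05); calibration (NB-Wald
type-I error in [0.03, 0.07] at 500 features and n = 30/30, power ≥ 0.8
for 4-fold changes, network discovery fraction under the null within
binomial slack of nominal over 200 replicates); and planted-structure
recovery on the default cohort (guild ARI, module ARI, eigen-metabolite
fidelity, signed coupling edges, MD-index directions, prognostic marker
rank and held-out AUC). These sizes keep the full suite and the
`scripts/acceptance.py` run in the minutes range on a single core while
leaving each check comfortably powered.

## Known limitations

- Per-feature ML dispersion is noisier than shrinkage estimators at small
  n; the significance rule compensates with the joint q/LFC threshold.
- The static module cut, although validated here, is less adaptive than
  dynamic tree cut on modules of very heterogeneous tightness.
- SparCC pseudo p-values are bootstrap sign-crossing frequencies, not the
  permutation p-values of the original algorithm's companion tooling.
- The exact Spearman p is enumerated only for n ≤ 9 (cost grows as n!).
- Cox and logistic fits use Wald inference; profile-likelihood intervals
  are not provided, and separation in the logistic model is an error
  rather than a penalized fit.
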