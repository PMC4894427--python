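# Methods

## The study design being modeled

The package analyzes a replicated comparative metabolomics design:
log2-scale intensities of a few hundred metabolites measured in liver
tissue from three primate species (human, chimpanzee, rhesus macaque),
six individuals per species, three technical replicates per individual
(54 measurement columns). Matched enzyme gene-expression data come from
the same eighteen individuals, and a KEGG-style tripartite annotation
links compounds to reactions, reactions to enzyme genes, and compounds
to pathways. All analyses treat the metabolite (or gene) as the unit of
inference and the individual as the unit of biological replication;
technical replicates carry no degrees of freedom for species contrasts.

## Mixed-model differential concentration

For one metabolite, with individual i of species s and replicate j:

    y_ij = mu_s + u_i + e_ij,   u_i ~ N(0, sigma_ind^2),
                                e_ij ~ N(0, sigma_rep^2).

Fitting is maximum likelihood, not REML: the pairwise tests compare
models that differ in their fixed effects, and REML likelihoods are not
comparable across fixed-effect structures. The likelihood is profiled
over the variance ratio lambda = sigma_ind^2 / sigma_rep^2: at fixed
lambda the species means have a closed generalized-least-squares form
(individual means weighted by n_i / (1 + lambda n_i)) and the residual
variance a closed profile form, so the optimization is one-dimensional
— a coarse grid on {0} ∪ logspace(-6, 4) refined by bounded Brent
search (inner tolerance 1e-12 on log-lambda). The design need not be
balanced; replicates excluded by quality control simply shrink n_i.

For each species pair the reduced model constrains that pair's two
means equal and LR = 2(l_full − l_reduced) ≥ 0 (values in (−1e-6, 0)
are clipped; anything more negative raises).

**Reference distribution.** At six individuals per species the pair
contrast behaves like a t statistic with nu = n_individuals(pair) − 2
degrees of freedom, so the null LR has mean ≈ nu/(nu−2) rather than 1
and a plain chi-square(1) lookup is anticonservative (measured type-I
rate 0.074 at nominal 0.05 over 1000 null metabolites). The package
therefore applies a Bartlett-type correction — the LR is divided by
nu/(nu−2) before the chi-square(1) tail lookup — which restores
calibration (0.053; Kolmogorov–Smirnov uniformity p = 0.70 in the same
experiment, recomputed by the acceptance suite each run). The LR
statistic itself is reported uncorrected and is what the network and
enzyme analyses consume.

**Multiplicity and patterns.** Benjamini–Hochberg runs separately
within each species-pair family, since per-pair discovery counts are
the quantity of interest. A metabolite is human-specific when
q_HC < 0.05, q_HR < 0.05 and q_CR > 0.1; chimp- and rhesus-specific by
symmetry; the thresholds are arguments (`sig`, `ns`). Direction is the
sign of the fitted mean difference from the full model. Constant
metabolites are reported with LR = 0, p = 1 rather than dropped; the
residual variance is floored at 1e-10.

The same machinery computes enzyme differential expression from a raw
genes × individuals matrix: with one observation per individual the
random intercept is absorbed into the residual and the test reduces to
a Gaussian fixed-effects LRT.

## Preprocessing

Quantile normalization forces every measurement column onto the
across-column mean of order statistics; ties receive the mean of the
reference values at the tied ranks. Outlier replicates are flagged by
(a) mean Pearson correlation with co-replicates of the same individual
below 0.8 — applied iteratively per individual so one corrupt replicate
cannot drag its siblings under the threshold — or (b) a PC1/PC2 score
more than 6 median-absolute-deviations from the component median. The
outlier PCA runs on the species-centered matrix so that genuine
species separation (usually the leading components) is not mistaken for
an artifact; and 6 MADs ≈ 4 sigma under normality, chosen because a
4-MAD cut (≈2.7 sigma) would flag roughly one clean measurement per 54
by chance alone. Normalization is re-run after exclusion so the
reference distribution is not contaminated.

Artifact components are selected among the top five PCs of the
species-centered matrix: batch-associated (one-way ANOVA F-test
p < 0.05) and species-unassociated (p ≥ 0.05). PCA of the raw matrix is
not used for selection because batch and species variance are of
comparable size in this design and PCA rotates the two into mixed
components that fail both filters. The selected measurement-space
directions are projected out of every metabolite profile (row means
restored). The number of removed components is data-driven, not fixed.

**A caveat on quantile normalization.** When a large fraction of
metabolites genuinely shift between species, rank distortion induces
false differences in the remaining ones — especially when shift signs
are imbalanced, which moves whole column distributions. The generator
therefore plants sign-balanced shifts, and the calibration/recovery
checks of the acceptance suite run on outlier-cleaned but
un-normalized data so they measure the test, not the normalizer. On
real data this caveat argues for inspecting the sign balance of
discoveries.

## Synthetic-data generator

    y[m, i, j] = mu_m + beta[m, s(i)] + u[m, i]
                 + c * sigma_ind * sum_{r in R(m)} f[r, i] / sqrt(|R(m)|)
                 + batch * v_m * s_b(j) + eps[m, i, j]

Defaults (chosen once as the study conditions): 200 metabolites,
6 individuals/species, 3 replicates; baseline means N(10, 2.0^2) log2
units (a spread large enough that replicate columns of one individual
correlate well above the 0.8 QC threshold while a corrupted replicate
falls clearly below); sigma_ind = 0.3, sigma_rep = 0.2 log2 units;
species effect 2.0 log2 units on round(0.15·n/2) metabolites per
lineage (disjoint sets, so each species pair carries ≈ 0.15·n planted
differences), signs alternating for compositional balance.

Coupling: each reaction carries a latent per-individual factor
f ~ N(0,1) shared by its compounds; the compound's individual effect is
split so total individual-level variance stays sigma_ind^2 while two
degree-1 compounds sharing a reaction correlate at c^2 (c = 0.8 by
default). Enzyme driving: 10% of enzyme genes get a human-lineage
expression shift of 1.5 log2 units (sd 0.25; alternating signs) and
their reactions' compounds inherit a same-sign 1.5 log2-unit human
shift — giving the cutoff-sweep analysis a recoverable monotone signal.
Batch is the replicate index; the batch term is a rank-1 component with
per-metabolite susceptibility 0.4 + |N(0, 0.6)| (every analyte drifts
with run order, to varying degree) and amplitude 0.5. Three outlier
replicates (at most one per individual) receive N(0, (10·sigma_rep)^2)
noise on all metabolites.

The network draws compound degrees from a geometric body (mean 1.7)
plus a 3% high-degree tail crossing the 20-reaction connectivity
cutoff; 200 reactions, each with at least one compound and one enzyme
gene (15% get a second enzyme); pathways are unions of the compound
sets of 2–6 reactions.

What the generator does *not* emulate: missing values and detection
limits, intensity-dependent variance, correlated batch and species
structure, dietary covariates, phylogenetic structure beyond a star
topology, and any raw-spectrum artifacts. Passing recovery tests shows
the estimators work under the stated generative model, not that real
liver data satisfy that model.

## Pathway scores

Fisher's combined probability, X² = −2 Σ ln p over a pathway's measured
members against chi-square with 2k df, per species pair, on raw
(unadjusted) p-values — Fisher's method assumes uniform nulls, which
q-values are not. Metabolites in several pathways contribute to each;
no overlap correction. Same-reaction correlation violates the
independence assumption and is reported as a caveat, not corrected.
Pathways with fewer than 2 measured members are skipped. The
human-specific flag mirrors the metabolite-level dual-threshold rule on
BH-adjusted combined p-values; ranking is by the smaller human-pair
combined p.

## Network statistics

Connectivity is the number of distinct reactions per measured
metabolite; degree ≤ 20 is "low" (the boundary goes to the low group;
configurable). The low-vs-high comparison uses the difference in group
median LR with a one-sided permutation test (group labels reshuffled,
sizes preserved).

Pair correlations are Pearson (Spearman by flag) across the individuals
of each species separately, after averaging replicates per individual.
"Different-reaction" pairs are restricted to network-annotated
metabolites sharing no reaction, so the contrast is not confounded by
annotation status. The coupling test reports percentile-bootstrap 95%
CIs (B = 1000) of each group's median and a permutation p built by
relabeling metabolite identities on the network — permuting rows and
columns of the same-reaction mask against the fixed correlation matrix,
which preserves both the network topology and the empirical correlation
structure. All permutation p-values use the add-one convention
(1 + #{perm ≥ obs}) / (B + 1) and are seed-controlled.

Direction concordance keeps pairs where both members (or, in the
`at_least_one_dc` mode, at least one) are DC at q < 0.05; a pair is
concordant when both direction signs are equal and nonzero. The 2×2
same/different-reaction × concordant/discordant table is tested with a
one-sided Fisher exact test; proportions carry bootstrap CIs. In null
checks the binomial band for the different-reaction proportion uses the
number of distinct metabolites entering pairs as the effective sample
size: pairs sharing a member are dependent, and the pair count would
overstate the information.

## Enzyme–metabolite integration

Associations are enzyme–metabolite pairs sharing at least one reaction,
restricted to entities with both data types; multiple shared reactions
collapse to one association. Stratifying **by metabolite**: metabolites
above the cutoff (top-N by DC LR, or q < 0.05 in q-mode) are "DC";
an enzyme joins the DC group only if all its associated metabolites are
DC, the non-DC group only if none are, and is excluded otherwise
(exclusion operates at the metabolite level; a reaction-level variant
is a flag). The group comparison of enzyme DE LR uses the difference in
group means — the location underlying the companion Welch t-test, and
robust to the null co-enzymes that legitimately land in the DC group
because they share reactions with a driver — plus a one-sided
permutation test over enzyme relabelings and bootstrap CIs; medians are
reported alongside. Stratifying **by enzyme** is the mirror image with
metabolite DC LR as the response. The cutoff sweep repeats the
comparison over a cutoff grid (default top-N ∈ {25, 50, 100, 200},
scaled down when fewer entities exist) and summarizes the trend with an
OLS line over cutoff rank and the Spearman correlation of difference
against stringency (stringency = smaller N). Because the per-cutoff
differences share data (nested groups), the naive OLS p on those points
is anticonservative — incidental noise tilts the whole sweep coherently
(measured 13–20% false significance at nominal 0.05 under the null).
The sweep therefore also reports a permutation-calibrated trend p:
entity responses are permuted with the group structure held fixed, the
sweep slope recomputed each time, and the one-sided add-one fraction
taken in the planted direction (difference growing with stringency).
The OLS line remains the descriptive fit; the permutation p is the
inferential quantity.

## Pipeline, seeds, problem sizes

`metadiv.pipeline.run_all` chains simulate/load → preprocess → DC →
pathways → network → enzyme stages; one top-level seed derives
per-stage seeds via `numpy.random.SeedSequence.spawn`, so a single
integer reproduces every permutation and bootstrap draw. The test suite
and `scripts/acceptance.py` use moderate problem sizes chosen as
adequate for the properties they check: 1000 metabolites for type-I
calibration, 100 seeds × the default study for coupling recovery,
20–30 seeds for the enzyme-link recovery and null checks, and B = 199
permutations inside multi-seed loops (B = 1000 for single headline
runs).

## Known limitations

- The Bartlett factor nu/(nu−2) matches the null mean of the pair
  contrast; it is exact neither for very unbalanced designs nor in the
  sigma_ind → 0 limit (where it is mildly conservative).
- Fisher pathway combination ignores within-pathway correlation, which
  the coupling analysis shows is real; pathway p-values are evidence
  summaries, not calibrated tests under coupling.
- The coupling permutation null treats metabolite identities as
  exchangeable on the network; degree–variance relationships in real
  data could break exchangeability.
- Quantile normalization distorts under dense, sign-imbalanced true
  differences (see above).
- Sex is carried as metadata only; the 6-individuals-per-species design
  is underpowered for within-species covariates.
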