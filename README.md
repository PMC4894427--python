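# metadiv

Comparative liver metabolomics across three primate species — human,
chimpanzee, and rhesus macaque — as a tested, reusable analysis pipeline.
The package targets the study design of replicated GC-MS metabolite
profiling: a log2 intensity matrix of a few hundred metabolites over six
individuals per species with three technical replicates each, matched
enzyme gene-expression data from the same individuals, and a KEGG-style
compound–reaction–enzyme network with pathway memberships.

## What it computes

**Differential concentration (DC).** Each metabolite is fitted with a
random-intercept mixed model on the log2 scale,

    y_ij = mu_s(i) + u_i + e_ij,   u_i ~ N(0, sigma_ind^2),  e_ij ~ N(0, sigma_rep^2),

by maximum likelihood (profile likelihood over the variance ratio with
closed-form GLS species means). For each species pair the reduced model
constrains the pair's means equal and the likelihood-ratio statistic
`LR = 2(l_full − l_reduced)` is referred to a Bartlett-corrected
chi-square with 1 df. Benjamini–Hochberg FDR is applied within each
species-pair family; a metabolite is *human-specific* when q < 0.05
against both other species while the chimpanzee–rhesus pair shows no
evidence of difference (q > 0.1).

**Pathway evidence.** Fisher's combined probability,
`X² = −2 Σ ln p_i ~ chi²(2k)`, over a pathway's measured members, per
species pair, with a pathway-level analog of the dual-threshold rule.

**Network statistics.** Metabolite connectivity (distinct reactions,
split at 20 into low/high groups with a one-sided permutation test);
within-species Pearson correlation of same-reaction versus
different-reaction metabolite pairs across individual means, with
bootstrap CIs on the group medians and a permutation null that relabels
metabolite identities on the network; cross-species direction
concordance of DC pairs with a one-sided Fisher exact test.

**Enzyme–metabolite integration.** Enzymes and metabolites are linked
through shared reactions; stratifying metabolites by DC status (enzymes
spanning both groups excluded) compares enzyme differential-expression
LR between groups, and the symmetric stratification by enzyme DE status
compares metabolite DC LR, each with Welch t, permutation p, bootstrap
CIs, and a cutoff-stringency sweep with an OLS/Spearman trend summary.

**Synthetic data.** `metadiv.simulate` generates all four inputs with
planted lineage-specific shifts, reaction-coupled metabolite pairs,
enzyme-driven shifts, a run-order batch component, and heavy-noise
outlier replicates — together with a ground-truth table, so every stage
of the pipeline is testable for calibration and parameter recovery.

## Worked example

```python
import metadiv as md

data = md.simulate(md.SimConfig(seed=11))          # synthetic study
clean, samples, qc = md.preprocess_pipeline(data.abundance, data.samples)
results = md.run_dc(clean, samples)
print(results.summary())
```

prints

```
Differential concentration (mixed-model LRT, FDR sig=0.05, ns=0.1)
  human vs chimpanzee: 62 metabolites at q<0.05
  human vs rhesus: 61 metabolites at q<0.05
  chimpanzee vs rhesus: 32 metabolites at q<0.05
  human_specific: 38
  chimp_specific: 14
  rhesus_specific: 13
```

i.e., with the default generator (55 planted human–chimpanzee
differences and 30 chimpanzee–rhesus differences among 200 metabolites
at this seed) the mixed-model LRT recovers the planted counts closely,
and the dual-threshold rule labels the human-lineage shifts
human-specific (40 planted). The QC step excluded exactly the three
planted outlier replicates and regressed out the batch-associated
principal component before testing.

The same analysis runs end to end from the shell:

```sh
metadiv pipeline --config config.yaml       # simulate -> ... -> summary.txt
metadiv simulate --out-dir sim --seed 11    # or stage by stage
metadiv dc-test --abundance sim/abundance.tsv --samples sim/samples.tsv \
    --out-prefix results/dc
```

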