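# dysbiosis

Downstream analysis of paired lesional / peri-lesional 16S rRNA genus count
tables, built for skin-microbiome studies in which every subject contributes
one diseased-site and one matched control-site swab (the motivating use case
is facial hyperpigmentation such as melasma, but nothing in the code is
specific to it). Starting from a counts matrix, sample metadata and an
optional clinical endpoint table, the package computes:

- **Community profiling** — prevalence/count filtering, relative abundances,
  Shannon alpha diversity with a paired Wilcoxon signed-rank contrast,
  Bray–Curtis beta diversity with a paired-permutation PERMANOVA,
  core-microbiome sets (prevalence ≥ 90% per site) and common/unique genus
  partitions, and per-genus paired differential abundance with
  Benjamini–Hochberg correction.
- **Co-occurrence networks** — per site, a sparse conditional-dependence
  graph via the centered log-ratio (CLR) transform, Meinshausen–Bühlmann
  neighborhood selection over a log-spaced ℓ₁ path, and StARS stability
  selection; edges carry subsample selection frequencies.
- **Network comparison** — node/edge counts, per-taxon degree contrasts and
  hub reports, and fragility = 1 − AUC of the largest-connected-component
  curve under targeted (highest-degree-first) or random node removal.
- **Subtyping** — per-subject lesion − peri-lesion difference profiles over
  the prevalent genera (≥ 60% of all samples), subject × subject Pearson
  correlation, hierarchical clustering on 1 − r with a coherence-guided cut
  (clusters must have ≥ 3 members and within-cluster mean r ≥ 0.6; the rest
  form the singleton/doublet bucket Cs), severity (mMASI) ANOVA + Tukey HSD
  across subtypes, and per-genus cluster enrichment.
- **Clinical association** — lesion vs peri-lesion endpoint contrasts
  (paired t on optionally log-transformed values, the balanced two-level
  reduction of the subject-random-intercept mixed model) and Pearson
  correlations of clinical parameters against genus difference profiles.

A first-class **synthetic-cohort generator** makes the whole pipeline
verifiable without any sequencing data: peri-lesion communities are
logistic-normal–multinomial draws whose latent Gaussian carries a planted
sparse dependence graph; lesion communities add subtype-specific latent
shifts (default: three subtypes of 22/7/7 subjects plus 4 unassigned, out of
40); clinical endpoints are linearly coupled to chosen genus differences at
target Pearson correlations. The planted edge set, subtype labels and
coupling coefficients are returned for recovery scoring.

## Core statistics

For a composition p₁…p_K, Shannon diversity is H = −Σ pᵢ log pᵢ and the CLR
transform is clrᵢ = log xᵢ − (1/K) Σⱼ log xⱼ with x = counts + 1. For each
taxon j, neighborhood selection solves lasso regressions
β̂ʲ(λ) = argmin ½n⁻¹‖xⱼ − X₋ⱼβ‖² + λ‖β‖₁ on standardized CLR columns; an
edge (i, j) appears when either β̂ʲᵢ or β̂ⁱⱼ is nonzero (OR rule). StARS
draws N = 50 subsamples of size b = min(⌊10√n⌋, ⌊0.8n⌋), computes per-edge
selection frequencies θ̂, and picks the smallest λ whose monotonized
instability D(λ) = mean 2θ̂(1 − θ̂) stays ≤ β = 0.05. Network fragility is
1 − ∫ LCC(f) df over the fraction f of nodes removed.

## Worked example

Generate a synthetic 40-subject cohort and run the subtyping stage:

```bash
$ dysbiosis simulate --out demo --seed 7
wrote synthetic cohort to demo
$ dysbiosis validate --counts demo/counts.tsv --meta demo/meta.tsv --clinical demo/clinical.tsv
80 samples x 150 taxa; 40 complete pairs; 0 rejects
$ dysbiosis profile --counts demo/counts.tsv --meta demo/meta.tsv --out demo/profile
alpha diversity Wilcoxon statistic=61 p=2.809e-06
$ dysbiosis subtype --counts demo/counts.tsv --meta demo/meta.tsv --clinical demo/clinical.tsv --out demo/subtype
severity ANOVA F=12.59 p=8.825e-06
       size    mean_r
label
C1       23  0.807897
C2        7  0.932900
C3        5  0.668168
Cs        5  0.153524
```

Reading the output: the planted lesional shifts depress Shannon diversity in
lesions (paired Wilcoxon p ≈ 3·10⁻⁶); the difference-profile clustering
recovers three coherent subtypes (within-cluster mean pairwise Pearson r of
0.81/0.93/0.67, all above the 0.6 floor) plus five unassigned subjects, and
the planted severity gradient across subtypes is visible in the mMASI ANOVA
(F = 12.6, p ≈ 9·10⁻⁶). Full runs (`dysbiosis run --config cfg.yaml`)
execute validate → profile → network (per site) → compare-nets → subtype →
associate and write a machine-readable report with per-stage output digests;
the same config, inputs and seed reproduce every artifact byte for byte.

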