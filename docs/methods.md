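# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults and the numerical choices. It describes what the code does and
why; every empirical figure mentioned is one the test suite or
`scripts/acceptance.py` computes at run time.

## Data model and filtering

The pipeline starts at a samples × taxa integer count table (TSV with
taxa as rows, or BIOM v1 "rich" JSON) with a ranked lineage string per
taxon, and a metadata table assigning each sample to a subject and a site
(`lesion` / `peri_lesion`). OTU-level tables are agglomerated to genus by
summing counts that share a genus label; lineages truncated above the genus
collapse to a placeholder named by their deepest resolved rank (e.g.
`o__Lactobacillales_unresolved`) rather than being dropped — such
placeholders can be biologically meaningful nodes, and discarding them would
silently delete community structure. Agglomeration conserves per-sample
totals exactly.

Two prevalence filters with different jobs:

- **Network filter** (default: present in ≥ 40% of the site's samples AND
  total count ≥ 10) — applied per site before network inference, where rare
  taxa produce unstable regressions.
- **Profile filter** (default: present in ≥ 60% of *all* samples) — defines
  the "prevalent genera" whose paired differences feed subtyping and
  clinical association.

"Present" means count > 0; prevalence thresholds use a ceiling
(`⌈q·n⌉` samples), so "at least 40%" is interpreted inclusively. The core
microbiome per site uses prevalence ≥ 90% (inclusive).

## Paired contrasts

Alpha diversity is the Shannon index in nats (base-2 available). Site
contrasts of diversity and of per-genus relative abundances use the
two-sided Wilcoxon signed-rank test on per-subject differences: exact null
for ≤ 25 nonzero differences without ties, normal approximation with
continuity correction otherwise; zero differences are dropped (Wilcoxon
convention), and an all-zero difference vector reports p = 1 with a warning.
The test is deliberately nonparametric: relative abundances are bounded,
skewed and zero-inflated. A paired t is available for endpoint contrasts
(below). Genus-level p-values get Benjamini–Hochberg q-values across the
tested genera.

Beta diversity is Bray–Curtis on relative abundances. The PERMANOVA
pseudo-F is permuted **within subject**: each subject's pair of site labels
is independently swapped or kept (999 permutations, seeded), because
exchangeability in a paired design holds within subject only. Free
permutation would mix between- and within-subject variation and inflate
power. The permutation p includes the observed statistic in the null set
((hits + 1)/(n_perm + 1)).

## Network inference

Counts + 1 are CLR-transformed; conditional dependence is estimated by
per-taxon lasso regressions (Meinshausen–Bühlmann neighborhood selection)
on standardized CLR columns, over a 20-point log-spaced penalty path from
λ_max (the largest absolute column correlation, at which the graph is empty
by the lasso KKT conditions) down to λ_max/100. Edges use the OR rule by
default (AND available). Constant columns are excluded with a warning.

StARS draws N = 50 row subsamples without replacement of size
b = min(⌊10√n⌋, ⌊0.8n⌋), re-estimates the path on each, and computes the
edge-selection instability D(λ) = mean over taxon pairs of 2θ̂(1−θ̂).
D is monotonized from the sparse end by a running maximum and the selected
λ* is the smallest penalty with monotonized D ≤ β = 0.05 — the densest graph
that is still reproducible under subsampling. If no penalty qualifies the
densest graph is returned with a warning. Neighborhood selection was chosen
over the graphical lasso because it is the standard default for this class
of microbiome network methods and markedly cheaper at this scale; all path
and StARS parameters are exposed in the run config. Per-edge selection
frequencies at λ* are kept as stability scores.

Benchmark (recomputed by `scripts/acceptance.py`): on planted chain graphs
(30 taxa, 80 samples, logistic-normal counts) the selected network's edge
set reaches precision ≈ 0.7–0.85 and recall ≈ 0.5–0.6 averaged over 10
seeds. StARS errs toward precision by design: it keeps only edges that
reappear across subsamples.

## Network comparison and fragility

Headline node counts exclude isolated nodes: two networks inferred over the
same filtered taxon set differ in "nodes" only if orphans are excluded, and
orphan counts are reported separately. Degree comparison joins per-taxon
degrees over the union of node sets (absent taxon → degree 0, flagged) and
reports the top-10 hubs per network.

Robustness curves remove the initially non-isolated nodes one at a time —
targeted: current highest degree, ties broken lexicographically by taxon id
for determinism; random: uniform orders averaged over 100 seeded replicates
— recording the largest-connected-component size as a fraction of the
initial non-isolated count. Fragility is 1 − AUC (trapezoid over the
fraction-removed grid, including the starting point). The curve is monotone
non-increasing by construction, a complete graph K_n has AUC exactly ½, and
hub-dominated graphs (stars) are maximally fragile under targeted attack —
these closed forms anchor the tests. The underlying study plots a fragility
panel without defining its metric; 1 − AUC of the attack curve is the
standard robustness construct and is documented here as this package's
definition.

## Subtyping

Difference profiles are lesion − peri-lesion relative abundances computed on
the full genus table (so each subject's unfiltered difference vector sums to
zero) and then column-subset to the prevalent genera. Subjects are compared
by Pearson correlation of these profiles; constant profiles yield undefined
correlations, recorded as missing, excluded from within-cluster means, and
entered into the clustering distance as 1 (r = 0).

Clustering is agglomerative on distance 1 − r (complete linkage by default;
average/single available). Every merge height is a candidate cut. A cluster
*qualifies* at a cut if it has ≥ 3 members (singletons and doublets belong
in Cs) and within-cluster mean pairwise r ≥ r_min = 0.6. The cut maximizes
the **number of subjects covered by qualifying clusters**, ties resolved
toward the larger height. An earlier formalization — maximizing the *count*
of qualifying clusters — proved self-defeating: complete-linkage children of
a coherent cluster are at least as coherent as their parent, so the finest
fragmentation into size-3 pieces always won and planted subtypes were
shredded (ARI ≈ 0.4 vs ≈ 0.84 for the coverage rule). Coverage maximization
is the precise form of "cut as high as the coherence floor allows".
Qualifying clusters are labelled C1, C2, … by decreasing size; everyone
else is Cs. r_min = 0.6 sits just below the smallest within-cluster mean R
the motivating study reports (≈ 0.647), and min_cluster_size = 3 encodes
its grouping of singletons and doublets.

Severity ANOVA is one-way across {C1…Ck, Cs} with Tukey HSD post-hoc
(groups of size 1 excluded with a warning; zero within-group variance
reported as p < 1e-12). Per-genus enrichment runs the same ANOVA on each
prevalent genus's difference values with BH adjustment across genera.

## Clinical association

For a balanced two-level within-subject design, the linear mixed model with
subject random intercept and site fixed effect has exactly the paired-t
estimate, standard error and n − 1 degrees of freedom for the site contrast,
so endpoint contrasts are computed as paired t-tests directly — same
inference, no iterative fit. Endpoints with skewness > 1 and strictly
positive values are log-transformed under the default `auto` policy
(contrast then estimates a log fold change).

Parameter × genus associations are Pearson correlations across subjects,
by default between the endpoint's lesion − peri-lesion difference and the
genus difference profile; endpoints recorded without a site (mMASI) use
subject-level values. Lesional-value mode is available per parameter, since
either reading is defensible. Raw p and BH q (within parameter) are both
reported; pairs with fewer than 4 complete observations are skipped with a
warning.

## Synthetic cohort generator

The generator is the package's verification instrument, so its mechanics
mirror the assumptions of the inference stages:

- **Latent dependence.** A symmetric positive-definite precision matrix on a
  planted graph (chain, hub, or Erdős–Rényi with density 0.04 by default;
  off-diagonal weight 0.3, diagonal lifted by |λ_min| + 0.5), inverted and
  rescaled to unit marginal variances. Logistic-normal + multinomial
  observation makes graph recovery a well-posed test for the CLR + lasso
  stage (a Dirichlet-multinomial would have no graph to recover).
- **Rank-abundance skew.** Latent means decay as a power law with exponent
  1.3 (top genus ≈ 1/3 mean share, as for a sebaceous-skin dominant such as
  *Cutibacterium*), with an extra linear log-scale decay of 0.12/rank beyond
  rank 40 so low-ranked genera drop below detection in many samples and
  prevalence filters act as they do on real tables. A pure geometric decay
  steep enough for the same dominance would silence all but ~30 taxa.
- **Subtypes.** Defaults: C1/C2/C3 at 55/17.5/17.5% of subjects (22/7/7 of
  40) plus 10% unassigned. Each subtype shifts five taxa (one top-4 genus
  each, alternating signs) by δ = 2.0 on the latent log scale; lesion
  latents add independent N(0, 0.4²) noise. These two magnitudes were set
  so the planted within-subtype profile correlations span ≈ 0.65–0.88 —
  the scale of within-cluster coherence the motivating study reports — and
  the cohort-level mean pairwise r lands near 0.15.
- **Clinical coupling.** For a target correlation r against genus difference
  d, the endpoint difference is β·d + ε with β = sign(r) and
  σ_ε = |β|·sd(d)·√(1−r²)/|r|, so the population correlation equals r
  exactly; defaults plant r = 0.48 (TEWL ~ *Actinomyces*), −0.40 and 0.40.
  mMASI is subject-level Gaussian with subtype means 7.5/8.7/9.8 (Cs 8.2)
  and SD 1. Read depths are uniform on 10,000–50,000.

Everything is deterministic under the config seed. What the generator does
*not* emulate: sequencing error and chimeras, strain-level structure,
compositional zeros from library-prep dropout (zeros arise only from
sampling depth), covariance between clinical endpoints, and longitudinal
sampling. Passing recovery tests therefore demonstrates correctness of the
downstream machinery under the stated generative assumptions, not
performance on any particular real dataset.

## Pipeline, seeds and determinism

`run_pipeline` executes validate → profile → network (both sites) →
compare-nets → subtype → associate, writing artifacts under `out/<stage>/`
and a report with per-stage SHA-256 digests, parameter echo, captured
warnings and wall-clock. One global seed is fanned out as
`(seed·10007 + k) mod 2³¹` with a fixed counter k per randomized stage
(beta permutations, per-site StARS, robustness replicates), so stages are
individually reproducible. Floats are written with a fixed `%.10g` format;
two runs with the same config, inputs and seed are byte-identical.

## Verification problem sizes

The self-checks use: 10 seeds for chain-graph recovery (30 taxa, 80
samples), 20 seeds for subtype ARI, 200 seeds each for the null severity
type-I rate, severity power and association detection, and two full
pipeline runs for determinism. These sizes give stable rates (binomial SE
≤ ~3.5 points at 200 draws) while keeping the whole verification suite in
the minutes range on a single CPU.

## Known limitations

- The Wilcoxon/paired-t choices assume the study's tests only where the
  underlying report is silent; printed p-values from the original analyses
  are not reproducible from summary data and are not targeted.
- Baseline-covariate adjustment for endpoints is out of scope (baselines
  are not part of the data model).
- No UniFrac or other phylogeny-aware metrics (no tree in the data model),
  and no rarefaction by default (an even-depth subsampler is provided for
  sensitivity analysis only).
- StARS instability is estimated from 50 subsamples; on small cohorts the
  selected λ* can sit at the warned densest-graph fallback when no penalty
  is stable.
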