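# Methods

## Design and data model

The pipeline compares two tissues (root and shoot apical meristem) within
each of two species, then compares the species to each other at the
GO-term and orthologue level. Input is a gene-level integer count table per
species (featureCounts dialect) with sample metadata (species, tissue,
replicate), a gene→GO annotation table, a strict 1:1 orthologue map, and
optionally a phenotype table. Counts are assumed to be 3'-tag (MACE-style):
one counting region per transcript, so no transcript-length correction is
applied anywhere.

## Normalization

Between-sample scaling uses TMM. The reference sample is the one whose
75th percentile of count fractions is closest to the across-sample mean
(the edgeR convention); genes with a zero count in either member of a pair
are excluded from M-value computation (the log ratio is undefined there);
M-values are doubly trimmed — 30% of each M tail, 5% of each A tail, rank
boundaries `[floor(n·t)+1, n+1−(floor(n·t)+1)]` — and averaged with
inverse delta-method variance weights; factors are rescaled to geometric
mean 1. Both trim fractions are configurable. Expression values are CPM
over the effective library size (library size × factor). The
implementation is validated against edgeR's `calcNormFactors` on frozen
fixtures.

## Replicate QC

Concordance is reported as all pairwise Pearson correlations within each
species × tissue group. Correlations are computed on log2(CPM+1) by
default. This choice is load-bearing: for NB counts with quadratic
overdispersion φ, multiplicative noise caps the linear-scale correlation of
perfect replicates at 1/(1+φ) no matter how large the biological signal is
(≈ 0.95 at φ = 0.05), while the log scale measures concordance relative to
the across-gene signal variance. Pairs below `min_r` (default 0.9) are
flagged, never removed; groups with fewer than two replicates are skipped
with a warning.

## Differential expression

Each gene is modelled as NB with log link, an offset equal to the log
effective library size, and a two-level group factor; replicates enter as
independent observations (a deliberate simplification of a mixed model —
with three pooled replicates per group there is no replicate structure left
to model as random). Variance is μ + φμ² with a single common dispersion φ
per contrast, estimated by maximizing the Cox–Reid adjusted profile
likelihood over genes with a bounded 1-D search on log φ (method-of-moments
fallback), clamped to [1e-6, 10]. Genes with zero counts in one group only
carry information through the likelihood; genes with zero counts across the
whole contrast are excluded from testing and from the adjustment
denominator, and are reported with p = 1.

The group effect is tested by a likelihood-ratio test (χ², 1 df). Because
the design is a one-way layout, the per-gene ML fits reduce to single-mean
NB fits solved by vectorized Fisher scoring across all genes at once.

The reported log fold change is descriptive: log2 of the ratio of group
mean CPMs with a 0.5 pseudocount on each side, which keeps it finite for
genes absent from one group. DEG selection uses FDR < 0.01 and
|log₂FC| > 3 (both-direction effects, hence the absolute value); p-values
are adjusted per contrast by Benjamini–Hochberg (reported as `fdr`) and
Bonferroni. Presence calls use mean CPM ≥ 1 per group by default; the
threshold is configurable because "expressed" has no canonical definition
for tag counts.

## GO expression analysis

For term *k* with member genes *i* present in the matrix, the average GO
expression within a sample group is `expr_k = Σᵢ CPM_ik / count(ik)` where
CPM_ik is the gene's mean CPM across the group's replicates (for balanced
replicates this equals averaging all replicate values directly). Genes
absent from the matrix are dropped from the member count.

Two groups are compared per term by stacking the member genes' group-mean
CPMs of both groups (2·count(ik) observations, rounded to the nearest
integer) into a two-group NB model tested by LRT. Gene identity is
deliberately not modelled — the observations are treated as exchangeable
draws from each group's expression distribution — so the test's noise term
is the between-gene spread within the term, and the common dispersion is
estimated by pooled method of moments across terms (typically ≈ e^{σ²}−1
for log-normal-like between-gene variation). A Gaussian model on log CPM
would be a reasonable alternative; the NB-on-rounded-CPM route was chosen
to keep gene-level and GO-level testing in the same model family.
Candidate terms require FDR < 0.01, |LFC| > 3 and at least 5 member genes.

Because the noise is between-gene spread, term detectability depends on
member count: var(logFC) ≈ 2φ_between/k, so at σ = 1.5 (φ_between ≈ 8.5)
and BH-adjusted significance around 1e-3..1e-4 a coherent 16-fold shift
needs roughly k ≈ 30 members. This bound drives the generator default
described below.

Cross-species comparison collects, per shared GO term, each species'
member-gene root-vs-shoot log fold changes and applies Welch's unequal
variance t-test between the two samples (a two-group Gaussian linear model
on LFC values is equivalent to a t-test; Welch guards against unequal
spread). Selection requires FDR < 0.05 and more than 2 member genes in
each species. Terms with fewer than two usable members on a side are
skipped.

DEG over-representation per term is a one-sided hypergeometric upper-tail
test of the term/DEG overlap against the tested-gene background, with BH
adjustment — a local stand-in for web-service enrichment tools, using the
annotation exactly as given (no GO-DAG ancestor propagation).

## Orthologue comparison

Pairs are joined at the raw-count level and the joined two-species table is
renormalized with its own TMM factors — the orthologue subset is its own
compositional universe, so reusing within-species factors would import
irrelevant composition corrections. Species are compared per tissue with
the same NB machinery. Classification: DEG requires FDR < 0.05,
|log₂FC| > 3 and mean CPM > 5 in *both* species; EEG requires FDR > 0.2
and across-species mean CPM > 5; DEG and EEG are mutually exclusive by
construction. A relaxed DEG variant (expression floor in *either* species)
is reported alongside, since the strict floor mostly removes pairs whose
divergence is so large that one species falls below 5 CPM. PCA of
expression matrices is column-centered SVD with a deterministic sign
convention (largest-magnitude loading positive per component).

## Phenotype statistics

Welch's t-test with Welch–Satterthwaite degrees of freedom, two-sided.
`compare_photoperiods` averages repeated readings (leaves, days) per
replicate plant before testing — the plant is the experimental unit — and
runs the four planned contrasts: photoperiod within each species, species
within each photoperiod.

## Synthetic data generator

The generator emulates the study's input side: two species with disjoint
gene-id namespaces (12,000 genes each by default), 7 vs 12 chromosomes
with random positions, a shared vocabulary of 300 GO terms with sizes
drawn log-uniformly from [1, 500], 3 replicates per tissue, and NB counts
(gamma–Poisson, common dispersion 0.05 — the tag-count dispersion is not
measurable from published figures, so it is a configured choice) around
log-normal baselines (ln-mean ln 50, ln-sd 1.5), rescaled per tissue so
each library's expected depth is 5,000,000. 30% of genes per species are
structural zeros ("unexpressed"); the fraction accepts a per-species
mapping to emulate asymmetric catalogs.

Planted effects, all recorded in a ground-truth table:

* **Gene tissue effects** — 5% of genes get a 2⁴ multiplier in one random
  tissue. The multiplier is applied on top of the baseline (the low side
  stays at baseline), so planted fold changes survive the LFC pseudocount
  even for lowly expressed genes.
* **Coherent GO shifts** — 10 terms with ≥ 30 expressed non-orthologue
  members (the detectability bound above) have all such members shifted in
  one tissue. Terms that share members share a direction (one direction
  per connected component of the overlap graph); otherwise overlapping
  terms would partially cancel each other and no term would be cleanly
  planted.
* **Orthologue divergence** — orthologue pairs inherit the species-A
  member's baseline and expression status (conserved expression), and
  ortholog genes are excluded from the gene/GO-level tissue effects; 50
  designated pairs get a 2^±5 species multiplier in one tissue.

Phenotype tables are Gaussian per group with configurable means
(defaulting to the reported chlorophyll group means), sd 2 and n = 10.

What the generator does **not** emulate: read-level artifacts (alignment,
duplicates), gene–gene correlation beyond GO-term co-shifts, tagwise
dispersion variation, batch effects, and annotation noise. Passing
recovery tests therefore shows the pipeline's statistical machinery is
correct and calibrated under the declared model, not that the biological
conclusions from any real dataset are reproduced.

## Numerical choices and edge cases

* NB fits: vectorized Fisher scoring, step clamp ±5 on the log scale,
  convergence at 1e-10; all-zero rows get β = −∞ and log-likelihood 0 by
  the 0·log 0 = 0 convention.
* Dispersion search: bounded Brent on log φ in [1e-6, 10], xatol 1e-4.
* LRT deviances are floored at 0 before the χ² tail.
* BH and Bonferroni via statsmodels/closed form; inputs outside [0, 1]
  are rejected.
* Welch test with zero variance in both groups: p = 1 on equal means,
  error otherwise.
* Degenerate PCA (constant matrix): zero variance fractions and a warning.
* Summary determinism: fixed float formatting and stable key order; the
  summary is recounted against stage files before writing.

## Problem sizes in the test suite

Functional tests run on a 3,000-gene configuration; calibration and
recovery checks use the full default conditions (12,000 genes per species)
with 20 null datasets and 10 recovery seeds, which keeps the entire suite
under half a minute on one core while leaving the Monte-Carlo margins
quoted in the tests.
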