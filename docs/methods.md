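# Methods

`magprofiler` re-implements, as a tested library, the genome-centric
analysis layer used to profile the microbiomes of H2-fed biogas-upgrading
reactors: from per-genome quality and coverage tables to draft-quality
tiers, abundance contrasts across a 2x2 temperature x H2 design,
permutation-based functional enrichment, gene-based ANI species calls,
syntroph role assignment, and category-abundance association statistics.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Quality tiers and eligibility (core_io)

Population genomes (PGs) are characterized by CheckM-style completeness and
contamination percentages. Two derived quantities:

* **MIMAG draft tier** — high-quality draft: completeness > 90% and
  contamination < 5%; medium: completeness >= 50% and contamination < 10%;
  otherwise low. The high tier is strict and the medium tier inclusive at
  its completeness boundary, following the MIMAG standard's conventions.
  Tiering is monotone: more completeness or less contamination never lowers
  the tier (property-tested).
* **Eligibility** for metabolic reconstruction: completeness > 50% AND
  contamination < 20%, both strict. Because quality is sometimes estimated
  twice (e.g. a CheckM re-run), the reader accepts an optional second pair
  of columns and applies OR logic — a PG is kept if either estimate passes.

## Coverage normalization and contrasts (abundance)

Coverage (mean per-base read depth of a PG's scaffolds in a sample) proxies
relative abundance but scales with sequencing depth, so each sample column
is multiplied by `min(read_totals) / read_total(sample)`: the shallowest
sample is the unchanged reference and within-sample ranks are preserved.

Abundance change across conditions C1 (meso pre-H2), C2 (meso post-H2),
C3 (thermo pre-H2), C4 (thermo post-H2) is expressed as six pairwise log
ratios (mean thermo/meso, mean post/pre, the per-temperature post/pre
ratios, and the per-phase thermo/meso ratios). **The logarithm is base 2**:
the tabulated contrasts -4.65 / -2.98 / -2.33 correspond to the described
25- / 8- / 5-fold changes only in base 2, and `fold_change` inverts a
contrast into a (direction, 2^|v|) pair.

Zero coverages would make ratios undefined, so a fixed pseudocount
(default 0.01 coverage units, configurable) is added to every coverage
before any ratio. The induced bias on a contrast is ~ pc/(c ln 2) for the
smallest coverage c involved; it is negligible (< 0.01) only when the
post-effect coverage is well above the pseudocount, which is why
recovery tests use baseline coverage 100.

Each contrast variable is summarized per PG by a signed SD band:
`sign(v - mean) * min(3, floor(|v - mean| / SD))` with the sample (n-1) SD
taken over the whole PG population, per variable (not pooled). Band 0
captures ~68% of a normal population (checked by simulation). PGs are
called *abundant* when normalized coverage exceeds 5 (strict) in at least
one condition; the temperature partition labels a PG meso/thermo when
|mean thermo/meso contrast| > 1 (a > 2-fold change, strict).

Partition-vs-grouping association uses the Pearson chi-square (no
continuity correction) with the odds ratio ad/bc and Woolf's 95% CI
(log OR +/- 1.96 * sqrt(1/a+1/b+1/c+1/d)); a zero cell triggers the
Haldane-Anscombe 0.5 correction for the OR/CI only, flagged in the result.

## Gene-based ANI (ani)

ANI between a PG and a reference gene set is computed one-directionally:
each PG gene is searched against the reference genes and the best hit per
gene is kept. The search is a k-mer-seeded global alignment: candidates
must share >= 1 exact 11-mer (a pure accelerator — validated against
brute-force all-pairs alignment on small instances), and candidates are
aligned globally (Biopython PairwiseAligner) with match +1, mismatch -1,
gap open 2, extend 1. Identity = matches / alignment columns excluding
terminal gaps; N never counts as a match. Ties in identity break by longer
alignment, then lexicographic reference id. A hit is an ortholog candidate
only at identity >= 70% and query coverage >= 0.5 (deliberately permissive,
configurable).

ANI is the unweighted mean of best-hit identities (a length-weighted mean
is available behind a flag); `gene_fraction` counts genes with a kept hit
over all PG genes. The species call is `ani > 95` (strict) AND
`gene_fraction >= 0.5` (inclusive), making the comparison deliberately
asymmetric — only the PG's genes need matches. An empty reference set
yields a no-comparison record, never ANI 0. On simulated references at
per-site substitution rate r, mean ANI tracks 100(1-r) within 0.5
percentage points (50 genes of >= 500 bp).

## Permutation enrichment (enrichment)

For each PG and functional category, the observed statistic N is the
number of distinct PG genes carrying the category. The null draws the same
number of genes uniformly **without replacement** from the entire
assembly's gene pool (a PG's genes are a subset of the assembly, so the
hypergeometric null is the natural one; a with-replacement binomial mode
exists behind a flag), repeated 1000 times by default with a mandatory
seed. The empirical p is the plain fraction of draws whose category count
reaches N (an add-one-corrected variant is available but off by default),
and enrichment is significant at alpha = 0.05 per test — no
multiple-testing correction by default, with Benjamini-Hochberg available
post hoc via the results table. The analytic hypergeometric upper tail is
reported alongside as `exact_p`; tests verify convergence of the sampled p
to it and ~alpha type-I error under the null. Subset sampling is
vectorized (the indices of the draw-size smallest of n iid uniforms form a
uniform random subset), chunked to bound memory.

## Role assignment (roles)

A PG's Wood-Ljungdahl (WL) pathway is *nearly complete* at >= 8 annotated
pathway genes (inclusive); the counted orthologs ship as an editable YAML
config (`data/wl_genes.yaml`). Direction is inferred from the post/pre-H2
contrast of the community the PG dominates — variable (iii) for
mesophilic-dominant PGs, (iv) for thermophilic-dominant, with dominance
decided by larger pre-H2 coverage when coverage is supplied, else by the
recorded contrast:

* contrast <= -1 (>= 2-fold decrease): SAOB candidate — raising H2 partial
  pressure makes syntrophic acetate oxidation endergonic;
* contrast >= +1 (>= 2-fold increase): homoacetogen candidate — H2 + CO2
  to acetate is favored;
* |contrast| < log2(1.5): stable, WL-bidirectional / metabolically
  flexible;
* otherwise indeterminate (reported, unlabeled).

The 2-fold and 1.5-fold defaults reproduce the published example calls and
are fully configurable, because borderline published calls are not a pure
function of the printed contrasts (a PG at +0.43 was called favored while
one at +0.55 was called stable; the defaults reproduce the latter reading
and leave the former as a documented discrepancy).

Propionate/butyrate degrader labels come from enrichment flags of the
Propanoate and Butanoate metabolism categories (significance mode,
default) or from count thresholds (count mode, for replaying published
tables whose asterisks mark enriched counts). Degrader labels may co-occur
with WL labels; the WL trio is mutually exclusive. Labels are a pure
function of (counts, contrasts, thresholds): row order never matters, and
raising the direction thresholds never adds SAOB/homoacetogen labels.

The packaged `data/pathway_counts.tsv` (35 PGs, WL/VFA pathway gene counts
with enrichment asterisks and post/pre-H2 contrasts) replays to 14 PGs
with nearly complete WL and 21 propionate/butyrate degraders among the
WL-lacking PGs.

## Association statistics (association)

Per-category regression: for each contrast variable (trait) and each
category separately, OLS of trait on (intercept, per-PG gene count,
completeness). Completeness enters as a percent-valued covariate — an
incomplete genome under-counts every category — not as a weight. Reported:
the count coefficient b and its two-sided p (the partial F with 1 df,
identically the squared t), significant at P <= 0.05 per test. Categories
are fit one at a time to avoid shared variance and over-parameterization;
constant-count categories are flagged unfittable. The fit is verified
against a closed-form normal-equations oracle to 1e-8.

Clustering: agglomerative flexible-beta via the Lance-Williams recurrence
`d(k, ij) = alpha d(k,i) + alpha d(k,j) + beta d(i,j)` with
alpha = (1-beta)/2, gamma = 0, beta = -0.25 by default (the standard
flexible-beta recommendation); since alpha_i + alpha_j + beta = 1, merge
heights are monotone. Ties break by lowest cluster-label pair. scipy has
no flexible-beta method, so the recurrence is implemented here; at beta=0
it coincides with WPGMA, which serves as an independent cross-check, and a
from-scratch oracle validates random instances. The default distance is
Euclidean on the contrast/abundance profiles (Bray-Curtis is a reasonable
alternative the caller can precompute). A cut is summarized by
R^2 = SSB/SST of the clustered values (pooled over variables); singleton
partitions give 1, one cluster gives 0, zero total SS reports 0 with a
warning.

## Synthetic communities (synthetic)

The generator emulates the study design — ~200 PGs across the four
conditions — with known ground truth:

* **Coverage**: per-PG baseline (log-normal, median 1.5 with sigma 2 in
  log2 units, so roughly a sixth of PGs cross the abundance threshold of
  5) x 2^(planted log2 effects on chosen contrast variables) x log-normal
  noise (default SD 0.25 log2 units). The emitted table is *raw* coverage,
  rescaled by distinct per-sample read totals so depth normalization is
  non-trivial and recovers the intended values exactly.
* **Genes**: counts per PG uniform in 150-250, lengths uniform in
  300-1500 bp, uniform base composition (codon structure is irrelevant to
  every statistic computed here). Categories are independent Bernoulli
  draws from background frequencies (defaults geometric between 0.5% and
  10% over 20 categories), multiplied by the planted fold for enriched
  (PG, category) pairs; infeasible folds (frequency x fold > 1) are
  rejected.
* **Quality**: completeness U(40,100)%, contamination Exponential(5)%
  clipped at 40%, so most but not all PGs pass eligibility.
* **References**: per-site substitution of a PG's genes at a controlled
  rate (always to a different base; non-ACGT sites untouched), giving
  expected identity 1 - rate for ANI validation.

Everything is driven by one mandatory seed; identical seeds give
byte-identical output files. The truth table records every planted effect.

What passing synthetic tests show — and do not. They show the estimators
invert the generative model: planted contrasts are recovered exactly at
zero noise, planted 5x enrichments of a 2% category are detected with
power >= 0.9 at ~200 genes/PG, ANI tracks planted divergence, and null
calibrations hold (type-I error ~ alpha, ~68% of PGs in SD band 0). They
do not show robustness to features of real metagenomes the generator omits:
binning chimerism and contamination leaking genes across PGs, correlated
category assignments, annotation error, strain heterogeneity, or
compositional coupling between PG abundances.

## Problem sizes and determinism

Test and acceptance runs use deliberately desk-scale configurations —
120-PG communities with ~200 genes/PG for enrichment power, 50 genes of
600-700 bp for ANI sweeps, 200-300 simulated PGs for calibration loops,
1000 permutation repetitions (p resolution 0.001) — sizes at which every
Monte-Carlo tolerance stated above is a >= 3-sigma bound. All stochastic
paths take explicit seeds; `scripts/acceptance.py --seed N` derives every
stream from N and prints each quantity it recomputes.

## Known limitations

* The ANI search is designed for gene sets of desk scale (hundreds of
  genes); it is not a replacement for whole-genome fragment-based ANI
  tools on thousands of genomes.
* Ortholog detection is one-way best hit; reciprocal-best filtering is not
  applied (the species-call contract only requires the PG's genes to have
  matches).
* The per-category regressions assume independent PGs; phylogenetic
  autocorrelation between related PGs is not modeled.
* The WL direction call reduces the H2 response to a single contrast; PGs
  whose abundance response is driven by other factors (substrate shifts,
  temperature interactions) will be mislabeled, which is why every call
  carries its evidence string.
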