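# Methods

This note documents the models and procedures `esnp` implements, the
defaults and why, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want written down.

## Linkage disequilibrium

Two-locus LD is computed from haplotype frequencies with the textbook
definitions (D, Lewontin's D', r²). Phased panels use direct counting.
Unphased genotypes use the classical EM over the double-heterozygote phase
ambiguity: only the (1,1) genotype class is ambiguous; the E step splits
it between the cis (AB/ab) and trans (Ab/aB) phases in proportion to the
current haplotype-frequency products and the M step re-counts.

* Initialization: linkage-equilibrium product of the (exactly known)
  sample allele frequencies, **plus two perturbed starts** at D = ±Dmax/2.
  The LE point is a stationary point of the likelihood whenever the
  genotype table is symmetric under allele flips, and EM started there
  stays on the D = 0 saddle; starting on both sides of zero and keeping
  the highest-likelihood fixed point removes the pathology
  deterministically.
* Convergence: largest absolute frequency change < 1e-8, max 1000
  iterations. With no double heterozygotes the first M step already
  equals direct gamete counting.
* Missing genotypes are dropped pairwise; `n_obs` records the
  chromosomes actually used. Multi-allelic sites are rejected outright
  (the pipeline restricts analysis to the two common alleles of a SNP).

What EM can and cannot recover: at n = 1,000 individuals the sampling
standard deviation of a mid-range haplotype frequency is ≈ 0.011, so no
estimator tracks the *population* frequencies to 0.02 reliably. The
meaningful accuracy statement — the one our tests make — is that EM tracks
the *realized sample* haplotype frequencies (i.e. recovers phase) to well
under 0.01 when LD is appreciable.

Proxy expansion searches ± 500 kb around each seed SNP (the era-typical
lookup bound; configurable) and keeps partners with r² ≥ 0.3, seed always
included. The strong-LD filter keeps pairs with r² ≥ 0.8 **and**
D' ≥ 0.9, both inclusive. When a pair's D' is unknown (published tables
often print r² only), the filter substitutes the algebraic lower bound
D' ≥ √r², which is exact in the sense that it can only under-claim D'.

## Independent signals

Single-linkage clustering on the graph linking two associations iff they
share a chromosome and are within 100 kb (inclusive) or have r² ≥ 0.8.
LD-augmented linkage is optional (`ld_source`); the default is
distance-only, since the independence definition is stated in kilobases.
The cluster representative is the lowest-p member (ties: lowest position,
then lexicographic id). Catalog filtering compares p-values strictly
(p < 1e-5 rejects a record at exactly 1e-5) and platforms inclusively
(exactly 100,000 assayed SNPs passes), matching the stated rules.

## Enhancer windows and the classifier

Candidate windows are `[pos−250, pos+250)` in 0-based half-open
coordinates; the SNP occupies offset 250. Features: per-mark
length-weighted mean bedGraph signal (uncovered bases count as zero),
per-mark peak-overlap fraction, chromatin-state composition (uncovered
bases count toward the quiescent state so fractions sum to 1), and
TF-peak count. Default marks: open chromatin (DNase), H3K4me1, H3K27ac,
and H3K4me3 as the promoter-discriminating mark.

The classifier standing in for an externally trained enhancer model is
standardized L2 logistic regression. The ridge weight is per-sample
(`C = 1/(0.01 n)`), which makes the fit invariant to duplicating the
training set; scores are therefore also invariant to feature rescaling
(standardization absorbs units). Cross-validation is stratified 5-fold,
seeded. The model serializes to a versioned JSON document (feature names,
standardization, coefficients, cutoff) and is re-scored by closed form, so
a JSON round-trip reproduces scores bit-for-bit. Default call cutoff 0.5,
inclusive at the boundary.

Enhancer boundaries for reporting are the merged union (overlapping or
book-ended) of DHS/histone intervals in the component containing the SNP;
with no overlap the bare 500-bp window is returned flagged.

## Promoter exclusion and annotation

Genomic context follows the usual annotation precedence
(exonic > splicing > UTR > intronic > upstream/downstream > intergenic),
with upstream/downstream at 1 kb and splicing at 2 bp inside introns. The
promoter filter drops candidates within a strand-aware window around any
TSS, default (−2000, +500). The width is a documented assumption — the
narrowing it reproduces was published without a numeric definition — and
is config-exposed and echoed in every run report. An alternative mode
drops candidates whose window overlaps a promoter-labeled chromatin-state
interval instead; TSS distance is the default because it is
annotation-only and panel-independent.

## Allele-specific TF binding

Each allele is embedded at offset 7 of a 15-mer. All full motif
placements inside the 15-mer are scored on both strands (an option
restricts to SNP-overlapping placements; non-overlapping placements tie
between alleles and therefore never create an allele-specific call on
their own). Scores are log₂ odds against the background base composition
with a total pseudocount of 0.8 per column split by background (common
JASPAR practice); both are configurable.

The percentile reference distribution — left undefined in the published
rule — is the score of a single random L-mer under the background
composition: exact by 4^L enumeration for L ≤ 10, otherwise 100,000
seeded draws with a reported Monte-Carlo standard error. The verdict is
allele-specific iff one allele's best-score percentile is strictly above
60 and the other's strictly below; both above is shared; a percentile of
exactly 60 always weakens the call ("above/below" read strictly).

A consequence worth knowing: because the observed statistic is a
*best-over-placements* score compared against a *single-k-mer*
background, near-consensus matches of **both** alleles sit far above the
60th percentile (a consensus site with one broken column still beats the
entire wrong-base score cluster, ≈ 75th percentile or higher). The rule
therefore discriminates only at borderline sites, where the single base
change moves the best score across the 60th-percentile boundary. The
synthetic generator plants exactly such a site (below), and random
flanking sequence at other SNPs can occasionally produce legitimate
chance crossings — these are properties of the rule, not bugs.

## Synthetic data

The generator emulates the inputs of a desk-scale fine-mapping study:

* **Haplotypes**: each (seed, proxy) pair is drawn from the
  four-haplotype multinomial solving D = sign·√(r²·pA qA pB qB), with
  feasibility checked against Dmax and the violated bound named. Proxies
  are conditionally independent given their seed; background SNPs are
  independent. No recombination map, mutation model, or population
  structure — the pipeline consumes only pairwise LD, which is exact in
  expectation by construction.
* **Tracks**: lognormal background noise (σ = 0.5) per 100-bp bin, an
  additive Gaussian bump (amplitude 8, sd = window/4) on the enhancer
  marks over planted windows and on DNase/H3K4me3 around TSSs; peak
  intervals at planted windows plus decoy peaks placed away from
  candidate windows; a chromatin-state segmentation partitioning the
  chromosome into promoter / strong_enhancer / quiescent. Real signal
  tracks have autocorrelated, copy-number- and mappability-driven
  structure this model does not attempt; passing tests therefore show
  pipeline correctness given informative tracks, not classifier
  performance on real chromatin.
* **Planted motif site**: the allele-sensitive column is the one with
  the largest log-odds spread (an equiprobable column raises an error, as
  no separation can be guaranteed). The site is deliberately a
  *borderline* match: non-SNP site columns and the free flank bases
  inside the 15-mer are chosen by exhaustive enumeration so the
  high-allele placement scores above, and every placement of the
  low-allele 15-mer below, the 60th-percentile score. This mirrors the
  biologically typical situation of a weak site created or destroyed by
  a variant, and is the only construction under which the percentile
  rule can produce an allele-specific verdict (see above).
* **Demo study** (`demo_config`): one 1-Mb chromosome, 2,000 haplotypes,
  three GWAS seed loci 300 kb apart, 24 proxies per seed (population r²
  between 0.15 and 0.9; three below the 0.3 expansion threshold per
  seed), 66 retained proxy pairs. One proxy per seed at r² = 0.9 sits in
  a planted enhancer window; one extra enhancer proxy has r² = 0.49
  (dropped by the strong-LD filter) and one sits 1,250 bp upstream of a
  TSS (dropped by the promoter filter). Twelve training enhancer windows
  and twelve background positions, away from all candidates, train the
  classifier. Sample-size choices keep sampling noise far from every
  filter boundary (e.g. sd(r̂²) ≈ 0.006 at r² = 0.9, n = 2,000) while the
  full simulate-plus-run cycle completes in a few seconds.

Determinism: one `numpy` Generator seeded from the config drives every
draw in a fixed order; identical configs produce byte-identical files.

## Assay arithmetic

Luciferase: per-well firefly/Renilla normalization, relative activity
against the mean (median selectable) of the baseline construct, zero-
Renilla wells excluded with a warning. Allele comparison is pooled-
variance Student's t by default (Welch selectable); two zero-variance
groups with equal means return p = 1 by convention. ChIP-qPCR assumes
amplification efficiency exactly 2 per cycle (config hook provided);
percent input adjusts the input Cp by log₂(1/input_fraction), and
fold-over-IgG reduces to 2^(Cp_IgG − Cp_target) — an identity the tests
assert numerically, which is also why only one formula is implemented.

## Known limitations

* The enhancer classifier is a stand-in with the published model's
  contract (same inputs/outputs, config cutoff), not its weights or
  training corpus; absolute scores are not comparable to the original.
* The percentile background is matrix-intrinsic and reference-free;
  other choices (genome-wide score backgrounds, dinucleotide models) would
  shift percentiles and are out of scope.
* Headline counts of the original genome-wide analysis (260 SNPs, 140
  signals, 6,230 proxies, 34 eSNPs) depended on specific historical
  catalog/panel/track versions and are not reproducible without those
  downloads; the package instead proves each stage against oracles and
  planted truth, plus the published strong-LD worked example (7 eSNPs).
* Annotation is gene-level, not transcript-isoform aware, and does not
  predict coding consequences.
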