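# Methods

This note documents the models, algorithms and numerical choices behind
`gbspop`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Data model and its central restriction

All genotypes are *diploid-coded*: unordered pairs of allele indices,
with dosage in {0, 1, 2}. This matches what RAD assemblers emit for
polyploid samples, where true allele dosage (e.g. AAAG vs AAGG in a
tetraploid) is not recoverable from short-read data at typical depths.
Calls of any other arity are rejected at parse time rather than silently
collapsed, because a silent collapse would misrepresent heterozygote
classes in every downstream statistic. Phase separators in VCF input are
accepted but phase is discarded: assembler phase for polyploids is not
meaningful. Multi-allelic records are parsed and carried through
filtering, but matrix construction (and hence PCA/admixture) requires
biallelic records, which mirrors how every statistic here is defined.

## Filtering cascade

Order: individual missingness → site completeness → minor-allele
frequency → centre-SNP thinning. The order is semantic, not cosmetic:
dropping a high-missingness individual changes every site's presence
denominator, so running the site filter first gives a different result
(the test suite contains a 6-sample fixture demonstrating this).

Boundary semantics follow VCFtools conventions: an individual is dropped
when its missing fraction is *strictly greater* than the threshold; a
site is kept when its presence fraction or MAF is *greater than or
equal* to the threshold (so a site whose rarer allele frequency is
exactly the 1% floor is retained). Defaults: maximum individual
missingness 0.40 (a stricter 0.10 profile is built into the CLI), minimum
site presence 0.80, MAF 0.01. An alternative minimum-minor-allele-*count*
mode (`min_allele_count`) is provided because at 50–100 individuals a
frequency floor of 1% and a count floor of 2 alleles are nearly but not
exactly equivalent; neither is asserted to be the uniquely correct
reading.

Centre-SNP thinning keeps, per contig, the SNP minimising
`|pos − centre|` where the centre is `(alignment length + 1)/2` when the
locus alignment is available and the midpoint of observed SNP positions
otherwise (the filter report records which definition applied). Distance
ties break to the lower position — deterministic and independent of
record order. Thinning to one SNP per contig is a blunt but standard
linkage-disequilibrium mitigation for RAD loci, where within-contig SNPs
are a few dozen base pairs apart and effectively fully linked.

## PCA

Missing dosages are mean-imputed per site *on the dosage scale* and the
matrix is then centred; covariance PCA (no standardisation) is the
default, with correlation PCA behind `scale=True` since reasonable
pipelines differ on this point. Zero-variance sites are dropped (with a
logged count) only when scaling, where they would otherwise divide by
zero; unscaled they simply contribute nothing.

The decomposition uses the samples × samples Gram matrix
(`XXᵀ/(n−1)`), which has the same non-zero spectrum as the site
covariance but is far smaller for GBS data (n ≪ m), via a deterministic
LAPACK eigensolver — results are bit-reproducible on a platform, and the
test suite checks agreement with a direct SVD to 1e−8. Explained
variance is reported as a percentage of the *total* variance (sum of all
eigenvalues). Component signs are fixed by making each component's
largest-magnitude loading positive.

## Likelihood-free admixture estimation

Genotype-likelihood admixture models assume the within-individual allele
counts are observed correctly; diploid-coded polyploid calls violate
this, so the estimator here never forms a likelihood. It follows the
latent-subspace strategy in two stages.

**Subspace stage.** Under the admixture (PSD) model,
`x_ij ~ Binomial(2, f_ij)` with `F = P Qᵀ` of rank K. The second-moment
matrix of the data columns estimates `FᵀF/m` plus a diagonal
contribution from binomial sampling noise; subtracting the plug-in
estimate of that diagonal (`Σ_j x_ji(2−x_ji)/(2m)`) before
eigendecomposition makes the top-K eigenvector estimate consistent.
`F̂` is the projection of `dosage/2` onto that span, clipped to
`[1e−6, 1 − 1e−6]`. The adjustment is switchable (`adjust_noise`)
because on noise-free inputs — dosages exactly `2F`, used by the exact
recovery tests — the adjustment subtracts a diagonal that the data do
not contain.

**Factorisation stage.** Constrained alternating least squares:
P-update by least squares clipped to [0, 1]; Q-update by least squares
followed by row-wise Euclidean projection onto the probability simplex
(sort-based algorithm, O(K log K) per row, deterministic). Because the
clip/projection steps are not exact constrained minimisers, a single
iteration can increase the residual; the solver therefore iterates
freely but records and returns the best iterate seen, making the
recorded objective trace non-increasing by construction. Convergence is
declared after 5 consecutive iterations with relative improvement below
`tol` (default 1e−6); hitting `max_iter` (default 1000) flags the fit
rather than raising. The problem is non-convex, so 5 seeded
Dirichlet(1, …, 1) restarts are run and the best final objective kept.

The factorisation is identifiable only up to column permutation, and —
when neither matrix touches its box boundaries — up to small stochastic
remixing as well. Recovery tests therefore (a) compare memberships after
Hungarian-algorithm column matching, and (b) use planted factorisations
with pure individuals and cluster-diagnostic sites when sub-1e−3
accuracy is asserted, since those anchors are what pins the
factorisation down. On realistic drifted data the practical consequence
is a small admixture-like blur (a few percent) in `Q̂`, visible in the
recovery errors the tests report.

K is swept over a caller-specified range (the CLI default is 1–8). When
the input contained missing data, the sweep reports per-K reconstruction
objectives but deliberately refuses to nominate a best K: the subspace
eigen-gap diagnostic is valid only on complete data, and mean imputation
distorts it.

## Fixed differences and consensus

A site is *fully segregated* between groups A and B when each group has
at least `min_calls_per_group` (default 1) non-missing calls and the
allele sets observed in the two groups are disjoint. Disjointness is
used rather than "fixed homozygous difference" because it generalises
beyond biallelic sites while coinciding with it on biallelic data; it is
also the strictest reading — one heterozygote anywhere disqualifies a
site. Missing calls are ignored, never treated as wildcards, and a
sample absent from the population map is an error rather than a silent
skip: a defaulted species label could fabricate diagnostic markers. The
default minimum of one call per group is deliberately permissive and
configurable, because diagnostic-marker counts are sensitive to it; a
`require_complete` flag demands full genotyping of both groups.

The flanking consensus of a diagnostic SNP is computed per alignment
column: majority base among non-gap, non-N characters; at the focal
column the IUPAC code of *all* observed bases (so the diagnostic
polymorphism itself is never flattened into a single base); at tied
columns the IUPAC code of the union of the tied characters' base sets —
an arbitrary pick would fabricate certainty that downstream homology
searches cannot detect. Majority-gap columns are removed (which also
trims all-gap margins) and the focal position re-indexed. Sample
sequences may themselves carry IUPAC codes (heterozygous calls); these
are expanded before coding.

## Synthetic data: what it emulates and what it does not

The generator emulates the *post-assembly product* of a GBS study:
contigs of `locus_length` bp (default 120) carrying 1–4 SNPs each,
diploid-coded calls for `K` labelled populations, MCAR missingness, and
optional planted diagnostic markers. Population frequencies follow
Balding–Nichols drift around a shared ancestral frequency
(`p ~ U(0.05, 0.95)`; default F = 0.15, a moderate level typical of
conspecific plant populations; per-population F values allow
hierarchical designs such as two close groups plus one diverged).
Within-locus SNPs share their population frequencies up to Gaussian
jitter (sd 0.05), inducing within-contig correlation without haplotype
simulation — sufficient to exercise one-marker-per-contig thinning, but
not a model of real LD decay. Memberships are one-hot or
i.i.d. Dirichlet(α); dosages are Binomial(2, qᵀp); missingness is
per-cell MCAR at `1 − (1−r_ind)(1−r_site)` (defaults 0.05/0.05,
≈ 10% realised).

Planted markers are placed on the centre-closest SNP of their locus (so
they survive thinning, as real diagnostic SNPs discovered in a filtered
dataset by construction did) with group A fixed homozygous-reference and
group B homozygous-alternate, and no missingness at those sites. Any
background site that is fully segregated between the designated groups
by chance is broken by flipping one call to a heterozygote, so the
planted list is the *exact* ground truth and plant-and-recover tests can
assert precision = recall = 1.

What passing tests therefore show: the implementation computes its
definitions correctly, recovers planted structure under the model it
assumes, and is deterministic. What they do not show: robustness to
assembly artefacts (paralog collapse, allele dropout), depth-dependent
genotyping error, structured (non-MCAR) missingness, or real LD — none
of which the generator produces.

## Problem sizes and numerics

Test and acceptance runs use desk-scale datasets (≤ ~100 samples,
≤ ~12,000 SNPs), chosen so the full suite completes in seconds to a few
minutes while keeping every estimator in its well-conditioned regime.
Filter-oracle checks run 200 random datasets up to 50 × 200 against an
independently coded brute-force reimplementation. Floating-point
tolerances: PCA vs SVD 1e−8; simplex row sums 1e−6 (estimation) /
1e−12 (projection); exact-recovery factorisations 1e−3. The VCF, popmap
and `.loci` writers are deterministic (fixed header lines, content-
derived padding), so write→read→write is byte-stable and the chained
pipeline is checksum-reproducible under a fixed seed.

## Known limitations

- Diploid-coded calls understate polyploid allele dosage; every
  frequency-based statistic inherits this bias. The package makes the
  coding explicit rather than attempting polyploid genotype calling.
- Mean imputation shrinks individuals with much missing data toward the
  per-site mean, pulling their PCA scores toward the origin and their
  memberships toward uniformity; the stringent missingness filters
  upstream exist precisely to bound this.
- The ALS factorisation offers no uncertainty quantification, and its
  small remixing indeterminacy (above) is a property of the model class,
  not of this implementation.
- Consensus extraction assumes the locus alignment is correct; it does
  not re-align.
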