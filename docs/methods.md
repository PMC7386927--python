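# Methods

This note documents the statistical machinery in `clonalpop`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Genotype representation and filtering

Genotypes are diploid alternate-allele dosages in `{0, 1, 2}` with a `-1`
sentinel for missing calls; every estimator conditions on observedness and
never treats a missing call as dosage zero. Coordinates are 1-based (VCF
convention). Site filters run in a fixed order — multiallelic →
missingness → Hardy–Weinberg → MAF → monomorphic — and each removed site is
attributed to the first rule it fails, so filter reports are additive.
All thresholds are strict: a site is removed only when its missing fraction
*exceeds* 0.80, its χ² *exceeds* 20, or its MAF is strictly *below* 0.01.
The Hardy–Weinberg statistic uses expected counts from the observed allele
frequency with no continuity correction; genotype classes with expected
count zero contribute zero, so monomorphic sites score 0. The test is
computed on the full matrix as supplied — if a stratified test is wanted,
subset first.

`naive_impute` fills missing calls with the rounded site-mean dosage
(halves round up). It is deterministic plumbing so that PCA can run on
complete data; it is not a statistical imputer and should not be used where
imputation quality matters.

## Clonal identity

**IBS similarity.** For samples i, j the similarity is the mean of
`1 − |gᵢ − gⱼ|/2` over jointly non-missing sites, computed exactly via
dosage-class indicator products (no missing-data approximation). Pairs
sharing no sites are flagged and only become an error if clustering is
requested.

**Dissimilarity.** The default conversion is `D = 1 − IBS`. A
`rows-euclidean` mode (Euclidean distance between rows of the similarity
matrix) is provided because distance tooling applied directly to a
similarity matrix computes exactly that; the calibrated threshold makes
group calls robust to the choice, since both conversions are monotone
transformations of the same ordering for tight clone pairs.

**Ward clustering.** The Lance–Williams minimum-variance update is applied
to the *unsquared* dissimilarities (the classic `ward.D` convention of
older hierarchical-clustering implementations); a `ward.D2` variant
(squared inputs, square-root heights, the scipy/modern-R behaviour) is
selectable. The implementation is an O(n³) vectorised agglomeration with a
deterministic tie-break: among equal-height candidate merges, the pair
whose smallest contained leaf indices are lexicographically least is
merged. Correctness is checked two independent ways: an exhaustive-search
Lance–Williams reference on random matrices (exact agreement), and scipy's
ward on square-rooted inputs with squared heights.

**Threshold calibration.** On a dendrogram of the replicated check samples,
`h_min` is the largest height at which a replicate set first becomes one
cluster and `h_max` is the height of the first merge uniting two different
sets (root height if none). Cutting anywhere in `[h_min, h_max)` exactly
reproduces the replicate partition — verified by scanning all merge
heights. Calibration fails loudly, naming the offending sets, when
`h_min ≥ h_max`.

The reported threshold is the **geometric mean** of the interval ends.
This was a genuinely open design point. The arithmetic midpoint looks
natural but is unsafe: Ward heights between distinct tight clusters inflate
with cluster size (merging clusters of sizes a and b separated by raw
distance D happens near `2ab/(a+b)·D`), so `h_max` sits one to two orders
of magnitude above replicate noise, and the midpoint lands on the
between-variety scale, merging singleton varieties. Under the package's
standard simulation conditions the interval is roughly (0.01, 2.2): the
geometric mean (~0.15) sits safely inside the gap between within-clone
heights (~0.01) and the smallest between-variety merge (~0.2), while the
midpoint (~1.1) does not. `rule="midpoint"` remains available.

Calibration is computed on the checks-only tree and the threshold is then
applied to the full cohort, mirroring how replicate panels are used in
practice; `calibrate_threshold` itself is agnostic to which tree it
receives.

**Groups and representatives.** Cutting keeps every merge with height ≤ t;
labels are `C_<1-based index of the group's first member>` and carry no
semantics. Deduplication draws one uniform representative per
(group, district) cell from a generator seeded explicitly, so a variety
present in k districts contributes k representatives.

## Population-genetic summaries

**F_ST.** The Weir–Cockerham (1984) estimator computes, per biallelic
site, sample sizes nᵢ, alternate-allele frequencies pᵢ, and observed
heterozygote frequencies hᵢ per population, then n̄, n_c, p̄, s², h̄ and the
variance components a (among populations), b (among individuals within
populations), c (within individuals). Sites where fewer than two
populations are genotyped, or where n̄ ≤ 1, are skipped and counted. Both
the ratio-of-sums `Σa / Σ(a+b+c)` (headline) and the mean of per-site
ratios are always reported, since toolchains differ in which they print.
Negative estimates are meaningful near zero differentiation and are not
truncated.

**Nucleotide diversity.** Per site,
`π = 2·c_ref·c_alt / (n(n−1))` with n the number of observed alleles —
identical to averaging mismatches over all allele pairs, which the tests
verify by enumeration. Windows are half-open 0.5-Mb tiles starting at
position 1 and running through the last genotyped position of each
chromosome; every window's sum is divided by the *full* window length
(including the final partial window), giving the per-bp scale on which
typical window-π output is reported (~10⁻⁴ for diverse panels). Windows
without variant sites report π = 0 and enter chromosome means.

**LD pruning.** Sites below the MAF floor are removed first; then windows
of 50 surviving sites advance by 10 within each chromosome, and while any
retained pair in the window has squared Pearson correlation of dosages
(pairwise-complete over missing data) above 0.3, the lower-MAF member of
the worst pair is removed (tie: later position). The removal rule is one
deterministic choice among several defensible ones; only the thresholds
are canonical.

**PCA.** Columns are centred and scaled (unit variance, ddof = 1) and the
matrix decomposed by SVD, matching centre-and-scale conventions of
standard statistical PCA. Missing data must be imputed or filtered first;
a constant column after MAF filtering (possible when every sample is
heterozygous) is an error rather than a silent drop. Component signs are
fixed by orienting each loading vector so its largest-magnitude entry is
positive.

## Introgression scoring

A diagnostic marker carries a donor allele essentially absent from the
crop background, so donor dosage (alt dosage, or `2 − dosage` when the
reference allele is diagnostic) measures wild ancestry. Per-sample
proportions are `Σ dosage / (2n)` over non-missing diagnostic genotypes —
markers missing in a sample are excluded from that sample's denominator,
so proportions are comparable across samples with different call rates.
Genome-wide proportions recompose exactly as the marker-count-weighted
average of regional and off-region proportions (asserted in tests). Focal
regions default to chromosome 1 from 25 Mb to the chromosome end (an
end sentinel resolved against the data) and chromosome 4 from 5–25 Mb.
F1 flagging uses a donor proportion in [0.30, 0.60] with heterozygous
fraction ≥ 0.80 among donor-carrying genotypes; both cut-offs are
configurable operationalisations of "looks like a first-generation
hybrid", not estimated quantities.

## Name correspondence

Names are normalised by trimming and case-folding only; spelling variants
remain distinct names deliberately, because variant spellings are
themselves information in survey data. The chord-diagram export keeps
groups with > 20 members and names with > 11 mentions (strict, matching
the membership-filter convention used for such figures); excluded names
within retained groups are pooled into `Other_names` *after* the group
filter, so each retained group's row still sums to its member count.

## Synthetic collections

The generator emulates: district allele frequencies from the
Balding–Nichols model (`Beta(p(1−F)/F, (1−p)(1−F)/F)` around ancestral
frequencies uniform on [0.05, 0.5]), founder genotypes Binomial(2, p),
clonal copies with genotype-level miscalls (resampled uniformly to a
different dosage class) and missing calls, cross-district sharing as
literal founder copies, five replicated checks with 17/12/19/18/6
replicates, founder-level donor segments at diagnostic loci inside the
focal regions (hom/het mix controlled by `donor_hom_prob`), and a naming
process with synonym and homonym perturbations. Default rates — F_ST
0.003 across four districts, 15 varieties per district with 1–5 clones
each, 0.5 % miscalls, 10 % missingness — define the standard study
conditions used throughout the tests and the acceptance script; positions
are uniform on 18 chromosomes of 30 Mb, which only window analyses
consult.

What the generator does *not* emulate: linkage disequilibrium and
recombination (sites are independent draws), allele-level sequencing error,
read-depth-dependent missingness, pedigree relatedness between distinct
varieties, and segment-length variation of introgressions. Perfect clone
recovery on these simulations therefore demonstrates that the calibrated
threshold separates replicate noise from between-variety distance under
the stated error model — it does not guarantee the same margin on data
where distinct varieties can be close relatives (e.g. parent–offspring
pairs from volunteer seedlings), which is precisely why the threshold is
calibrated per dataset rather than fixed.

## Problem sizes and numerics

Tests and the acceptance script use 5,000-site collections (~280 samples)
for clone recovery, 100 × 20,000 for F_ST recovery, and ≤ 10-point
matrices for the exact oracles — sizes chosen so the whole suite runs in
seconds while keeping Monte-Carlo error well inside the asserted
tolerances. The Ward implementation is O(n³) time / O(n²) memory and is
comfortable to a few thousand samples; IBS computation is three matrix
products over dosage-class indicators and scales to full GBS panels.
Dissimilarities are clipped at 0 to absorb floating-point negatives;
merge-height monotonicity is asserted after clustering; the calibration
interval uses exact float comparisons on merge heights, with cut
comparisons at `height ≤ t`.
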