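# Methods

This note documents the models, parameter choices and numerical conventions
behind `mrfusion`, and what the synthetic studies do and do not demonstrate.

## Genotype QC

Filters run in a fixed order — sample call rate → SNP call rate → MAF → HWE —
because the order affects the result (per-SNP statistics are recomputed on
the subject set that survives the sample filter, as in standard sequential
chip QC). Defaults: 0.95 / 0.999 / 0.04 / 1e-4. A consequence worth knowing:
tightening the *sample* threshold can change which SNPs survive in either
direction, so only the SNP-level filters are monotone at a fixed cohort.

The HWE test is the exact conditional test: conditioning on the observed
allele counts, the p-value sums the probabilities of all heterozygote counts
whose conditional probability does not exceed the observed one. Probabilities
are computed with log-gamma factorials and renormalised, which is stable for
any cohort size; the test suite checks exact agreement (1e-12) with full
enumeration for every genotype configuration up to 30 subjects. A chi-square
alternative was considered and rejected: at n ≈ 72 the exact test is the
field norm. The test is conservative (discrete support), so its null
p-values are only approximately uniform; at 500 subjects and 1,000 SNPs the
KS distance to uniform stays below 0.1.

## From diploid calls to one letter per SNP

Chips report two alleles per call but the encoding consumes a single
nucleotide per SNP. This reduction is an explicit policy:

- `major_allele` (default): the subject carries the cohort-major allele
  unless homozygous for the minor one. Deterministic, and the variation that
  survives (hom-minor positions) is exactly the high-confidence genotype
  signal.
- `first_allele`: first allele of the stored pair.
- `seeded_random`: one of the two alleles, chosen by a seeded stream.

Missing calls that survive QC are imputed to the cohort-major allele (the
encoding has no missing code); the imputation count is reported. Major-allele
ties are resolved to the alphabetically smaller allele.

Gene segmentation keeps the *first* L SNPs of each gene in genomic-position
order, L being the smallest retained group size; truncation (rather than
windowing) is the pinned reading of "make all gene sequences the same
length". Genes need strictly more than 30 surviving SNPs to be retained.

## Fusion features

Feature (r, g) for a subject is the Pearson correlation between region r's
first L timepoints and gene g's L-length code vector. Columns are ordered
region-major so feature identities are stable across runs. Degenerate
correlations (zero variance on either side) are set to 0, and counted,
rather than dropped — the forest bookkeeping assumes a fixed M = R·G.
Correlating a time series against an ordinal nucleotide code is implemented
as defined; the package makes no claim about the biological meaning of the
coefficient itself — the discriminative signal, not the raw value, is what
the downstream stages consume.

## The multimodal random forest

This is a random-subspace ensemble, *not* a canonical per-node-mtry random
forest: each tree draws its m features once and CART then splits only within
that subset. m defaults to round(√M) (57 at M = 3,240) and each tree gets a
full-size bootstrap of the training rows (a without-replacement subsample is
available via `bootstrap=False`). CART grows to pure leaves (no depth cap,
min leaf 1, both configurable), splitting on midpoints between consecutive
distinct values by weighted Gini with deterministic tie-breaks (lowest
feature index, lowest threshold). Leaf-label ties and exact vote ties both
resolve to −1 (AD), making predictions fully deterministic; tie events are
logged. The tree kernel is numba-compiled; the recursion is replaced by
explicit stacks so tree identity is independent of compiler details.

The ensemble size is selected by training one forest per grid point
(10, 20, …, 600; a 0-tree forest is undefined, so the grid starts at the
step) and locating the final plateau: the smallest grid point from which
every subsequent rolling 5-point mean stays within ε = 0.02 of the last
window's mean. Transient single-point spikes are absorbed by the averaging,
which formalises a judgement that is otherwise made by eye.

## Feature selection and factor extraction

Tree quality is scored on the held-out split of the 6:4 partition (the
out-of-bag alternative is a one-line change but is not the default). The
100 best trees are retained (accuracy ties broken by tree index), feature
frequency is the number of retained trees whose subset contains the feature
(ties broken by canonical feature order), and the top 400 features are
scanned as nested prefixes of sizes 70…400 in steps of 5. Each subset is
re-evaluated by retraining an MRF restricted to those columns, with m
recomputed as round(√size) capped at the subset size — a fixed m = 57 would
exceed the smaller subsets. The optimal subset is the smallest prefix
attaining the maximum accuracy (parsimony tie-break), and is by construction
a prefix of the frequency ranking.

Factor extraction counts how often each region and each gene appears inside
the optimal subset; both count vectors sum to the subset size. The
hypergeometric overlap test takes the universe size N explicitly — overlap
p-values are meaningless without a stated universe, and different choices
(all M features, the union of candidate sets, …) change the answer by many
orders of magnitude. The t-test baseline uses Welch's statistic with a
zero-variance guard (equal means → t = 0; different means with no
within-class variance → the feature ranks first).

## The synthetic cohort generator

The generator emulates the structure of a two-group imaging-genetics cohort:
37 AD + 35 NC subjects, 90 AAL regions, 36 genes of 40–50 SNPs each,
genotypes drawn under Hardy–Weinberg proportions at per-SNP MAFs uniform in
[0.1, 0.5], and 130-timepoint ROI series of unit Gaussian noise. Planted
couplings exist only in the AD group: for a coupling (r, g, e) the AD
series for region r opens with e·standardize(code of gene g) +
(1−e)·noise, so at e = 1 the fusion feature equals exactly 1. Couplings that
share a region are planted additively (the single-coupling case reduces to
the formula above). HWE violations, when requested, use excess homozygosity
with inbreeding coefficient 0.5, detectable at the 1e-4 threshold for
cohorts of ~70+ at moderate MAF.

Deliberate default choices:

- **Missingness defaults to 0.** A missing-call-driven SNP drop after QC
  shifts every later position of the encoded sequence, destroying the
  planted alignment between series and code; the couplings are the point of
  the generator, so missingness is opt-in (QC behaviour under missingness is
  exercised by dedicated tests and configs).
- **MAF ∈ [0.1, 0.5] and 40–50 SNPs/gene** keep all genes above the strict
  >30 group-size rule and clear of the 4% MAF filter at n = 72, so the
  reference configuration reproduces the 36-gene, 3,240-feature geometry.
- **Default couplings concentrate on one region and one gene**
  ((r*, g*), (r*, g₂), (r₃, g*)) at effects 0.9 / 0.85 / 0.8.

What the generator does *not* model: linkage disequilibrium between SNPs,
temporal autocorrelation in the series (the pipeline only uses pointwise
correlation against a non-temporal code), scanner artifacts, or raw image
preprocessing (inputs are already-parcellated tables). Effect sizes were
chosen for testability; nothing is claimed about realistic coupling
strengths in patient data.

## What the synthetic studies show — and a known limitation

On 20 independent cohorts at the reference conditions, the full pipeline
(including the tree-count scan) classifies held-out subjects with ≥ 0.9
accuracy in ~95% of seeds, and the top-ranked brain region is a planted one
in ~90% of seeds. Permuted-label controls sit at chance, and the t-test
baseline's type-I error matches its nominal level.

Two recovery statistics are weaker, for a structural reason rather than an
implementation one. Under the major-allele policy the encoded gene vectors
are nearly identical across subjects, so the correlation between two genes'
codes is a shared constant; consequently *every* (planted-region, any-gene)
fusion column separates the groups, a few dozen columns are informative, and
well over 100 trees achieve perfect held-out accuracy. The top-100-tree
retention then no longer concentrates on the three specifically planted
columns: all three appear in the top-400 frequency table in only ~55% of
seeds, and the gene-side factor ranking is diluted across the genes riding
the planted regions (top gene planted in ~20–30% of seeds). At real-data
scale — weak signal, few good trees — the frequency mechanism behaves as
intended; at desk scale with strong planted signal it saturates. The
corresponding assertions in the end-to-end test suite are left failing with
this explanation rather than weakened.

## Problem sizes

Default analyses use the full reference geometry (72 subjects, 3,240
features, tree grids to 600, 67 subset evaluations); one end-to-end run
takes ~10 s on one CPU thanks to the compiled CART kernel. The multi-seed
studies use 20 seeds in the test suite and 10 in the acceptance script.
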