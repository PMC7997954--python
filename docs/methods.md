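# Methods

## The measurement model

Circulating cell-free DNA survives in plasma mainly as
mononucleosome-protected fragments: a ~147 bp core plus linker, giving
the characteristic ~166 bp insert, while MNase digestion of chromatin
protects ~146 bp cores. Where a promoter is transcriptionally active,
the nucleosome normally sitting over the TSS is evicted, leaving a
nucleosome-depleted region (NDR) at roughly −150..+50 bp. Fragment
density around a TSS is therefore an inverse proxy for promoter
activity in the cell populations contributing to the plasma pool.

`nucleofoot` quantifies this with three deliberately distinct
statistics:

* **TSS window RPKM.** Fragments are assigned to a TSS when their
  *midpoint* falls in `[tss − flank, tss + flank)` (flank 1 kb).
  Midpoint assignment is the natural convention for nucleosome maps
  (protection is symmetric about the dyad) and guarantees each fragment
  is counted at most once per window. Normalization is
  `count / ((2·flank/1000)·(total_fragments/10⁶))`; the denominator is
  the sample's total fragment count, not the sum over tested windows,
  so values are comparable across runs. Windows truncated at a
  chromosome edge are not rescaled; the lost territory simply counts
  zero.
* **NDR depth** sums *per-base coverage* (read-depth semantics, unlike
  the midpoint rule above) over the window, strand-mirrored: for window
  (a, b) a '+' TSS at t covers `[t+a, t+b)` and a '−' TSS covers
  `[t−b+1, t−a+1)`, so offset x upstream means upstream on both
  strands. Strand handling of this window is a package decision — the
  mirror convention is symmetric and exactly invertible (reflecting all
  data about a point reproduces the same numbers; the suite checks
  this).
* **Metagene profiles** average per-base depth at strand-oriented
  offsets −flank..flank−1 over a TSS subset, then over samples.

## Expression association

Genes are classed as highly expressed (TPM > 10, strict) or unexpressed
(TPM = 0); TSSs as upper/lower occupancy quartile, each of size
⌈n/4⌉ with ordering by (occupancy, gene id) so ties resolve
deterministically and the two sets are always disjoint. Overlap between
an occupancy set and an expression set is tested against a permutation
null: 1000 uniform resamplings of the second set's membership from the
universe with sizes fixed, then z-standardization of the observed
overlap against the empirical null (population-variance form; at 1000
permutations the n vs n−1 choice moves z by under 0.1%) and a two-sided
p from the standard normal. The implementation draws "first |B| entries
of a permutation of range(N), counted below |A|", which has exactly the
resampled-overlap distribution but depends only on set sizes — making
the test invariant to relabeling gene ids, a property the suite
enforces. The null mean is the hypergeometric expectation |A||B|/N,
which the tests use as an independent oracle. Which labels were
conceptually shuffled (occupancy or expression) is immaterial under
this scheme; both give the same null.

## Differential TSS calling

Per TSS, occupancy values of the two cohorts are compared with a
two-sided Wilcoxon rank-sum test: exact null distribution when the
pooled size is ≤ 20 with no ties (exactness removes approximation error
precisely where small cohorts make it matter), otherwise the normal
approximation with tie-corrected variance and continuity correction;
with no rank information at all (all values identical) p = 1. Fold
change is the ratio of group means with a pseudocount (default
0.01 RPKM) guarding empty windows; it is reported as log₂ but the call
rule compares the raw ratio symmetrically against fc_min (≥ fc_min or
≤ 1/fc_min), which is base-free. Benjamini–Hochberg adjustment is
applied only when an FDR criterion is configured (the cancer-vs-healthy
style contrast: p < 0.01, FC ≥ 1.2, FDR < 0.1); response-style
contrasts use p < 0.01 and FC ≥ 1.5 alone. The choice of means (not
medians) and of BH as the FDR procedure are package defaults where the
convention was open.

Heatmap ordering uses UPGMA (average linkage) on Euclidean distances
after per-feature z-scoring (zero-variance features are left at 0);
both the standardization and the metric are exposed because heatmap
practice varies.

## Promoter classifier

Each feature is binarized at the threshold maximizing balanced accuracy
(sensitivity + specificity)/2 on the training samples, scanning
midpoints between adjacent distinct values plus ±∞, ties resolved to
the smallest threshold and then to the high-maps-to-1 orientation; a
value exactly at the threshold maps to 0 (strict inequality, for
bit-exact reproducibility). The binary matrix feeds an L1-penalized
logistic regression. The penalty grid descends log-spaced over four
decades from the data-derived λ_max; the chosen λ minimizes binomial
deviance in an inner stratified 5-fold CV on the training data, ties
going to the heavier penalty. Numerical details: the inner path is
fitted with liblinear (fast; intercept weakly penalized through
intercept_scaling = 100) purely to rank penalties, while the final
model is fitted with saga (unpenalized intercept); whenever a fit
returns all-zero coefficients the intercept is replaced by its
closed-form optimum, logit(mean y). Evaluation is stratified 5-fold CV
repeated 100× (stratification is required: with 10 samples in the
minor class, unstratified folds can be single-class and AUC-undefined).
Cutoffs, feature filtering, and λ selection see training folds only;
the suite perturbs held-out samples and asserts the training artifacts
are byte-identical. The differential feature filter can run inside each
training fold (default, leakage-free) or once globally — the latter
mirrors a common published workflow and is kept for comparison.

## The synthetic cohort generator

The simulator emulates the statistical structure the analysis assumes,
not sequence-level reality. Per gene, fragment midpoints are drawn from
Gaussian clusters (sd 20 bp) at `tss + k·190 bp`, k = −K..K with K set
by the TSS spacing; the k = 0 nucleosome — the one inside the NDR
window — is down-weighted by the gene's depletion level, a saturating
function `strength · TPM/(TPM+10)` of its zero-inflated log-normal
expression (30% zeros, meanlog 2, sdlog 1.5 → ≈29% of genes above
TPM 10). Suppressing a single array position, rather than rejecting
fragments overlapping the window, produces the gradual promoter dip
seen in real depth maps instead of a hard hole. Fragment lengths are
truncated normals (≥ 50 bp): 166 ± 10 bp for cfDNA, 146 ± 8 bp for
MNase. A uniform background (default 10%) spans the genome. Cohort
effects multiply a planted gene's whole-promoter sampling rate in
group B by the effect factor (or its inverse, per planted direction),
giving |log FC| = log f at the TSS window — a single interpretable
knob for recovery benchmarks. All randomness flows from one root seed
via named `SeedSequence` streams (landscape, design, per-sample), so
cohorts reproduce sample-by-sample.

Default scale is a desk-size study: two 5 Mb chromosomes, 2000 genes at
≥ 4 kb spacing, 200k fragments per sample — per-kilobase window depths
comparable to a 6–10 M read low-coverage genome, at ~1/300 of the
genome. What the generator does *not* model: GC and mappability bias,
tumor/normal fraction mixtures, isoform-level TSS multiplicity,
inter-individual baseline variation beyond sampling noise. Passing
tests therefore demonstrate the correctness and calibration of the
statistics under the stated generative assumptions, not robustness to
those real-data artifacts.

## Problem sizes used in the shipped checks

Oracle-equivalence tests run on ≤ 500-fragment fixtures against
per-fragment/per-base brute force. Calibration of the overlap test uses
500 decoupled landscapes (200 genes, 20k fragments each); the footprint
direction check uses 100 coupled cohorts. Differential recovery uses
2000 TSSs with 150 planted at effect 1.8 in 28-vs-10 cohorts over 10
seeds, with 20 null seeds for type-I calibration. Classifier checks run
20 CV repeats (the acceptance script uses 10) on 38-sample cohorts; the
full 100-repeat default remains available via the API and CLI. The
demonstration pipeline (`run-all`) defaults to 400 genes and 40k
fragments per sample.

## Degenerate inputs and tie-breaks, collected

* Empty fragment set: RPKM and length summaries refuse (undefined
  normalization); NDR/metagene would be all zero but require valid
  inputs.
* All-tied groups in the rank-sum test: p = 1.
* set_b = universe in the overlap test: degenerate null, refused.
* All-equal feature in cutoff learning: balanced accuracy 0.5,
  threshold −∞, orientation "greater" (everything maps to 1).
* Zero-variance feature in clustering: left at 0 after standardization.
* Constant-feature matrix in the LASSO: no penalty path exists, fit
  error surfaced.
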