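# Methods

## Data model and preprocessing

The input is a labeled expression matrix: n samples × p genes with one
class label per sample (m ≥ 2 classes, each with at least two samples
for fitting). No missing values are allowed; files are CSV/TSV with a
header and a label column, in either samples-as-rows or genes-as-rows
orientation (the flag only transposes layout, never values).

**Outlier adjustment** (training data only, never test samples). For
each gene j, values outside `mean_j ± u_α · sd_j` are replaced by the
corresponding edge of the leave-one-out band,
`loo_mean ± u_α · loo_sd`, where the leave-one-out statistics exclude
the offending cell. Bounds are computed once from the original values;
replacements do not cascade. Defaults: α = 0.05 with the customary
rounded quantile u = 1.96 (other α derive u from the normal quantile);
the standard deviation is the sample (n − 1) estimator, with the
population estimator available via `sd_ddof=0`. A constant gene has
sd = 0 and hence no outliers. The adjustment is not guaranteed
idempotent (replacing a cell shifts the band on a re-run), though on
Gaussian data a second pass almost always changes nothing; the package
applies exactly one pass, before one-vs-rest splitting.

## Contingency tables and tie handling

All scoring flows through 2 × r tables (rows: positive, negative):

* vertical individual (2 × 2): gene values above/below the gene's
  endpoint `EP_j = (mean over negatives + mean over positives) / 2`;
* horizontal pair (2 × 2): within-sample order `X_ij > X_iq` vs `<`;
* vertical pair (2 × 4): joint endpoint states in column order
  (>,>), (>,<), (<,>), (<,<).

A value exactly equal to its threshold (or an exact within-sample tie)
contributes 0.5 to each of the two columns of its class row; a sample
tied on both genes of a vertical pair contributes 0.25 to all four
columns (the two splits are independent). Counts are therefore
half-integers and every table's grand total equals the sample count.
Column order is fixed for reproducibility; all downstream scores are
invariant under column permutation and row swap.

Endpoints are always recomputed from the sample set actually present in
a table — in particular after a transductively relabelled sample is
merged (see below) — but outlier adjustment is never re-run on merged
data: it is a training-set preprocessing step.

## Scores

With `φ(x, T) = −x log₂(x / T)` and the convention `0 · log 0 = 0`:

* complexity `C = C_row + C_column` as in the README;
* maximum complexity `C_max = n log₂ r + φ(f₊, n) + φ(f₋, n)` — the
  complexity of the equal-column table with the same margins;
* relative simplicity `RS = (C_max − C)/C_max`, defined as 0 when
  `C_max = 0` (degenerate single-column margins);
* pair RS pools both pair tables before normalising:
  `RS_pair = ((C_hor_max + C_ver_max) − (C_hor + C_ver)) /
  (C_hor_max + C_ver_max)`.

Base-2 logarithms throughout. Cell terms accumulate in a fixed order
(positive row left-to-right, then negative row; for column sums, the
positive entry above the negative one, columns left-to-right), so the
vectorised kernels reproduce a literal cell-by-cell loop bit for bit.
RS is exactly 0 on a maximum-complexity-form table whenever its log
terms are dyadic, and within one or two ulps of 0 otherwise.

### Chi-square variants

The 2 × 2 statistic uses Yates' continuity correction **without**
flooring the corrected term at zero:
`χ² = n (|f₊₁f₋₂ − f₊₂f₋₁| − n/2)² / (f₊ f₋ f₁ f₂)`, and 0 whenever a
margin is empty. This is the single variant consistent with all the
worked 2 × 2 values this package reproduces, including one whose
corrected term is negative before squaring (standard floored Yates
would return 0 there, uncorrected Pearson disagrees elsewhere); the
floored and uncorrected forms remain available via
`chi2_correction={yates|none}`. Wider tables use the plain Pearson
statistic with df = r − 1, skipping cells with zero expectation.

`chi2_auto` adds the empty-column rule used for sparse pair tables:
drop all-empty columns first; if exactly two columns remain, the table
is scored with the corrected 2 × 2 formula (a sparse two-state pair
table carries exactly the information of an individual-gene table);
otherwise plain Pearson. Degrees of freedom follow the reduced width.

### Score backends

`rs` (default), `entropy`, and `chi2` are drop-in scoring rules with
identical interfaces over the same tables. The entropy backend applies
`(H_max − H)/H_max` to the same row + column decomposition as
complexity — every frequency-weighted term `n_i log₂(n_i/N)` becomes a
probability-weighted Shannon term — so it differs from RS precisely by
discarding absolute frequencies. (No canonical formula exists for this
comparator; this construction is the package's own, chosen to isolate
the frequency-weighting difference.) The chi2 backend scores
individual tables with the corrected statistic, and pairs with the sum
of the horizontal corrected statistic and the vertical `chi2_auto`
statistic.

## Integrated ranking

`IRS_j = RS_j + Σ_{q≠j} [RS_j/(RS_j + RS_q)] · RS_{j,q}` over **all**
p − 1 partners — an exact O(p²) evaluation, vectorised via per-class
mass matrices (tie mass included) so that p in the thousands remains
tractable; cell masses are multiples of 0.25 and sum exactly in
floating point. When `RS_j = RS_q = 0` the weight is 0/0 and the pair's
credit is defined as 0 for both genes (two individually uninformative
genes direct no credit; this also keeps the formula literal — see
Limitations). Ranking is descending by IRS with ties broken by input
gene order; a `pair_subset=K` accelerator restricting partners to the
top-K individually scoring genes exists but is off by default and
unused in any validation.

## Selection and classification

**Direct classification** is transductive and parameter-free: assign
the query sample each candidate label in turn, merge it with the
training samples, recompute the subset score on the merged data
(endpoints included), and predict the label with the strictly larger
score; ties go to the negative label (or the later class of a contest).
Single-gene subsets compare the gene's individual score; larger subsets
compare the network score `RS_net = Σ_j Σ_{q≠j} RS_pair(j, q)` (each
unordered pair counted twice). If an assignment empties one class, its
score is defined as 0.

**Forward selection** walks the integrated ranking: the first gene sets
the benchmark unconditionally at its leave-one-out MCC; each later
candidate within the scan bound B (default 100) is kept only on a
*strict* MCC improvement. The leave-one-out scheme is itself
transductive: the held-out sample is merged back, relabelled, before
scoring, so training statistics always cover all n samples — this
deliberately mirrors the selection-time classifier rather than
conventional LOOCV. MCC is defined as 0 when any confusion-matrix
marginal is empty. The whole procedure is deterministic.

**Multiclass** fitting runs outlier adjustment once, then per class:
one-vs-rest split → integrated ranking → forward selection, yielding m
binary-discriminative informative gene (BDIG) subsets. Prediction is a
sequential tournament in canonical class order (first-appearance order
unless configured): classes 1 and 2 contest first, restricted to their
training samples and the union of their BDIG subsets, decided by the
direct classifier with the earlier class in the positive role; the
winner meets the next class; the last winner is the prediction
(m − 1 contests, balanced contest sample sizes). The tournament is not
provably order-invariant; the order is therefore explicit and
configurable.

## Synthetic data

The generator plants pairs of genes following six joint-effect
templates — consistent reversal of expression (I) and of relative
expression (II), consistent expression (III) and relative expression
(IV), heterogeneous sample background (V, where within-class background
levels alternate across samples and defeat any single-gene threshold),
and interaction (VI, where only the joint state carries the class).
The target class expresses a pattern's positive template, every other
class its negative template; multi-variant patterns alternate variants
across samples within a class. Defaults: additive Gaussian jitter with
sd = 5 % of each pattern's template range; noise genes i.i.d. uniform
on [5, 110], spanning the template levels; everything is determined by
one seed. An 8-sample × 12-gene noise-free fixture containing all six
patterns is built in, and at zero jitter the generator reproduces it
exactly.

What the generator does *not* emulate: probe saturation, batch effects,
heavy-tailed platform noise, gene–gene correlation among noise genes,
class imbalance beyond what the spec requests. Passing tests therefore
demonstrate the machinery and its detection logic, not field
performance on real microarrays.

## Validation problem sizes

Chosen once as realistic for the small-n / large-p regime: the scoring
property suite enumerates all 2 × 2 integer tables with n ≤ 12 and
checks 10,000 random tables; ranking equivalence against the literal
double-loop oracle uses p ≤ 30, n = 12; pattern-recovery rankings use
binary datasets of 40 samples × 512 genes (12 planted, 500 noise) over
20 seeds; end-to-end classification uses 3 classes × 10 samples with
30 genes, with a 20-seed label-permutation control evaluated on
independent draws.

## Known limitations

* Under the literal integrated-score formula, a gene whose individual
  RS is exactly 0 receives zero weight on every pair term, so
  pattern V/VI genes — individually invisible by construction — collect
  (almost) no integrated credit and cannot outrank hundreds of noise
  genes that each accumulate many small pair terms. The horizontal
  rescue of pattern V is fully visible in the pair scores themselves
  and in the sparse-table chi-square, but not in the integrated
  ranking at large p. Forward selection can still pick such genes only
  if they survive the ranking cut.
* The no-floor continuity correction can exceed the uncorrected
  statistic when `|ad − bc| < n/2`; it is kept because it is the
  variant the reproduced reference values require, not as a
  recommendation for general inference.
* Transductive leave-one-out keeps the held-out sample in the scoring
  statistics (by design); reported benchmark MCCs are therefore not
  conventional cross-validation estimates.
* O(p²) pair evaluation per one-vs-rest task is exact but quadratic;
  tens of thousands of genes call for the top-K accelerator at the
  cost of exactness.
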