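# Methods

This note documents the models, conventions and design choices behind
`diagrank`, in the spirit of the methods documentation of mature statistical
packages: what is computed, under which assumptions, which defaults were
genuinely open choices, and what the bundled tests do and do not establish.

## Criteria from cross-validated predictions

All criteria are computed from hard (0/1) predictions; probabilistic scores
and ROC-style analysis are deliberately out of scope. The positive label is
always caller-supplied semantics (the disease class), never inferred from
sort order. Internally every rate criterion lives on the fraction scale;
reports render percentages, and MCC is likewise reported on the percent
scale with the scale stated in the header.

Degenerate denominators follow the common conventions and are unit-tested:

* precision := 0 when tp + fp = 0 (no positive predictions);
* F1 := 0 when precision + sensitivity = 0;
* MCC := 0 (the random-prediction value) when any marginal of the
  contingency table is zero.

Fold aggregation uses the arithmetic mean and the **sample** standard
deviation (n − 1 denominator); with one fold the std is 0. One invariant is
worth stating explicitly: per fold F1 is exactly the harmonic mean of
precision and sensitivity, but the *mean over folds* of F1 is not the
harmonic mean of the mean precision and mean sensitivity — fold summaries
must be produced by averaging per-fold values, never by re-applying the F1
formula to column means.

## The bundled case study and one erratum

The package ships a transcription of a published benchmark of 19 CNNs for
binary melanoma diagnosis (five stratified folds, 491 melanoma / 500
non-melanoma images; criteria on the percent scale; parameter counts in
millions). The fixtures are validated for internal consistency on load:
per-fold accuracies must average to the summary accuracy column, the
complement identities Err = 100 − Acc, FNR = 100 − Sen, FPR = 100 − Spe must
hold at printed precision, and normalizing the raw matrix must reproduce the
published normalized matrix at its 4-dp precision.

One cell of the per-fold accuracy table is internally inconsistent in the
source: the DenseNet201 row as printed averages to 94.04 with sample std
4.91, while the summary table reports 93.94 ± 4.97. A fold-2 value of 91.44
(printed: 91.94) reproduces **both** the published mean and the published
std exactly, identifying the printed value as a typographical error. The
loader applies this erratum by default and keeps the verbatim table
available (`load_fold_accuracies(corrected=False)`). Because the fold values
are themselves printed at 2 dp, recomputed means are compared to the summary
column at one unit in the last printed digit (±0.01); that is the tightest
tolerance 2-dp inputs support, not a loosened target.

## Normalization

Direction-aware min/max scaling: beneficial columns are divided by their
maximum, non-beneficial columns invert to min/value. All entries must be
strictly positive (the non-beneficial rule divides by them). Normalization
is computed at full floating precision and rounded only in reports; for the
0/1 usual preference this is immaterial because preferences depend only on
within-column orderings, which are identical at 4-dp and full precision for
the bundled data — the reproduction tests confirm bit-identical flows either
way. Column extrema are taken over the supplied alternatives only; there are
no external reference values. A constant column normalizes to all-ones.

## Entropy weighting

The implementation uses the standard within-column form: shares are
column-normalized, entropy is summed over alternatives with the constant
g = 1/ln m, which is the only reading under which e_j ≤ 1 holds. The
p·ln p term is taken as 0 at p = 0. A uniform column has maximum entropy and
receives weight 0; if every column is uniform there is no discriminating
criterion and fitting raises. Entropy weights are provably non-negative,
sum to 1, and are invariant to positive rescaling of any column
(property-tested).

The case-study weight vector shipped with the fixtures is **not** an entropy
output: it contains negative values and magnitudes above 1, which the
entropy equations cannot produce (d_j ≥ 0 forces w_j ∈ [0, 1]). Its negative
signs fall exactly on the four non-beneficial criteria, but the procedure
that generated it is not recoverable from the published account, so the
package stores it verbatim as a user-supplied vector and does not guess a
derivation. Both weighting routes are first-class and selected by
configuration.

## PROMETHEE II conventions

* **Preference at ties.** The usual criterion is implemented as P(d) = 1 iff
  d > 0, hence P(0) = 0. The published description assigns both 0 and 1 at
  d = 0; P(0) = 0 is the standard resolution and the only one consistent
  with π(a, a) = 0. Ties do occur in the case-study matrix (two networks
  share 5.3 M parameters; two share a specificity column value), so the
  choice is load-bearing.
* **Weight signs.** The preference index uses weight magnitudes by default.
  With the signed case-study vector the published flows are not recovered;
  with magnitudes the recomputed flows match the published ones to ~1e−7
  (the residue of the 9-significant-digit printed weights). Signed use
  remains available (`weight_signs="signed"`) for sensitivity analysis.
* **Flow convention.** Flows are offered `averaged` (divide by m − 1, the
  textbook form and the package default) and `summed` (no division). The
  published case-study flows correspond to the summed convention, so the
  reproduction profile pins `summed`. The two differ by the constant factor
  m − 1 and never change the ranking.
* **Rank ties.** Exact score ties get consecutive ordinal ranks with a
  deterministic tie-break by alternative id, so output is stable across
  runs.

Net flows always sum to zero (π-antisymmetry), and a strictly dominant
alternative attains ϕ = Σ|w_j| under the averaged convention; both are
property-tested against a brute-force triple-loop reference.

## VIKOR conventions

* v defaults to 0.5 (the consensus convention, balancing group utility
  against worst individual regret); the source analysis never states its v,
  and v does not affect the Q endpoints.
* The default input is the normalized (max-oriented) matrix with weight
  magnitudes, matching the "same weights, same matrix" pairing with
  PROMETHEE. Raw-matrix mode with explicit beneficial/non-beneficial
  best/worst rules is also implemented, since the best/worst rules are
  stated for raw values.
* A criterion whose best equals its worst value cannot be scaled; the ranker
  either raises an error naming the criterion (default) or excludes it
  (`zero_range="exclude"`). If S and R are both constant over alternatives
  the input is degenerate and fitting raises; if exactly one of them is
  constant, its Q term is taken as 0 (it carries no discrimination).
* Reproduction surface: on the case study the recomputed Q endpoints
  (ResNet101 = 0 at the joint S/R minimum, SqueezeNet = 1 at the joint
  maximum, for every v), the top-two and bottom ranks, and 11 of 19 ranking
  positions match the published column. The published *intermediate* Q
  values (e.g. 0.080 for DenseNet201, vs 0.194 recomputed) could not be
  reproduced under any documented combination of matrix choice, weight-sign
  treatment and v that was tried; the convention that generated them is
  under-specified in the source. The package therefore reports its own
  values side by side with the reference column in the reproduction diff and
  asserts only the robust surface. The compromise-set ("acceptable
  advantage / acceptable stability") conditions of full VIKOR are not
  implemented, as they are not part of the benchmarked procedure.

## Synthetic data generator

`simulate_predictions` emulates the structure of the case study: a pool of
n_pos positive and n_neg negative cases (defaults 491/500, the case-study
counts) is split into stratified folds whose per-class sizes differ by at
most one, remainder folds first; each simulated classifier predicts each
test case independently — positives are called positive with probability
equal to the planted sensitivity, negatives are called negative with
probability equal to the planted specificity. All randomness flows through
one seeded generator; identical plans give bit-identical tables.

What it does *not* emulate: real classifiers evaluated on the same test
images make correlated errors (hard images are hard for everyone), class
imbalance effects, and fold-to-fold heterogeneity beyond binomial noise.
Passing tests on synthetic data therefore establish the correctness of the
decision pipeline (metrics → matrix → weights → rankings) and its ability to
recover planted orderings, not the behaviour of the methods under correlated
real-world error structure.

A note on the split arithmetic: 491 positives over five folds necessarily
yields fold sizes 99, 98, 98, 98, 98, so four of five training cycles see
393 positives and one sees 392. The generator implements the exact partition
and documents the ±1 discrepancy rather than forcing equal folds.

`planted_dominance_matrix` builds random positive matrices with one
alternative strictly best on every criterion (direction-aware); both ranking
methods must place it first, which is verified across 50 seeded draws.

## Problem sizes in the test suite

The suite keeps simulations small enough to run in seconds while remaining
statistically meaningful: oracle-equivalence checks use 200 random
prediction vectors of up to 50 cases and random matrices up to 8 × 6;
binomial-recovery checks use 200 cases per class per fold over five folds
(pooled n = 1000, so three binomial standard errors on a 0.9 sensitivity is
±0.028); the end-to-end ordering-recovery test uses 500 cases per class per
fold. These sizes were chosen as the smallest at which the tested
concentration bounds are sharp enough to be informative.

## Known limitations

* Only the usual (threshold) preference function is implemented; the other
  five classical PROMETHEE shapes (U, V, level, linear, Gaussian) are not.
* Binary classification only; no multi-class criteria.
* Entropy weights can be dominated by a single high-contrast column (the
  worked example in the README shows the parameter-count column absorbing
  0.59 of the weight); this is inherent to objective dispersion-based
  weighting, not a defect, but analysts should inspect the weight vector.
* The published intermediate VIKOR Q values remain unreproduced (see above);
  any analysis depending on them should treat the package's recomputed
  values as the self-consistent reference.
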