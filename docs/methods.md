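# Methods

## Problem setting

The package models one protein at a time. The data are N synonymous
codon encodings of that protein — in-frame DNA/RNA sequences of one
shared length — each with a measured expression level y > 0 in
arbitrary, protein-specific units, and optionally a precomputed
minimum-free-energy (MFE) value for the whole mRNA and/or a short 5'
window (kcal/mol). Models are protein specific by construction: the
codon-identification block has one column per codon position, the
expression scale is not transferable, and the MFE window convention
differs between panels. Attempting to score sequences of another length
with a saved model is an error, not a warning.

## Feature encodings

* **Codon identification.** Codons are numbered 1..64 by
  `1 + 16·i₁ + 4·i₂ + i₃` with letter indices A=0, C=1, G=2, T=3 — a
  4-ary-tree ordering in which codons differing in a late position get
  nearby numbers (AAA=1 is closer to AAC=2 than to ACC=6). The closed
  form is verified in tests against the full 64-entry published table.
  The block contributes L columns for an L-codon protein, far fewer
  than the 64·L of a one-hot encoding, at the price of imposing an
  ordinal scale; the tree ordering makes that scale meaningful.
* **Codon bias.** Within-amino-acid codon frequencies. Values are stored
  as fractions in [0, 1] rather than percentages: both regressors
  standardize features, so the ×100 constant is irrelevant, and
  fractions keep group sums exactly 1. A codon whose amino-acid group
  never occurs in a sequence gets bias 0. The genetic code is the NCBI
  standard table by default and injectable; the three stop codons form
  one synonymous group (every ORF in a panel carries exactly one stop).
  Two reductions of the 64-column block exist: dropping columns that are
  all-zero across the dataset (codons absent from every encoding), and
  restricting to an explicit user-chosen codon subset. The historical
  "selected" 15-codon subset is not published, so it is configuration
  input only, never a default.
* **Codon count.** Raw occurrence counts of each codon; sums to L.
* **MFE.** Always ingested, never computed — folding engines are an
  external concern. Whether the whole-sequence or the 5'-window value
  enters the model is a switch, because which one validates better is
  dataset-dependent. Window conventions (e.g. nucleotides −4 to 37
  counted from the ORF start) are metadata of the input table.

Blocks concatenate in the fixed order [MFE | bias | count | codon-ID].
For a 288-codon panel with all blocks this gives 1+64+64+288 = 417
columns; for a 575-codon panel in which only 61 distinct codons occur
and absent bias columns are dropped, 1+61+64+575 = 701.

## Regression backends

ε-SVR (RBF kernel, via LIBSVM through scikit-learn) and PLS regression
(scikit-learn) sit behind one fit/predict contract. Decisions worth
recording:

* **Standardization inside the training fold.** Features are scaled to
  zero mean / unit SD with training statistics only; constant columns
  pass through as zeros. Global scaling would leak test information
  into hyperparameter selection; no scaling would let the codon-ID
  block (range 1..64) dominate RBF distances.
* **Target never standardized.** Instead ε is specified relative to
  SD(y_train) and γ per feature (divided by the column count), so one
  grid transfers across panels whose expression ranges differ by two
  orders of magnitude.
* **Default grids** (all overridable): C ∈ {4⁻², …, 4⁶},
  γ·n_features ∈ {4⁻⁵, …, 4¹}, ε/SD(y) ∈ {0.01, 0.05, 0.1, 0.5};
  PLS components ∈ {1..10, 12, 14, 16, 18, 20}. These are coarse log
  grids around the library defaults; no claim is made that they match
  any historical study's grid, which was not published. Grid order is
  declared-list order with C slowest — it is also the tie-break order.
* **Reduced predictor state.** After fitting, models are collapsed to
  explicit arrays (PLS: weight vector + intercept; SVR: support
  vectors, dual coefficients, intercept, γ) and predictions are
  computed from those. This makes prediction independent of library
  object internals and lets models serialize to versioned JSON with no
  pickling.
* Degenerate inputs: a zero-variance target fits (with a warning) and
  predicts the constant; a PLS component count exceeding
  min(n_features, n_train−1) is clipped with a warning.

## Nested cross-validation

`make_fold_plan` deals shuffled pattern indices round-robin into m
outer folds, and, for each outer fold, deals the remaining patterns
into n inner folds — sizes differ by at most one ("equal size" is
impossible for most N, and near-equal is the only consistent reading).
Hyperparameters are selected per outer fold by minimizing the mean
validation RMSE over the inner folds, ties resolved to the earliest
grid point; different outer folds may select different grid points and
each fold's choice is recorded. The out-of-fold predictions assemble
into one prediction per pattern, from which the repetition's RMSE and
R² are computed.

Repetition r of the procedure regenerates *both* the outer and inner
groupings from seed `base_seed + r`. A single integer therefore pins
every random choice, and identical configurations produce byte-identical
result files. The final (deployment) model is fit on all patterns with
hyperparameters chosen by a plain n-inner-fold CV over all patterns.

R² is defined as the squared Pearson correlation between measured and
predicted values, reported in [0, 1]; the coefficient of determination
is exposed separately (`explained_variance_r2`) because the two diverge
for badly calibrated but well-correlated predictors. One pragmatic
exception to the strict definition: inside repetition scoring, a
constant out-of-fold prediction vector (possible for a degenerate SVR
fit whose ε band swallows all training points) is recorded as r2 = 0.0
with a warning rather than aborting the repetition; the standalone
`r_squared` raises on constant input.

## Ensemble averaging and error summaries

The ensemble prediction for pattern i is the arithmetic mean of its
out-of-fold predictions across repetitions; RMSE/R²/APE are computed on
that averaged vector. All repetitions get equal weight. The convexity
guarantee MSE(ensemble) ≤ mean(MSE_r) is asserted numerically in tests
for every ensemble formed. APE thresholds use strict inequality
("fraction with APE smaller than 30%"), configurable; histogram bins
default to 10-percentage-point widths from 0 to the maximum APE.

## Model comparison

Two configurations are compared through their per-repetition metric
distributions. Default: unpaired two-sample t-test with the Welch
unequal-variance correction and the Satterthwaite degrees of freedom,
reported with the (1−α) confidence interval on the mean difference
(α = 0.05). Whether the historical comparisons were paired or pooled
was never stated; unpaired Welch is the assumption-lightest default,
and a paired mode is provided for runs that shared base seeds (same
fold groupings), where it is strictly more powerful. Mann-Whitney is
the distribution-free cross-check: exact enumeration when both samples
have fewer than 20 values, normal approximation with tie correction
otherwise; it yields a p-value but no CI on the mean difference. No
multiple-testing correction is applied across comparisons — reported
CIs are per-comparison, as in the protocol this reproduces; apply your
own correction when scanning many comparisons.

## Synthetic data generator

The generator emulates the structure of real expression panels — many
same-length synonymous encodings of one protein — with a known signal:

    y_i = exp( Σ_f w_f·x_{i,f} + ε_i ),   ε_i ~ N(0, noise_sd²)

over codon-bias features and an MFE surrogate. Choices and what they
mean:

* **Exponential link**: keeps y > 0 (APE needs it) and produces the
  right-skewed, wide dynamic ranges real panels show. It also makes the
  zero-noise benchmark deliberately *not* exactly linear in the
  features — a linear model's test R² tops out around the squared
  correlation between exp(z) and z.
* **MFE surrogate**: −10 × GC fraction of the first 42 nucleotides.
  Real 5'-window folding energies are lower (more stable) for GC-rich
  5' ends; the surrogate preserves that sequence dependency
  deterministically without a folding engine. It does not reproduce
  actual base-pairing energetics, positional structure, or the
  whole-mRNA/window distinction's subtleties.
* **Uniform synonymous sampling**: each variant picks uniformly among
  the synonymous codons per position, so bias features vary freely.
  Real panels are designed, not uniform; tRNA-pool kinetics are not
  modelled. Passing tests on this generator therefore demonstrates the
  *pipeline's* correctness (no leakage, signal recoverable when
  present, honest nulls), not field performance on laboratory data.
* **Defaults** (chosen once as the study-scale conditions): 150
  variants of a 95-amino-acid protein, noise_sd 0.3, weights over
  common leucine/alanine/arginine codon biases (±0.8–1.0) plus 0.1 on
  the MFE surrogate — magnitudes that span about one decade of
  expression. An optional saturating mode passes the linear predictor
  through tanh.

## Problem sizes and configurations used in the checks

The end-to-end checks use the MFE + bias feature blocks (65 columns) —
the blocks the generator's signal actually lives in, and the classic
reference-model configuration. With all four blocks enabled the 160+
signal-free count/ID columns dominate the RBF distance and dilute PLS
directions at N = 150, which is a real property of the method worth
knowing, not a test artifact. Runs use 7 outer / 6 inner folds at
N = 150 (and 6/5 at N = 120), 10–20 repetitions, and compact grids
(PLS components 1–12; SVR C ∈ {4¹..4⁵}, ε/SD ∈ {0.05, 0.1},
γ·n_features ∈ {4⁻²..4⁰}) — enough repetitions for stable ensemble
behaviour while keeping the suite quick; production runs would use the
full default grids and 100 repetitions.

## Known limitations

* Ordinal codon-ID scale is a modelling assumption, not biology; its
  usefulness rests on the tree ordering.
* Expression units are arbitrary and per-panel; RMSEs are not
  comparable across proteins.
* Mann-Whitney exactness switches at n = 20 per sample; near the
  switch, p-values change discontinuously in the fourth decimal.
* The generator's MFE surrogate and uniform codon sampling are
  idealizations (see above); no claim about laboratory panels follows
  from synthetic benchmarks alone.
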