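# Methods

## Problem and model

`phageprom` identifies promoters in bacteriophage genomic sequence and
classifies them by origin. Phage genomes carry two kinds of promoters: those
recognized by the host's bacterial RNA polymerase (sigma70-style −35/−10
boxes) and those recognized by a phage-encoded single-subunit RNA polymerase
(longer, highly conserved elements, e.g. the T7 class). The classifier is a
two-layer cascade of independent binary CNNs:

1. **layer 1** — promoter vs non-promoter, gating at probability ≥ 0.5;
2. **layer 2** — run only on layer-1 positives: phage vs host promoter.

`p_phage` is the probability of the phage class. In the original benchmark
convention phage promoters are the layer-2 minority/"negative" class and host
promoters the majority/"positive" class; the output header states the mapping
both ways to avoid ambiguity.

### CNN

Input is a zero-padded 99×C positional encoding (C = 4 for one-hot). The
network is, in order: two blocks of [Conv1D(16 filters, kernel 5, ReLU, same
padding) → MaxPool(size 4, stride 2) → Dropout 0.5], then Flatten →
Dense(64, ReLU) → Dropout 0.5 → Dense(1, sigmoid). Kernel and bias L2
penalties of 1e-4 apply to the convolutional and dense layers. Training
minimizes binary cross-entropy with Adam (learning rate 1e-3, β₁ = 0.9,
β₂ = 0.999, ε = 1e-7) at batch size 20 for a fixed 85 epochs — no early
stopping and no validation split. These values are the package defaults; all
are exposed on `CNNConfig`.

The implementation is pure numpy (im2col convolutions, hand-written backward
passes, Glorot-uniform initialization, inverted dropout) and is exactly
reproducible given `CNNConfig.seed` on a single thread. Border handling is
"same" padding so the 99-row input survives two valid poolings
(99 → conv → 99 → pool → 48 → conv → 48 → pool → 23); padding mode, the
initializer and the Adam learning rate are not architecture-defining and are
configurable. Under the defaults the classification threshold is 0.5 for both
layers (`threshold`, `threshold2` on `CascadeModel`). Layer-2 training is
unweighted by default even for imbalanced datasets, mirroring the benchmark
protocol; `fit` accepts any labeled set, and class weighting can be emulated
by resampling upstream.

## Hard-negative generation

Non-promoter training examples are derived from the promoters themselves.
Each positive is cut into 8 contiguous blocks of near-equal size (a 99-mer
gives sizes 13,13,13,12,12,12,12,12, remainder front-loaded); 5 block slots
are chosen uniformly at random; the blocks in those slots are rearranged by a
uniform random derangement (no selected block stays in its own slot; sampled
by rejection) and the rearranged content is re-cut to the slot sizes, so the
3 unselected blocks keep their exact coordinates. For lengths divisible by
the block count this is a pure block permutation. Consequences:

* output length and base composition are always conserved;
* at least 3 of 8 blocks are position-conserved in every output;
* the mean conserved-position fraction over random 99-mers is 3/8 = 37.5%,
  inside the 35–40% band that makes these negatives "hard": they share
  substantial local sequence with real promoters, so the classifier cannot
  separate the classes on composition alone.

The derangement (rather than an unconstrained permutation of the selected
blocks) is deliberate: allowing chance fixed points would raise the expected
number of in-place blocks to 4 of 8 and the conserved fraction to ~50%,
defeating the 35–40% design target. `conserved_fraction` compares block
content slot-by-slot on the shared grid, so shuffled blocks that coincide in
content by chance are (correctly) credited as conserved.

Each record in a dataset build uses an RNG substream keyed by
`(seed, record index)`, making results independent of slicing order.

## Feature encodings

Ten schemes share one backend. Positional matrices (`onehot` 99×4, `ncp`
99×3) are zero-filled to 99 rows; `N` encodes as an all-zero row. All
composition vectors are computed on the unpadded sequence — zero-filling
would corrupt frequency statistics — and windows containing `N` are excluded
from counts and correlation terms (denominators use the number of valid
terms).

* `kmer`: overlapping k-tuple frequencies (k = 3 default), normalized by the
  window count L−k+1 so they sum to 1.
* `pseeiip`: 64 trinucleotide frequencies weighted by the summed
  mononucleotide electron-ion interaction pseudopotentials
  (A 0.1260, C 0.1340, G 0.0806, T 0.1335); a `mode="mean"` switch divides
  the weight by three for users who read "mean EIIP" literally.
* `psednc` / `pcpsednc` / `pcpsetnc` / `pseknc`: pseudo-composition vectors
  `[f / Z, …, w·θⱼ / Z]` with `Z = Σf + w·Σθ`, where θⱼ averages the
  squared-difference correlation Θ(i, i+j) = meanᵤ (Pᵤ[i] − Pᵤ[i+j])² over
  window pairs at rank j. Dimensions are 16+λ, 16+λ, 64+λ and 4^k+λ; all sum
  to 1 by construction.
* `dacc` = `dac` (N·LAG auto-covariances) ++ `dcc` (N·(N−1)·LAG
  cross-covariances) of the standardized index profiles, each term averaged
  over its L−lag−1 window pairs.
* `moran`: Moran spatial autocorrelation I(u, lag) of each standardized
  dinucleotide index profile; a zero-variance profile yields 0 by definition.

Defaults λ = 2, w = 0.1, LAG = 2, k = 3: small enough for 99-bp inputs, in
the usual range for pseudo-composition descriptors, and all overridable via
`EncoderParams`.

### Physicochemical index tables

All Pse/covariance encoders standardize each index to mean 0 / population
SD 1 over its 16 (or 64) oligonucleotides before use, so only the relative
structure of a table matters. Three tables ship as TSV package data:

* `dinucleotide_indices_6.tsv` — approximate literature B-DNA step parameters
  (twist, tilt, roll, shift, slide, rise); default for PseDNC, PseKNC,
  DAC/DCC/DACC and Moran.
* `dinucleotide_indices_38_synthetic.tsv` — a **synthetic stand-in** for a
  curated 38-index dinucleotide reference set (deterministic seeded draws;
  the curated list is not redistributable). It exercises the identical code
  path; users wanting biologically meaningful PCPseDNC features should pass
  their own `PhysicochemicalIndexSet`.
* `trinucleotide_indices_6.tsv` — derived exactly from authentic constants
  (triplet GC and purine fractions, summed EIIP, and summed
  SantaLucia nearest-neighbor ΔG°₃₇/ΔH/ΔS of the two component steps);
  default for PCPseTNC.

The Moran descriptor is defined here on dinucleotide physicochemical
profiles; protein-style amino-acid autocorrelation has no meaning for a DNA
tool.

## Synthetic benchmark

`synthetic_data` emulates a phiSITE-style promoter benchmark so the whole
pipeline is testable without downloads. Host promoters implant an AT-tract
UP element (`AAAATTTT`, starts 3–7), a −35 box (`TTGACA`, starts 20–24) and a
−10 box (`TATAAT`, starts 48–52), each with 5% per-base mutation; phage
promoters implant a 23-bp T7 φ10-class consensus
(`TAATACGACTCACTATAGGGAGA`, starts 37–41, 2% mutation). Background is
uniform i.i.d. A/C/G/T; real phage promoter regions are AT-rich, and the
background frequencies are a recipe knob, but uniform is the default so the
classes cannot be separated by composition alone. Layer-1 positives are an
even phage/host mixture; negatives come from the hard-negative generator, so
they share 35–40% conserved blocks with their source promoters by
construction. Defaults are n = 500 per class at 99 bp.

The recipe was calibrated once so that, under the fixed model and training
protocol above, 5-fold cross-validation with one-hot + CNN reaches ~0.92
mean accuracy and the cascade ~0.93 three-class accuracy — learnable but not
trivial (wider motif windows or 10% mutation rates drop CV accuracy to
0.81–0.88). The motif model is consensus + i.i.d. mutation, not a PWM, and
the generator makes no claim of matching real promoter statistics: passing
tests demonstrate that the pipeline can learn degenerate positional motifs
against hard negatives, not that it attains any particular accuracy on real
phage genomes.

## Evaluation

Acc, Sn, Sp, precision/recall and MCC are computed from confusion counts;
MCC with a zero denominator is defined as 0. ROC points and AUROC use the
"score ≥ threshold ⇒ positive" convention with trapezoidal integration
(AUROC equals the Mann–Whitney statistic, ties counted half). Stratified
k-fold cross-validation (k = 5 default) reports the unweighted mean over
folds and retains per-fold reports; fold sizes differ by at most one.

## Numerical and design notes

* Sequences longer than 99 bp are rejected, not truncated; any length
  1–99 is accepted and zero-padded at encoding time.
* Sigmoid is evaluated in a numerically stable branch form; training aborts
  with a diagnostic if the loss goes non-finite.
* `standardize_indices` refuses constant indices (undefined z-score) naming
  the offending index; standardization is idempotent.
* Stratified splits round the per-class test count to the nearest integer
  and clamp it to [1, n−1], preserving class ratios within one record.
* Baseline models are seeded wrappers over scikit-learn/xgboost with library
  defaults; "SVM bagging" is a bagging ensemble of 10 probability-calibrated
  SVCs. Multinomial naive Bayes rejects negative-valued encodings with an
  explicit error rather than failing inside the library.
* Model archives are a zip of `config.json` (with a schema version) plus the
  weight tensors; loading verifies the schema version and round-trips
  predictions bit-for-bit.

## Problem sizes

The test suite trains CNNs on 40–1,000 sequences (up to the default
n = 500/class benchmark with 5-fold cross-validation plus a full cascade) and
drives the negative-generator statistics with 10,000 sequences; the complete
suite runs in a few minutes on one CPU. These sizes give stable estimates for
the properties asserted while keeping the package quick to check.

## Known limitations

* The real phiSITE-derived benchmark and the originally trained weights are
  not distributed; accuracies on the synthetic benchmark do not transfer to
  real genomes.
* The default 38-index PCPseDNC table is a labelled synthetic stand-in (see
  above).
* No genome-wide scanning: inputs are pre-extracted ≤ 99-bp fragments.
* Layer-2 probabilities are not recalibrated for class imbalance; with
  heavily imbalanced training sets the 0.5 threshold favours the majority
  class.
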