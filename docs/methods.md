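# Methods

## Problem and model

The package discriminates cis-Golgi from trans-Golgi resident proteins from
primary sequence alone. The classifier is a random forest over two
composition encodings; no evolutionary information (alignments, PSSMs) is
used, which keeps prediction cost at O(L) per sequence and makes the model
portable to settings without database access. The working assumption is
that compartment identity is reflected in (a) medium-range dipeptide
statistics — residue pairs bridged by hydrogen bonding across helix/sheet
geometry — and (b) the residue chemistry of the terminal segments, which
host signal-anchor domains.

## Encoders

**k-gapped dipeptide composition.** For gap k (default 2, "k intervening
residues"), the feature for ordered pair (A1, A2) is

    count{ i : s[i] = A1 and s[i+k+1] = A2 } / (L − k − 1),

a 400-vector summing to 1. A sequence must satisfy L ≥ k + 2. The gap
convention is configurable (`gap_convention="distance"` pairs positions i
and i+k with normaliser L − k) because the literature is not unanimous
about whether "k-gap" counts intervening residues or index distance; the
intervening-residue reading is the default as it matches the k-spaced
amino-acid-pair (CKSAAP) convention prevalent in this problem area. Feature
names follow the `A1A2.gapK` pattern (e.g. `FP.gap2`) so that importance
reports read naturally.

**Split amino acid composition.** Three blocks — N-terminal (Xn = 30
residues), intermediate, C-terminal (Xc = 30) — each yield a 20-entry
frequency vector normalised by its own block length; each block sums to 1
(60 features total, names `Nterminal_A` / `InterTier_A` / `Cterminal_A`).
Sequences shorter than Xn + Xc + 1 are rejected rather than encoded with
overlapping or truncated segments: overlap would double-count residues and
there is no principled way to apportion them.

## Feature selection

Features are ranked by the two-group one-way ANOVA F statistic, the
between-class mean square (df = 1) over the pooled within-class mean square
(df = N − 2); for two groups this is exactly the squared pooled t
statistic, and it is invariant to affine rescaling of a feature.
Degenerate columns get sentinels instead of epsilon-regularised scores: a
feature with zero within-class variance but distinct class means scores
+inf (it must rank first), a globally constant feature scores 0. Ties are
broken by original column index, making the ranking deterministic.

Ranking is computed on the original labeled matrix, *before* SMOTE, so
synthetic samples never influence which features are kept.

## Class balancing

SMOTE brings the minority class to parity with the majority: each synthetic
sample is z = x + u (x′ − x) with x a uniformly drawn minority row, x′ one
of its k = 5 nearest minority neighbours (Euclidean distance on the raw
composition values, which already live in [0, 1]; no standardisation), and
u uniform on [0, 1]. If the minority class has m ≤ k members, k is reduced
to m − 1 with a warning. Original rows are preserved bit-identically, in
input order, ahead of the synthetic block, and the draw is a single-seed
deterministic stream.

## Evaluation protocols

Jackknife cross-validation is leave-one-out with pooled confusion counts
(per-fold averaging is meaningless with one-sample test folds). Each fold's
forest uses seed + fold-index, so one integer reproduces the whole run.
Metrics are ACC, Sn (recall on trans, the positive class), Sp (recall on
cis) and MCC; an MCC whose denominator contains a zero factor is defined as
0. Note that a fully misclassified confusion matrix has a *non-zero*
denominator and MCC = −1; the 0 convention applies only to genuinely
undefined cases such as a single predicted class. The positive class is
fixed to trans because the benchmark test composition (51 trans, 13 cis)
together with the conventional Sn/Sp orientation is only internally
consistent that way.

The independent test is a single prediction pass on a held-out labeled set;
the test set is never balanced and never re-encoded with training
statistics.

**Leakage.** The classical protocol — select features and SMOTE-balance on
the full training set, then cross-validate — leaks both selection and
synthetic-neighbour information across folds and flatters jackknife scores.
The default pipeline reproduces that protocol for comparability, and the
caveat is deliberate and documented. `safe_jackknife` is the honest
counterpart: ANOVA ranking, top-n selection and SMOTE are all refit inside
every training fold. On signal-free data the safe protocol stays at chance;
the classical one need not.

## Two-stage optimization pipeline

Stage 1 sweeps top-n dipeptide subsets for n = 1..n_max (default 100; an
n_max above the column count is clipped with a warning), recording
jackknife and independent metrics per n. The winner is the n with the
highest jackknife accuracy by default (`selection_criterion="cv_acc"`);
selecting by independent accuracy is supported but optimistically biases
the reported held-out metrics, and is flagged as such. Ties go to the
smallest n. Stage 2 fuses the winner's dipeptide columns with the 60 SAAC
columns (survivors first) and re-ranks the fused matrix from scratch; the
final model is trained on the stage-2 winner's balanced matrix. All stage
seeds derive deterministically from one master seed, and the run report
records the chosen n, feature lists and sub-configs needed to replay any
stage in isolation.

## Random forest

scikit-learn's `RandomForestClassifier` behind a thin contract layer:
500 trees and sqrt-feature subsampling by default (stable impurity-based
importances at ≤ 460 features; the original hyperparameters for this
problem are not recoverable, so defaults favour reproducibility and are all
exposed). Prediction aligns columns to the training feature names, so
column order is irrelevant and name mismatches are hard errors. A 50/50
forest vote goes to the positive class (deterministic tie rule).
Importances are mean impurity decrease, normalised to sum 1. Determinism
holds at the prediction level for a fixed seed and library version;
bit-level floating point may differ across BLAS builds, predictions in
practice do not.

## Importance breakdown

Forest importances are re-allocated to the five Lehninger residue classes
(aromatic F/W/Y; non-polar aliphatic G/A/V/L/I/P/M; polar uncharged
S/T/C/N/Q; positively charged K/R/H — histidine counted as positively
charged, not aromatic; negatively charged D/E). A dipeptide feature
contributes half its importance to each member residue's class; a SAAC
feature contributes fully to its residue's class and, on a separate axis,
to its segment. Class percentages therefore sum to 100 exactly, segment
percentages to the SAAC share. `top_cumulative` returns the smallest
importance-ranked prefix reaching a given cumulative fraction.

## Synthetic data generator

The generator emulates the shape of the curated benchmark sets: 42 cis /
95 trans training records (minority/majority ratio 0.44) and a 13 / 51
test split, sequence lengths uniform on [80, 600] residues (the minimum
must stay ≥ 61 so SAAC is defined). Residues are i.i.d. from a background
distribution — uniform by default so the ANOVA null is exactly exchangeable
between classes; a natural-frequency background can be supplied. Signal is
planted two ways: a gapped-dipeptide motif rewrites eligible positions i to
(A1, A2 at i+k+1) with a per-position excess probability (default 0.15) in
one class, and a terminal bias rewrites positions inside one SAAC segment
to a chosen residue. Rewrites happen in position order with
last-writer-wins overlap resolution, keeping generation O(L).

What this does *not* emulate: homology structure, realistic length/
composition correlations, phylogenetic redundancy, or the low (<25%)
sequence-identity curation of real benchmarks. Passing tests on this
generator demonstrate that the pipeline recovers planted composition signal
and stays calibrated under the null — not that real cis/trans discrimination
reaches any particular accuracy.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: planted-signal checks
use 100 sequences per class with excess rate 0.15, forests of ~100 trees,
and top-20 feature subsets; the ANOVA-recovery check spans 20 generator
seeds. Library defaults remain 500 trees and n_max = 100. Composition
normalisation identities hold to 1e-12; F-statistic oracle agreement is
asserted to 1e-9 relative; feature tables round-trip CSV at repr precision.
Seeds everywhere are single integers below 2^31, with sub-seeds derived by
a fixed affine hash so that every stage is independently replayable.

## Known limitations

- The classical (default) protocol's jackknife scores are optimistic by
  construction; use `safe_jackknife` for honest generalization estimates.
- Impurity-based importances are biased toward high-cardinality/high-
  variance features; the physicochemical breakdown inherits that bias.
- SMOTE interpolation can place synthetic compositions off the simplex of
  realisable sequences (each feature stays within the minority bounding
  box, but joint constraints between features are not enforced).
- With very short minority classes (m = 2, 3) SMOTE degenerates to points
  on a handful of segments, and jackknife folds may lose a class entirely;
  the fold then trains on the remaining class and is scored as-is.
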