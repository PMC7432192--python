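# Methods

This note documents the models, defaults and design choices behind
`lncdbn`, and what the bundled synthetic benchmark does and does not show.

## Problem framing

Association databases record only verified positive lncRNA–disease pairs.
We therefore build one one-vs-rest binary problem per cancer: positives are
the lncRNAs recorded for that cancer, negatives are sampled uniformly
without replacement from every dataset lncRNA not recorded for it (default
ratio 1:1). lncRNAs known for *other* cancers remain eligible negatives —
this matches the per-cancer framing, at the cost of occasionally labelling
a truly-associated-but-unrecorded lncRNA as negative, which biases measured
AUC slightly downward. Only cancers with strictly more than
`min_positives` (default 20) surviving positives are retained, so every
fold of a 10-fold stratified split contains at least two positives.

## Features

**Gene panel.** A gene enters the feature panel iff strictly more than
`threshold` (default 5) distinct lncRNAs target it; on the full curated
target table this yields a 45-gene panel. The panel is ordered by
(descending lncRNA count, gene symbol) — the ordering is arbitrary but must
be fixed and recorded, because feature positions are meaningless without
it. The panel is computed once on the full target-gene table, not per
training fold. This mirrors how the 45-gene panel is fixed globally before
any cross-validation and is a known, deliberate source of mild optimism:
panel membership uses no labels, so the leakage is limited to the cohort
composition.

**Expression.** The 13-tissue profile is min–max scaled per tissue over the
dataset by default (`scaling="minmax_per_tissue"`, constant columns map
to 0), so both rows of the final 2×13 feature live on a comparable (0,1)
scale — the gene row consists of sigmoid outputs. Raw values
(`scaling="none"`) are available; nothing in the method requires either
choice, but unscaled magnitudes (log-normal, long right tail) would
dominate tanh-activated convolutions.

The default tissue list has 13 entries (adipose, adrenal, breast, colon,
heart, kidney, liver, lung, lymph node, ovary, prostate, testis, thyroid)
and is fully configurable; the pipeline only requires that the expression
table and the encoder output agree on width.

## DBN encoder

Bernoulli–Bernoulli RBMs with energy `E(v,h) = −a·v − b·h − h·W·v`,
trained by CD-k (default k=1): hidden probabilities from data give the
positive statistics, one block-Gibbs step (sampled hidden states,
probability reconstructions for the visible layer) gives the negative
statistics. Layer sizes default to (32, 13): the second hidden layer must
match the 13-tissue row so the two can be stacked, and a 12-unit variant
(configurable) is rejected at feature-combination time rather than padded.
Defaults: learning rate 0.1, 100 epochs, mini-batches of 16, weights
initialised N(0, 0.01²), biases 0 (zero weights would leave hidden units
symmetric and unable to specialise). The stack is trained greedily; each
layer trains on the previous layer's hidden *probabilities*, not samples —
the deterministic, lower-variance convention. Encoding is the composed
hidden-probability map: deterministic, outputs strictly inside (0,1).

The DBN is unsupervised and is fit once per dataset on all lncRNAs' gene
vectors. Because no labels enter the encoder this is not label leakage, but
test-fold feature vectors do influence the encoding; `dbn_per_fold=True`
provides the strict variant that refits the encoder on each training fold.

## Classifier

The CNN treats the 2×13 matrix as a one-channel image: conv 64 filters
(1,4) → maxpool (2,2) → conv 128 filters (1,2) → maxpool (1,2) → dense 512
→ 2 output units, tanh activations throughout and sigmoid outputs. Valid
padding with pool stride equal to pool size is the only convention under
which this layer sequence fits a 2×13 input; the resulting shape chain is
(2,10,64) → (1,5,64) → (1,4,128) → (1,2,128) → 256 → 512 → 2. The two
output units are independent sigmoids trained with per-unit binary
cross-entropy against one-hot labels; the association score is the positive
unit. Forward and backward passes are written directly on float64 numpy
arrays (im2col convolutions); an analytic-vs-numerical gradient check in
the test suite guards the backpropagation.

Training defaults: Adam, learning rate 1e-3, 200 epochs, full batch.
Training sets here are tiny (tens to low hundreds of samples), so
full-batch training is cheap and removes mini-batch noise; Adam was chosen
over plain SGD (also available, `optimizer="sgd"`) because it reaches both
perfect training accuracy on separable toy sets and high held-out AUC on
the planted-signal benchmark in fewer epochs, with no per-problem
learning-rate tuning. The DNN baseline uses hidden layers (64, 32), tanh,
same head and optimizer, on the flattened 26-dim feature — sized to the
same order of parameter count as the CNN's dense stage.

## Baselines and harness parity

PCA–CNN replaces the DBN code with 13 principal components (parity with the
code width makes the encoder comparison fair); components are fit per
training fold by default (`pca_global=True` mirrors the DBN's global fit).
When a gene panel is narrower than 13 the component count is capped at the
panel width and the code zero-padded. DBN–DNN keeps the encoder and swaps
the classifier. Folds and negative samples are derived from the experiment
seed and the cancer name only — never the method — so all methods see
byte-identical splits.

All stage seeds derive from one experiment seed through a stable tag path
(CRC-32 of stage name + indices into a `SeedSequence`), so any sub-result
(one fold, one sampling) is reproducible in isolation.

## Metrics and summaries

AUC is computed as the Mann–Whitney rank statistic (ties credited 1/2);
AUPR as the area of the step precision–recall curve over descending
distinct thresholds, ties grouped, no interpolation. Both are checked in
the tests against exhaustive enumeration and against scikit-learn.
Reports always carry a `summary_type` field: `pooled` (metric on the
concatenation of held-out scores across folds/cancers) and `macro` (mean of
per-cancer values) are computed independently and never substituted for one
another — with unequal per-cancer sample sizes they genuinely differ.

## Synthetic benchmark

The generator emulates the three input tables with planted signal:
associated lncRNAs target each of `n_linked_genes` (default 15) designated
panel genes with probability `p_in` (default 0.6) versus background
`p_bg` (0.1), and receive a `+expr_shift` (2) baseline-SD mean shift in
`n_shift_tissues` (3) designated tissues over a log-normal
(meanlog 1, sdlog 1) expression baseline. Default cohort: 300 lncRNAs, 200
genes, a 45-gene panel, one cancer with 60 positives. lncRNAs without a
planted cancer are attached to small filler conditions (15 lncRNAs each, under
the cohort threshold) so they enter the association universe as negative
candidates without creating spurious cohorts. Truth labels are emitted
out-of-band (`truth.yaml`) so the TSVs stay byte-compatible with the
real-data readers.

What passing on this benchmark shows: the pipeline recovers a planted
joint gene+expression signal far above chance, collapses to AUC ≈ 0.5 under
label permutation, and the three methods are comparable on identical
splits. What it does not show: performance on real curated data, whose gene
panel is sparser and correlated, whose expression has batch and annotation
artefacts, and whose "negatives" are unverified absences; the generator
plants independent Bernoulli targeting and i.i.d. log-normal expression,
both cleaner than reality.

## Numerical choices and degenerate inputs

- Sigmoids via `scipy.special.expit` (saturates, never NaN); reconstruction
  cross-entropy clamps probabilities at 1e-12.
- Tied prediction scores are written in deterministic order (descending
  score, then lncRNA id).
- Expression rows with missing values are dropped and counted, not imputed.
- An lncRNA absent from the target table encodes as an all-zero gene vector
  (with a warning) at predict time; at assembly time such lncRNAs are
  excluded by default (`require_targets=True`).
- Constant expression columns min–max scale to 0 rather than dividing by
  zero.
- PCA on rank-deficient gene matrices keeps zero-variance trailing
  components by default; `on_deficient="error"` makes it strict.

## Known limitations

- Real-database snapshots (association, target, expression) differ between
  releases; numbers computed on them are snapshot-specific by nature.
- The per-cancer models are independent; no information is shared across
  cancers, and cancers barely above the cohort minimum yield noisy fold
  metrics (21 positives across 10 folds leaves ~2 positives per held-out
  fold).
- The DBN is an encoder only; it is never fine-tuned jointly with the
  classifier.
- Negative sampling assumes unrecorded means unassociated; measured AUC is
  a lower bound to the extent that this fails.
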