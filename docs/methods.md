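# Methods

## Data model

A panel couples, on one cell-line index: log-scale gene expression
(cell line × gene), gene-level minimum and maximum integer copy numbers
with a per-line average ploidy, and long-format somatic variant records
(`cell_line`, `gene`, `consequence`). Drug responses are a drug ×
cell-line table of binary labels with NA for unscreened pairs;
"sensitive" is the positive class everywhere. All on-disk formats are
plain TSV; a JSON sidecar stores the synthetic ground truth.

## Preprocessing

* **Transcript collapsing.** Transcript-level expression is mapped to
  gene symbols; multiple transcripts of one symbol are averaged
  (arithmetic mean), unmapped transcripts are dropped with a logged
  count.
* **Variance filter.** The top `keep_fraction` (default 0.2) of genes
  by sample variance are kept — `ceil(keep_fraction · p)` genes, in
  their original column order. Variance ties at the cutoff resolve to
  the gene earlier in input order, so the selection is reproducible.
  The filter is fit on the training panel before gene alignment with
  the external panel; the pipeline also restricts the copy-number and
  mutation layers to the retained genes so all layers share one gene
  universe (the alternative order, align-then-filter, is available by
  composing the functions directly).
* **Copy-number binarization.** For each gene, min and max copies are
  divided by the line's ploidy and log2-transformed; the ratio larger
  in absolute value is kept, with magnitude ties going to the
  max-derived ratio. A gene is called altered when |log2 ratio| exceeds
  a tolerance of 1e-9 — effectively, integer copies equal to the ploidy
  are the only neutral state. Zero copies are floored at 0.25 before
  the ratio, since log2(0) is undefined; the floor makes homozygous
  deletions strongly negative (log2(0.125) = −3 at ploidy 2) without a
  special case.
* **Mutation matrix.** A cell line × gene entry is 1 iff the line
  carries ≥ 1 non-silent variant of the gene (missense, nonsense,
  frameshift). Unknown consequence classes either raise (strict mode)
  or are kept as protein-affecting with a warning.
* **Alignment.** Two panels are restricted per layer to their shared
  genes, in the training panel's order; an empty intersection is an
  error.

## AE-NN

Per drug and per fold of a stratified 5-fold split (stratification
keeps the minority sensitive class present in every fold; unscreened
NA lines are dropped first):

1. each omics layer is standardized (train-split statistics) and
   compressed by a symmetric autoencoder — ReLU hidden layers, linear
   bottleneck and output, trained on reconstruction MSE;
2. the concatenated bottleneck codes feed a ReLU + sigmoid classifier
   trained with mini-batch Adam on cross-entropy for
   `epochs_per_fold = 3` epochs; the fold's held-out probabilities are
   the average of the three per-epoch predictions (a best-epoch mode,
   selecting the epoch with the highest held-out AUC, is provided for
   comparison);
3. the fold threshold maximizes F1 on the held-out probabilities over
   the 101-point grid {0, 0.01, …, 1} under "sensitive iff p > t",
   with F1 = 2TP/(2TP+FP+FN) and ties resolved to the smallest grid
   value.

The final decision threshold is the mean of the five fold thresholds;
reported CV AUC/F1 are fold averages. External samples are scored by
the mean of the five fold models' probabilities; the call is sensitive
strictly above the final threshold — equality maps to resistant, since
sensitivity is defined by strict exceedance. Autoencoders are refit
within each fold on that fold's training split only, so no information
from held-out lines leaks into the codes. A drug whose labels contain
fewer than two lines in either class is skipped with a logged status
rather than fitted.

Defaults (config-exposed): bottleneck 64 per omics with one hidden
layer of 256, classifier hidden layer 64, Adam at 1e-3, batch 64. The
pipeline and the test conditions use compact dimensions suited to
panels of a few hundred lines and 50–200 genes: bottleneck 16, hidden
64/32, learning rate 1e-2, batch 16 — with only ~25 gradient steps per
classifier epoch at that scale, the larger step size is what makes the
three-epoch budget sufficient.

## Super.FELT-style model

Per fold, each omics layer is embedded by a supervised encoder trained
with the margin triplet loss max(0, ‖z_a−z_p‖² − ‖z_a−z_n‖² + m),
m = 1 by default; triplets are sampled within mini-batches (every
sample with an available same-class partner anchors one triplet). A
sigmoid classifier head is trained on the concatenated embeddings.
Each fold keeps its own threshold: among the distinct operating points
of the fold-test ROC curve, the one maximizing F1, with ties resolved
to the largest cutoff (most conservative toward resistant). Fold
members call sensitive when p ≥ t — their thresholds are attained
score values, so the ROC convention of inclusive cuts applies — and an
external sample's final call is the majority of the five member calls;
with an even fold count an exact tie resolves to resistant. The
mutation layer enters as the binary matrix from preprocessing.

## Consensus selection

For one external line: drugs called resistant by the AE-NN model and —
in `both` or `resistant_only` consistency mode — also by the second
model are ranked by AE-NN CV AUC (descending; ties alphabetical by
drug id for determinism) and the top k kept; analogously for
sensitive. When annotations are supplied, up to m further drugs with
the matching AE-NN call are appended from the assay-available set,
FDA-approved first, then by AUC. Group summaries report mean and
sample SD (ddof = 1, 0 for singletons) of AUC and F1, rounded half-up
to two decimals in reports while unrounded values are retained. The
consistency requirement is explicit for resistant candidates and
configurable for sensitive ones because the two directions are not
symmetric in practice: a resistant shortlist is used to rule drugs
out, so false consensus is cheap to demand, while sensitive shortlists
may be extended by annotation.

## Evaluation primitives

ROC AUC is the Mann–Whitney pairwise-concordance probability computed
from average ranks, giving 0.5 credit to probability ties; single-class
input yields NaN. Spearman correlation uses average ranks
(`scipy.stats.spearmanr`); F1 and accuracy/sensitivity/specificity come
from explicit confusion counts, with undefined ratios reported as NaN.
Concordance reports join predicted and published calls on drug id,
exclude NA published labels, and report overlap, consistent count, and
the three confusion metrics with sensitive as the positive class.

## Synthetic data generator

The generator emulates the training regime the protocol expects:

* **Expression** is drawn on a log-like continuous scale with
  gene-specific means U(3, 10) and SDs U(0.4, 1.2), organised in 10
  co-expression modules with within-module z-score correlation 0.6.
  Modularity matters: an unsupervised bottleneck can only preserve
  structured variance, and real transcriptomes are strongly modular.
* **Copy number** is integer copies around the line's ploidy
  (2, 3 or 4 with probabilities 0.8/0.15/0.05); events (default rate
  0.08) are gains of 1–4 or losses of 1–2 copies, and 10% of events put
  a breakpoint in the gene so min and max copies differ. Gains and
  losses feed back into expression at 0.5 SD per log2 copy-ratio unit
  (gene dosage), correlating the layers.
* **Mutations** are per-(line, gene) variant records at rate 0.02 with
  consequences silent/missense/nonsense/frameshift at
  0.30/0.45/0.15/0.10, so the silent filter is exercised.
* **Response labels**: each drug gets a marker set of 10 genes drawn
  from the dispersed genes of one randomly chosen module, with
  one-signed weights of magnitude `effect_size`·U(0.5, 1.5) — a
  pathway-like signal whose module alignment makes it recoverable by
  bottleneck models, and whose dispersion lets a variance filter retain
  it. Labels are Bernoulli(σ(w·z + c)) with the intercept c solved so
  the expected sensitive fraction equals the configured prevalence
  (default 0.15; sensitive is deliberately the minority class).
* **External lines** are drawn from the same generative model, then
  distorted per gene by x → a·x + b with a ~ 1 + N(0, s) and
  b ~ N(0, s) (default s = 0.1), emulating a platform gap; copy numbers
  are re-drawn independently. The planted label of every external line
  is returned.

What the generator does **not** emulate: count-level noise (inputs are
assumed already normalized), linkage between copy-number segments of
neighbouring genes, mutation hotspots, drug–drug correlation in
responses, and batch structure within the training panel. Passing
recovery tests therefore shows that the models extract a compressible,
module-aligned signal under class imbalance and platform shift — not
that they would meet any particular accuracy on real screens.

Because labels are Bernoulli draws from the true response probability,
some planted-sensitive lines have intermediate probability and are
irreducibly ambiguous; external-call recall is accordingly more
variable across seeds than call accuracy, which is dominated by the
resistant majority.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.Generator`; estimator seeds
fan out to per-fold, per-layer child seeds via `SeedSequence`, and the
pipeline derives per-stage seeds by hashing the stage name with the
global seed, so a fixed configuration reproduces every output file
byte for byte. Standardization guards zero-variance features by
substituting unit SD. The F1-grid step must divide 1 evenly; the grid
is generated as integer multiples to avoid floating-point drift.
Degenerate threshold inputs (no positive labels) return 0 with a
warning rather than raising, mirroring the F1-undefined-as-0
convention.

## Problem sizes

The default test and demonstration conditions — panels of 80–600 lines,
50–200 genes, bottlenecks of 4–16 — were chosen as the smallest sizes
at which the protocol's behaviour (signal recovery, threshold
calibration, consensus) is cleanly observable; all are configuration,
not code, and scale up directly.
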