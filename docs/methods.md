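# Methods

## The prediction task

Small interfering RNAs (siRNAs) direct sequence-specific knockdown of a
target mRNA. Measured silencing efficacy — the fraction of target
expression removed, normalized to [0, 1] — varies widely between siRNAs
against the same gene, and depends both on the sequence context around the
target site and on the thermodynamics of the siRNA duplex. `sirnadeep`
treats efficacy prediction as a regression problem over two input
modalities and fits a small convolutional network to map them onto the
unit interval.

## Input representations

**Sequence context.** Each record carries a 21-nt binding region on the
mRNA plus up to `n` flanking nucleotides on each side (default n = 20, so
a 61-position window). The window is one-hot encoded row-wise with fixed
column order (A, U/T, G, C): A=(1,0,0,0), U/T=(0,1,0,0), G=(0,0,1,0),
C=(0,0,0,1). When the available context is shorter than the requested
flank, the missing positions are encoded as uniform (0.05, 0.05, 0.05,
0.05) rows — a weak, non-committal signal rather than a hard zero, so
convolution outputs near the edges stay small but defined.

**Thermodynamics.** Twenty descriptors are computed from the guide
(antisense) strand under a perfect-match nearest-neighbor model:

1. total hybridization ΔG of the duplex (initiation term + sum of
   dinucleotide-step ΔGs + terminal A/U penalties), 1 value;
2. differential stability of the two duplex ends (ΔG of the terminal
   step(s) at the guide's 5' end minus its 3' end) — the asymmetry
   implicated in guide-strand selection by RISC, 1 value;
3. the per-step ΔG profile along the antisense strand, 18 values.

Eighteen steps imply a 19-nt duplexed core; this matches canonical 21-mers
with 2-nt 3' overhangs, so the trailing 2 nt of the guide are excluded
from the thermodynamic calculation. Step parameters are the published
RNA/RNA ΔG°37 nearest-neighbor values of Xia et al. (1998), bundled as a
plain-text table (`src/sirnadeep/data/xia1998_rna_nn_dg37.tsv`); any
user-supplied table with the same 16-step schema is accepted. The width
of the "end" used in the differential is configurable (`end_window`,
default 1 step per end).

## Architecture

For an input window of L = 21 + 2n rows:

- **Convolution.** A bank of m×4 kernels (2 ≤ m ≤ 20) slides over the
  window; each kernel k carries a learnable scalar scale δ_k (initialized
  to 1), so its feature map is x = δ_k · (S ⋆ M_k), length L − m + 1.
  With n = 0 this is the classic 22 − m. Convolution deliberately runs
  over the full flanked window — exploiting flank context is the point of
  the encoding — and global pooling keeps downstream dimensions
  independent of L.
- **Activation.** ReLU by default (sigmoid available for comparison
  scans).
- **Pooling.** Global max and global average over each feature map: one
  (y_max, y_avg) pair per kernel, 2d values for d kernels.
- **Merge.** The 2d pooled values are concatenated with the 20
  thermodynamic descriptors (merged dimension 2d + 20; 50 for the
  reference model) and batch-normalized with learnable per-feature
  shift/scale. Training uses the batch's own statistics; at inference the
  statistics are frozen from the full training set at the end of training.
- **Head.** One hidden layer of 25 sigmoid units, then a single output
  unit: efficacy = σ(Σ w_i h_i). The output has no bias term; a network
  with zero output weights therefore predicts exactly 0.5.

The **reference configuration** is one kernel per height 6–20 (15
kernels, 30 pooled values), ReLU convolutions, sigmoid hidden layer,
n = 20, learning rate 0.1.

## Training

Full-batch gradient descent (minibatch size configurable) on mean-squared
error with a fixed learning rate; no momentum or adaptive step. The loss
is not stated more precisely by the task than "training error", so MSE is
used: the regression target lives in [0, 1] and the stop rule reads
naturally as a scalar error. Training stops when the iteration count
exceeds `max_iterations` (default 1000) or the training MSE drops below
`error_tolerance` (default 0.001). Weights are initialized
uniform(−r, r) with r = 1/√fan-in from a seeded generator; runs are
bit-reproducible given (data, config, seed). All gradients are analytic
(hand-derived backprop through pooling, batch norm and the δ scales) and
are checked against central finite differences at relative error ≤ 1e-4
in the test suite.

δ_k is described in the source formulation as a learning-rate-like factor
inside the convolution sum; mathematically it is a per-kernel
multiplicative scale, and it is implemented as such — a learnable scalar
absorbed into the kernel at inference.

## Evaluation

- **PCC** between observed and predicted efficacies, with sample (ddof=1)
  standard deviations.
- **AUC** with ties counted one half, plus the ROC polyline of
  (1 − specificity, sensitivity) points. Because efficacy is continuous,
  AUC requires a binarization rule: a record is "positive" when its
  observed efficacy ≥ 0.7. The cutoff is configurable
  (`--auc-threshold`) and reported alongside every AUC.
- **k-fold cross-validation** (default k = 10) with seeded, disjoint,
  exhaustive folds. Per-fold PCC/AUC are reported together with their
  means and with pooled-prediction metrics over all held-out predictions;
  the mean is used for model selection. Size-1 folds leave per-fold PCC
  undefined (NaN); the pooled value then serves as the aggregate.

## Synthetic data

The generator emulates the *shape* of curated silencing datasets without
reproducing any real measurement: contexts are i.i.d. draws from a
configurable base composition, the guide is the reverse complement of the
binding region, and efficacy follows

    latent = motif_effect · 1[motif planted] + thermo_effect · ΔΔG_ends + ε
    efficacy = σ(latent),  ε ~ N(0, noise_sd²)

with a short motif planted in the flanks of a random half of the records
(`motif_prob = 0.5`; the carrier fraction is a free choice — half/half
maximizes the information the planted signal carries). `motif_position`
can pin the motif a fixed distance upstream of the binding region, which
the flank-length recovery experiment uses to make the motif invisible to
short windows. The sigmoid link puts synthetic efficacies in the model's
own output range, making parameter recovery well-posed. Ground truth
(motif presence and position, end differential, latent score) is emitted
as a sidecar table so tests read it rather than re-deriving it.

Defaults (2000 records, motif effect 3.0, thermo effect 1.0, noise SD
0.1, uniform base composition) are the study conditions used by the
recovery tests and the acceptance script.

**What passing does and does not show.** Recovery on this generator
demonstrates that the pipeline can learn a flank-borne motif through the
convolutional path and a thermodynamic signal through the merged
descriptors, end to end. It does not show performance on real silencing
data: real efficacy distributions are not sigmoid-linked to two additive
signals, real motifs are soft position-weight patterns, and measurement
noise is not homoscedastic Gaussian.

## Experiment harness

Four scans re-run cross-validation over one-dimensional grids: flank
length n ∈ [10, 30], kernel height m ∈ [2, 20] (each single-height
network uses 22 − m kernels of height m, so 19 networks over the full
grid), the four {ReLU, sigmoid}² activation pairings, and learning rates
{0.5, 0.1, 0.01, 0.001}. Every row is reproducible from its (config,
seed) cell. Qualitative claims ("the optimum flank is the one that
reveals the planted motif") are asserted as sign tests over ≥ 5 seeds,
never per-seed.

On the synthetic objective, batch normalization plus full-batch descent
is robust to large learning rates, so "0.5 trains worst" does not
reproduce here; what does hold, on every seed tried, is the
slow-convergence side (0.001 under-converges at a fixed iteration
budget), and that is what the test suite asserts.

## Problem sizes and numerical choices

Tests and the acceptance script run the full-scale recovery at 2000
records with the reference configuration (1000 iterations) and run the
scan experiments at 400 records / 400 iterations / 3-fold CV with reduced
kernel banks — sizes chosen so a complete run stays comfortable on a
single CPU while the planted signals remain clearly recoverable.
Batch-norm ε is 1e-5; ties in max pooling route the gradient to the first
argmax; all arithmetic is float64.

## Known limitations

- No secondary-structure or target-accessibility terms; thermodynamics
  assumes a perfect-match duplex over the 19-nt core.
- The strand convention (guide = 21-nt antisense, 5'→3') and the end
  width of the differential are documented conventions, not fitted
  choices; reverse-complement utilities are provided for the opposite
  convention.
- Plain gradient descent can under-converge at very small learning rates
  within the default iteration budget; increase `max_iterations` or the
  learning rate for small datasets.
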