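# Methods

## The prediction problem

Whole-genome bisulfite sequencing (WGBS) reports, for each covered CpG
site, the fraction of overlapping reads carrying a methylated cytosine — a
methylation *level* y ∈ [0, 1].  With little input material (single cells,
oocytes, early embryos) the data coverage rate — the fraction of all genome
CpG sites with a profiled state — can fall below 1%, which cripples any
downstream analysis done at the level of genomic features.  `cpgfill`
trains a multi-task neural network to predict the methylated-class
probability ŷ for every uncovered CpG site, retains only confident
predictions, and quantifies the resulting gain in feature-level coverage.

## Cleaning model

Raw strand-resolved calls pass through a fixed pipeline: replicates are
merged by summing read counts; calls with fewer than 4 overlapping reads
are discarded (per strand by default; a pooled-depth variant is exposed as
a configuration flag); and a CpG site is kept only when both strand
cytosines survive the filter *and* agree after binarisation at 0.5.  CpG
methylation is maintained symmetrically on both strands, so discordant
(hemi-methylated) sites are treated as profiling artifacts.  The kept level
pools both strands' counts — counts, not per-strand levels, are the
sufficient statistic.  A site level exactly at the binarisation threshold
counts as unmethylated (strict `>`), a convention applied uniformly across
the package.

## Network

Inputs per site: a one-hot DNA window centred on the CpG's forward-strand
C (1001 bp by default; `N` and off-chromosome positions become all-zero
rows), and one neighbor vector per profile — the levels of the nearest 25
covered CpG sites on each side concatenated with their base-pair distances
divided by 25 kb and clipped at 1 (a vector of length 100).  Missing
neighbor slots are padded with level 0.5 and distance 1.0, the least
informative values, and flagged in a mask that the loss and metrics can
consult (the recurrence itself consumes pad values as-is).

Three shared feature extractors feed task-specific heads:

* **Sequence**: two convolution blocks (convolution → ReLU → max pooling →
  batch normalisation) followed by a fully connected layer with ReLU.
* **Methylation**: a bidirectional GRU whose recurrence axis is the
  *profile* axis — each step consumes one profile's 100-vector — with the
  two final hidden states concatenated.  Profiles enter in alphabetical
  sample-id order; the order is recorded in checkpoint metadata.
* **Joint**: two fully connected layers (ReLU, batch normalisation) over
  the concatenated Sequence and Methylation features.

Each task head is a hidden fully connected layer with ReLU and a two-logit
softmax; the reported ŷ is the methylated-class probability (computed as
`sigmoid(z1 − z0)`, the exact two-class softmax).  A model predicts from
sequence only (`seq`), neighbors only (`met`), or both (`full`).

The network runs on a compact reverse-mode automatic-differentiation
engine over numpy arrays (`cpgfill.nn`), written for this package: float64
throughout, fully deterministic for a fixed seed, gradients verified
against central differences in the test suite.  Default layer sizes
(conv 128×11/pool 4, conv 256×3/pool 2, fc 256, GRU 256, joint 512→256,
head 128) follow the DeepCpG-family scale; the `desk` preset
(window 121 bp, conv 32×9/pool 4 + 32×3/pool 2, fc 64, GRU 32, joint
64→32, head 32) is sized for CPU-scale experiments and is what the tests
and the reproduction script use.

## Objectives

For observed level y and prediction ŷ (clipped to [ε, 1−ε], ε = 10⁻⁶):

* logistic loss on binarised labels: −y·log ŷ − (1−y)·log(1−ŷ), y ∈ {0,1};
* KL divergence on raw levels: y·log(y/ŷ) + (1−y)·log((1−y)/(1−ŷ)) with
  0·log 0 = 0 — identical to the logistic loss when y is binary, but it
  preserves the information carried by intermediate levels;
* mean squared error with or without a terminal sigmoid, as baselines.

The multi-task objective is Σ_j α_j Σ_i β_ij · loss_ij over observed
entries.  All α_j default to 1.  β_ij follows the binarised class
distribution of profile j: inverse class frequency normalised so the
weights of a profile sum to its observed count (β = N_j / (2·n_class),
computed once on the training split); a uniform scheme is available.  By
default the batch reduction is the weighted *mean* over observed entries,
which makes learning rates batch-size independent; the literal sum is a
configuration switch.

## Training protocol

Chromosome-based splits: chr1, 4, 7, … train; chr3, 6, 9, … validation;
chr2, 5, 8, … test.  Adam with L2 weight decay (10⁻⁴) applied in the
optimiser and an explicit L1 penalty (10⁻⁴) added to the objective;
mini-batches of 128; learning rate selected by grid search (default grid
10⁻¹ … 10⁻⁶, selection by validation minor-class F1, ties to the smaller
rate); early stopping monitors the validation minor-class F1 with patience
5 and restores the best-validation parameters.  The patience value, epoch
budget and regulariser coefficients are package choices exposed in
configuration.  All randomness (initialisation, shuffling) flows from one
seed; reruns are bit-identical.

### Transfer settings

Source-side, on dense profiles: `Seq` and `Met` (single-path models from
scratch), `Full1` (full model from scratch), `Full2` (Joint + heads trained
with the pretrained Seq/Met subnetworks frozen), `Full3` (same but
fine-tuned).  Target-side, every combination of transferring/freezing the
Sequence, Methylation and Joint subnetworks: `SeqN/T1/T2`, `MetN/T1/T2`,
`FullN`, `FullTS1/2`, `FullTM1/2`, `FullTB1/2`, `FullTA1/2` — "1" variants
keep transferred subnetworks fixed, "2" variants fine-tune them.
Classification heads are never transferred.  Frozen groups are excluded
from the optimiser *and* run in inference mode, so their batch-norm
statistics cannot drift; the engine asserts bit-identity of frozen groups
after training.

## Evaluation

With heavily imbalanced binarised labels (oocyte/embryo methylation rates
of a few percent), accuracy and AUC reward a constant majority predictor.
The primary metric is therefore the F1 score with the *minor* binarised
class of the evaluation subset as the positive class (ties resolve to the
methylated class); precision, recall, accuracy, AUC-ROC and AUPRC are
reported alongside.  The τ-retention analysis keeps predictions with
ŷ > τ or ŷ < 1−τ (strict; boundary values drop) and recomputes the F1 on
the retained subset over a τ grid (default 0.50–0.95 in steps of 0.05).
τ selection uses validation chromosomes by default; imputation uses
τ = 0.8.

## Imputation and feature summarisation

Imputation is a single pass: every genome CpG absent from the target
profile is scored, predictions outside (1−τ, τ) are retained with the
continuous ŷ stored as the level (plus a binarised state), and observed
records pass through untouched.  Neighbor features always come from
originally observed sites, never from imputed values, so there is no
feedback loop.  Feature-level summaries use 300-bp non-overlapping bins
(trailing partial bins dropped), 1001-bp promoter windows centred on TSSs
(clipped at chromosome ends and flagged), and CGI intervals from BED.  A
bin "has data" with ≥ 3 known-state CpGs; promoters and CGIs require ≥ 10.
After imputation, "known state" means observed ∪ retained-imputed.  The
profile correlation matrix is the Pearson correlation of per-feature mean
levels over features complete in every profile; hierarchical clustering
and PCA of that matrix are left to standard tooling on the exported TSV.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, at
desk scale.  A random genome (3 × 70 kb, GC 0.42, ≈ 3,000 CpGs per
chromosome — one train, one validation, one test chromosome under the
default split plan) carries a planted 8-mer motif (`TAGTTGGA`, density
1/400 bp).  True levels are `sigmoid(baseline + 4·near_motif + field)`
where `near_motif` indicates a motif within 50 bp and `field` is an
Ornstein–Uhlenbeck process over CpG positions (sd 1.5, correlation length
2,000 bp).  Source profiles (baseline 0, methylation rate ≈ 0.75, like
somatic tissues) share 70% of their field; target profiles (baseline −2.5,
rate ≈ 0.2, like hypomethylated oocytes/embryos) share only the sequence
determinant and carry independent fields — precisely the structure
subnetwork transfer can exploit and from-scratch training on a sparse
target cannot recover.  A configurable fraction of sites (default 0.3) is
squeezed into (0.2, 0.8) by the order-preserving map 0.2 + 0.6·level,
mimicking widespread intermediate methylation.  Observation: each site is
covered with the profile's coverage probability; each strand of a covered
site draws depth 1 + Poisson(mean − 1) and a binomial methylated count;
hemi-methylation artifacts are planted by sampling one strand from the
complementary level with a configurable rate.

Scaled-down conditions were fixed after a design phase that compared
candidate settings against analytic/oracle ceilings (nearest-neighbor
interpolation of observed levels; the planted-motif indicator): source
coverage 30%, sparse targets 1–2%, four target tasks.  The KL-vs-logistic
comparison uses its own regime (target baseline 0, intermediate fraction
0.35, per-strand depth 6) because the KL objective's advantage acts
through binarised-label noise at intermediate sites, which hypomethylated
targets with labels far from 0.5 cannot exhibit.  Because simulated truth
is available at every site, desk-scale models are scored against the true
methylome on held-out (test) chromosomes, which keeps sparse-target
evaluation well-posed.

What passing these benchmarks shows — and what it does not: the synthetic
data are sequence- and neighborhood-determined by construction, with iid
site coverage and a single planted motif; real methylomes have richer
sequence determinants, regional coverage biases, bisulfite-conversion
error and cell-population heterogeneity.  Directional results (transfer
helps sparse targets; KL beats logistic under intermediate methylation)
mirror the mechanisms, not the magnitudes, of what larger-scale training
on real bovine methylomes reports.

## Numerical choices and degenerate inputs

Predictions are clipped at ε = 10⁻⁶ inside logarithms; gradients are zero
in the clipped region.  Batch normalisation uses batch statistics during
training and running statistics (momentum 0.1) for inference, making
inference deterministic and batch-size independent.  Ties: binarisation
and τ-retention use strict inequalities; LR-grid ties go to the smaller
rate; the minor class defaults to "methylated" on exact label-count ties.
Empty profiles encode as fully padded neighbor vectors; an empty training
stream or an all-masked batch is an error/warning rather than silent
progress; a NaN loss aborts with diagnostics.

## Known limitations

Non-CpG (CHG/CHH) contexts, bisulfite conversion-efficiency correction and
read-level processing are out of scope; inputs are processed call files.
The GRU consumes padded neighbor slots (no masked recurrence).  Training
is single-threaded CPU numpy: the full-scale configuration (1001-bp
windows, 22 source tasks) is far slower than a GPU framework, and the desk
preset is the practical envelope here.  Imputation is single-pass by
design; iterative refinement and uncertainty intervals on imputed levels
are not provided.
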