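# Methods

## Data model

The unit of prediction is a per-read candidate site: a 13-base motif with
the candidate cytosine at index 6 (0-based), plus three per-base tracks —
normalized current means (dimensionless), current standard deviations
(non-negative) and signal lengths (integer counts ≥ 1). Coordinates are
0-based and strand-aware; the motif is reported on the read strand, so the
central base is always `C` on that strand. Feature files are plain TSV
(gzip-transparent) with comma-joined tracks; this mirrors the per-site TSV
layout common to nanopore feature-extraction pipelines. Basecalling,
resquiggling, alignment, and extraction of the tracks from raw signal are
out of scope — the package consumes extracted features.

## Ground truth

Bisulfite sequencing provides per-site methylated/unmethylated read counts
(cytosine-report-like TSV). A site is called **positive** when coverage is
strictly above 5 and the methylation rate strictly above 90%, **negative**
when the rate is exactly 0%, and **excluded** otherwise. Two conventions
were open and are fixed here:

* "above 5" and "over 90%" are read literally as strict inequalities.
* The coverage filter is applied to negative sites as well, although the
  published rule states it only for positives: a 0%-rate call supported by
  one or two reads is not a credible negative, and credible negatives are
  the stated purpose of the 0% rule. `coverage_filter_negatives=False`
  restores the literal reading.

Sites with zero coverage have an undefined rate and are excluded, never an
error. Calls are attached to read-level instances by site; instances at
excluded or unmapped sites are dropped. Prediction is per read; site-level
aggregation across reads is left to downstream consumers (the predictions
TSV carries coordinates for exactly this purpose).

## Tokenization

A pore accommodates roughly five bases, so the sequence branch consumes
overlapping 5-mers: 9 tokens per 13-base motif (stride 1). The vocabulary
is the 1024 ACGT 5-mers in lexicographic order plus an UNK id (any window
containing N) and a reserved PAD id. No CLS/SEP tokens are used; the
encoder operates on the 9 positions directly. Ids are a pure function of
the k-mer, and checkpoints store a vocabulary hash so a model cannot be
silently applied with a different token map.

## Architecture

Defaults (all configurable through `ModelConfig`): token embedding 64,
2 Transformer layers with 4 heads (feed-forward width 2× the embedding),
signal encoder 39→64→64 with ReLU, Bi-GRU width 64, dropout 0.2 on the GRU
input during training. Positional information uses learned embeddings over
the 9 token positions. The published architecture fixes none of these
sizes; the defaults are chosen to train in minutes on one CPU while leaving
the architecture faithful (Transformer → concatenation → Bi-GRU).

The fusion geometry was genuinely open: the branch outputs "are
concatenated" before the Bi-GRU, but the shapes are unstated. Here the
signal branch is pooled to a single vector and concatenated onto **each**
of the 9 token-context steps, and the Bi-GRU runs over those 9 fused steps;
this preserves the sequential structure the bidirectional recurrence is
meant to exploit. The fused representation is the concatenation of the
final forward and backward hidden states (128-d by default). The
classifier is two linear layers with ReLU emitting two logits and a
softmax; the Bernoulli cross-entropy of the published formulation is
equivalent to this two-logit form.

GRU gates follow the common reset/update convention
(`h' = (1−z)·n + z·h`, with the reset gate applied to the hidden
contribution of the candidate state).

Ablation variants are config flags, not separate models: `mask_means`,
`mask_stds`, `mask_lens` zero one signal track before encoding;
`mask_sequence` replaces the sequence branch output with zeros; `no_gru`
replaces the Bi-GRU with a fully connected layer over the flattened
concatenation (same output width); `no_contrast` keeps the architecture
but trains the contrastive phase on cross-entropy alone.

## Losses

The contrastive loss is implemented exactly as published:

    L_con = 1/(2N) Σ (1−y)·D² + y·max(margin − D, 0)²,  margin = 2,

with `D` the cosine similarity and `y = 1` for same-class pairs. Because
cosine similarity is bounded by 1 and the margin is 2, the same-class term
never saturates — same-class pairs are always pulled toward alignment,
while different-class pairs are pushed toward orthogonality (D = 0, not
−1). Both properties are consequences of the printed form and are kept
deliberately; the loss is not reinterpreted as `1 − cos` distance.

Pairs are built by shuffling the batch deterministically and splitting it
into two equal halves (the odd leftover is dropped); pair *i* couples
element *i* of each half. The cross-entropy clamps probabilities at 1e-7.
The combined objective is `α·L_con + (1−α)·L_CE` with α = 0.8.

## Training

Adam (β = 0.9/0.999) with an exponential learning-rate decay of 0.95 per
epoch (the published schedule names Adam and "a learning rate decay
strategy" without its form). The alternating freezing strategy is
interpreted as: the contrastive module has no parameters of its own, so
its phase freezes the classifier and updates the encoder with the combined
loss (the cross-entropy gradient flows through the frozen classifier into
the encoder), and the classification phase freezes the encoder and updates
the classifier with the cross-entropy. Alternation is per-epoch by default
(contrastive epoch, then classifier epoch); `per_batch` interleaves both
phases within each batch. Freezing is enforced by the optimizer (frozen
parameters and their moment estimates are never touched), and each log
entry records the audited total change of the frozen module — exactly 0.

Model selection keeps the checkpoint with the best validation AUPRC, the
metric most informative under class imbalance; the published account
reports best validation performance around epoch 30 of 100 without naming
the criterion. Early stopping is available (`early_stop_patience`) but off
by default. The confusion-matrix threshold defaults to 0.5.

Everything is float64 NumPy on a single thread: two runs with the same
seed are bit-identical, including dropout masks and batch order.

## Metrics

ACC, Precision, Recall and F1 are computed from the confusion counts at
the threshold. AUROC is the Mann–Whitney rank statistic with midrank tie
handling; AUPRC is average precision (step integration, not trapezoidal —
the two differ, and step integration is the convention that cannot
overestimate). Both are delegated to scikit-learn, which implements
exactly these definitions, and are cross-checked in the test suite against
independent O(n²) brute-force oracles. Undefined ratios (no predicted
positives, no true positives, single-class labels) are reported as 0 with
an explicit warning flag rather than raising.

## Synthetic data

The simulator generates what the detector assumes about real data:

* **Motifs** follow the CpG/CHG/CHH grammar around the central cytosine
  (H ∈ {A, C, T}); `mixed` draws contexts uniformly. Motifs are otherwise
  uniform random — they carry no class signal, so the sequence branch has
  nothing real to learn from simulated data.
* **Means** are Gaussian around a fixed per-base level table (A: 0.5,
  C: −0.3, G: 0.3, T: −0.5 — arbitrary documented values standing in for a
  pore model) with SD `noise_sigma`; methylated instances are shifted by
  `delta` on the ±`effect_width` positions around the center, emulating the
  ~5-base pore footprint.
* **Stds** are folded-normal (|N(0, 0.5)| + 0.1); **lens** are
  1 + Poisson(`len_rate`). Each track receives the class shift only if
  named in `effect_tracks` (default: means only), which gives ablation
  experiments a ground truth — mask the only informative track and
  performance must drop.
* **Imbalance**: `n_pos = round(n·p/(1+p))` realizes any positive:negative
  ratio `p`, covering the ~0.02–1.85 regimes of real methylomes.
* The bisulfite simulator draws shifted-Poisson coverage and binomial
  methylated counts at truth-dependent rates (0.97 / 0.0 / 0.5), so the
  labeling rules see realistic boundary cases including sub-threshold
  coverage.

What the simulator does **not** model: sequence-dependent methylation
propensity, basecalling errors, alignment artifacts, inter-read covariance
at a site, and realistic pore current tables. Passing tests on simulated
data therefore demonstrate that the implementation recovers planted signal
under the stated noise model — not field performance on real reads.

## Protocol sizes

The reference protocols used by the test suite and the acceptance script
are sized for a single CPU: signal-recovery runs use 4000 instances at
proportion 0.25 (8:1:1 split) with the default model for 8 epochs at
lr 3e-3; the ablation comparison uses 2000 instances for 6 epochs. Under
the 3-sigma effect these reach held-out AUROC ≥ 0.95 (in practice ≈ 1.0)
and the no-effect null stays within 0.45–0.55; these sizes are the
package's reference conditions, and larger runs only sharpen the same
conclusions.

## Known limitations

* No GPU path; the NumPy core is single-threaded float64. Fine for the
  reference protocols, not for genome-scale training.
* Per-read prediction only; site-level aggregation is deliberately left to
  the caller.
* The published headline numbers on real *A. thaliana* / *O. sativa* /
  NA12878 datasets require the original multi-million-site data and
  GPU-scale training and are not reproduced here; the package reproduces
  the method, its exactly recomputable statistics, and its qualitative
  behaviour under controlled synthetic conditions.
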