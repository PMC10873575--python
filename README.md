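# nanocon

Detection of 5-methylcytosine (5mC) sites from nanopore sequencing reads
with a contrastive-learning hybrid network.

## The problem

Nanopore sequencing reads DNA by measuring the ionic current as a molecule
transits a protein pore; cytosine methylation perturbs that current, so 5mC
can in principle be called directly from the signal, without bisulfite
conversion. Two things make this hard in practice: the signal is noisy, and
real methylomes are heavily imbalanced — from roughly 2 methylated sites per
100 unmethylated ones in *A. thaliana* up to a positive-majority regime in
human CpG-rich data (imbalance ratios ~0.02 to ~1.85).

This package implements **NanoCon**, a hybrid network for per-read 5mC
calling designed around that imbalance, together with the data plumbing
(feature files, bisulfite ground-truth labeling, dataset splitting), the
training schedule, an imbalance-aware metric suite, and a synthetic-signal
simulator so that every component is testable without any external download.

## The model

Each candidate site is a 13-base motif centered on a cytosine plus three
per-base signal tracks: current means, current standard deviations, and
signal lengths (13 values each).

* **Sequence branch** — the motif is tokenized into its 9 overlapping
  5-mers (a pore reads about five bases at once) and encoded by a
  Transformer: multi-head self-attention
  `softmax(QKᵀ/√d_k)·V` with `Q = XW_Q`, `K = XW_K`, `V = XW_V`,
  plus feed-forward blocks, residual connections and layer normalisation.
* **Signal branch** — the 39 signal statistics go through a fully connected
  network.
* **Fusion** — the signal vector is concatenated onto each of the 9 token
  contexts and a bidirectional GRU integrates the steps; its final hidden
  states form the fused representation `x`.
* **Objectives** — a margin contrastive loss over random instance pairs,

  `L_con = 1/(2N) Σ (1−y)·D(x_i,x_j)² + y·max(margin − D(x_i,x_j), 0)²`

  with `D` the cosine similarity, margin 2, and `y = 1` for same-class
  pairs, combined with the binary cross-entropy as
  `L = α·L_con + (1−α)·L_CE`, α = 0.8. Training alternates phases: the
  classifier is frozen while the encoder learns the combined loss, and vice
  versa.

The whole network, including reverse-mode differentiation and the Adam
optimizer, is implemented in NumPy (`nanocon/_autograd.py`); runs are
bit-reproducible on CPU under a fixed seed.

## Worked example

```python
from nanocon import (ModelConfig, NanoConModel, SimConfig, TrainConfig,
                     evaluate, simulate_dataset, split_dataset, train)

instances, manifest = simulate_dataset(
    SimConfig(n_instances=4000, proportion=0.25, delta=3.0,
              noise_sigma=1.0, seed=0))
split = split_dataset(instances, seed=0)          # 3200 / 400 / 400
model = NanoConModel(ModelConfig(), seed=0)
model, log = train(model, split.train, split.validation,
                   TrainConfig(epochs=8, batch_size=64, lr=3e-3, seed=0))
report = evaluate(model, split.test)
print(f"AUROC={report.AUROC:.4f}  AUPRC={report.AUPRC:.4f}")
```

prints

```
AUROC=1.0000  AUPRC=0.9998
```

— on simulated data whose methylated instances carry a 3-sigma current-mean
shift in a ±2-base window around the cytosine, the detector separates the
classes essentially perfectly on the held-out test split. Re-running the
same protocol with `delta=0.0` (no class signal) yields AUROC ≈ 0.51:
the detector is calibrated at chance when there is nothing to detect.

The same pipeline is available from the shell:

```sh
nanocon simulate --n 4000 --proportion 0.25 --delta 3 --seed 0 --out features.tsv
nanocon train --features train.tsv --val val.tsv --epochs 8 --seed 0 --out model.npz
nanocon predict --ckpt model.npz --features test.tsv --out preds.tsv
nanocon evaluate --preds preds.tsv --out metrics.json
nanocon smoke --seed 0 --out smoke/      # end-to-end miniature run
```

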