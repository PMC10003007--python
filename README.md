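# probatac

Modelling single-cell chromatin accessibility from DNA sequence with a
probability-sparse attention encoder — and reusing the fitted model for
cell-type annotation, dropout denoising and TF-activity inference.

## The problem

scATAC-seq measures which regulatory regions ("peaks") are open in each
cell, producing an extremely sparse peak-by-cell matrix: most entries are
zero, and many of those zeros are *dropouts* — truly open regions that the
assay failed to capture.  `probatac` is for computational biologists who
want a single sequence-aware model behind four standard analyses:

1. **Accessibility prediction** — learn `P(open | sequence, cell)` from the
   peak DNA sequence itself;
2. **Cell-type annotation** — cluster the per-cell weights of the model's
   read-out layer (a cell embedding) with Louvain on a KNN graph;
3. **Denoising** — find likely dropouts with a per-peak, per-cluster
   Gamma–Normal mixture fitted by EM, and recover only those entries from
   the model's predictions;
4. **TF activity** — insert a TF's motif into dinucleotide-shuffled
   backgrounds (per-cell activity) or mutate every base of a sequence
   (per-nucleotide ISM importance).

## The model

An L-bp one-hot sequence passes through a convolutional stem into token
embeddings `u`; fixed sinusoidal position embeddings are added,
`X0 = αu + PE`.  Encoder layers apply *probability-sparse* multi-head
self-attention: each query's attention distribution is scored for deviation
from uniform,

    M(q_i, K) = LSE_m(q_i k_mᵀ/√d_h) − mean_m(q_i k_mᵀ/√d_h),

and only the top `u = ⌈c·ln L_Q⌉` queries attend,
`A = softmax(Q̄Kᵀ/√d_h)V`, the rest receiving the key-wise mean of V.
Attention is followed by a feed-forward block and convolution + max-pooling
over tokens.  A dense read-out gives per-cell probabilities
`y = σ(Z W_p + b_p)`; the columns of `W_p` are the cell embeddings and
`b_p` a per-cell depth intercept.  Training minimises cell-averaged binary
cross-entropy with Adam and patience-5 early stopping.

Counts of a peak within a cell cluster are modelled as
`λ·Gamma(x; α, β) + (1−λ)·Normal(x; μ, σ)`; the posterior weight of the
Gamma (dropout) component at an observed count decides recovery
(`d ≥ T = 0.5`), and recovered entries take `r = ŷ·μ̂`.

Everything runs on NumPy (including a small reverse-mode autodiff engine
bundled in `probatac.autodiff`); there is no GPU dependency.

## Worked example

```python
import numpy as np
import probatac as pb

# a synthetic study with known ground truth: 3 cell types x 200 cells,
# 1000 peaks of 300 bp, 3 planted motifs, depth-dependent dropout
dataset = pb.simulate_dataset(pb.default_design(seed=1))

config = pb.desk_config(n_cells=600, input_length=300, seed=1)
model = pb.AccessibilityModel.from_dataset(dataset, config)
results = model.fit()
print(results.summary())

auroc = results.evaluate_auroc("test", labels=dataset.truth)
print(f"held-out auROC vs clean truth: {auroc:.3f}")

graph = pb.build_knn_graph(results.cell_embeddings(), k=15)
clusters = pb.louvain_cluster(graph, resolution=1.0, seed=0)
types = [lab for lab in dataset.cell_labels]
print(f"Louvain ARI: {pb.clustering_metrics(clusters, np.array(types)).ari:.3f}")
```

which prints (numbers from this exact run):

```
Accessibility model (probability-sparse attention encoder)
==========================================================
cells: 600    input length: 300 bp
embedding width d: 48   heads: 4   layers: 2
tokens per stage: [150, 75, 75]
parameters: 104,272
epochs run: 18   best epoch: 13
best validation BCE: 0.4130
held-out auROC vs clean truth: 0.857
Louvain ARI: 0.965
```

The auROC is computed per cell across held-out peaks against the
generator's clean truth matrix (so dropout noise in the observed labels
does not cap it) and averaged over cells; 0.5 is chance and the Bayes limit
of this study design is roughly 0.89.  The ARI compares Louvain communities
on the learned cell embeddings with the true cell types (1 = perfect).

A command-line interface mirrors the library:

```bash
probatac simulate --seed 1 --out fx/
probatac train --dataset fx/ --seed 1 --out model.npz
probatac embed --model model.npz --out cells.tsv
probatac annotate --embeddings cells.tsv --k 15 --seed 0 --out clusters.tsv
probatac denoise --matrix fx/ --clusters clusters.tsv --model model.npz --out den/
probatac activity --model model.npz --pfm motifs.jaspar --peaks fx/peaks.fa --out act.tsv
```

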