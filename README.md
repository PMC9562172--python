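# tgem

Interpretable gene-wise self-attention models for expression-based
phenotype classification — cancer types from bulk RNA-seq, immune cell
types from scRNA-seq, or any multi-class problem posed as a samples ×
genes matrix with per-sample labels.

## Why this model

Convolutional and dense networks predict phenotypes from expression well
but explain little: genes have no meaningful order for convolutions, and
hidden units mix genes beyond recognition. Here every gene is a scalar
token with its own learned Query/Key/Value weights,

```
q_g = wq_g x_g,   k_g = wk_g x_g,   v_g = wv_g x_g,
a_gi = softmax_i(q_g k_i)   (i ≠ g),
z_g  = Σ_{i≠g} a_gi v_i,
```

so attention weights are directly indexed by gene pairs. Head outputs
are mixed by a learned vector `wH`, layer-normalized, and added to the
input (`z = x + layernorm(wH^T Z)`); after `L` such layers a dense
readout gives `p(y|x) = softmax(φ(z_L) W^T + b)`. The one-to-one
correspondence between input gene and output representation is what
makes the model interpretable:

* **Attention entropy** per Query gene, `H(a_g) = −Σ a_gi ln a_gi`,
  distinguishes broad from focused attention.
* **Integrated gradients** attribute a class logit to individual
  attention weights against a zero-attention baseline.
* **Pruning** heads/layers (zeroing `wH` entries) and **linear probes**
  on intermediate representations quantify where the signal lives.
* Thresholded attributions form a directed **Key → Query regulatory
  network** whose high-degree **hub genes** are candidate phenotype
  markers, with hypergeometric **geneset enrichment** of the informative
  genes.

The model, its backpropagation, and the attribution machinery are
implemented in NumPy; file formats, metrics helpers, enrichment and
graph export go through pandas/scipy/scikit-learn/statsmodels/networkx.

## Worked example

```python
from tgem import TGEM, SimulationSpec, simulate, make_geneset_collection

# 3 classes x 300 samples, 200 genes, 20 planted markers per class
dataset, truth = simulate(SimulationSpec(seed=0))

results = TGEM(dataset, n_layers=1, n_heads=2, seed=0).fit()
print(results.summary())
```

```
Gene-wise self-attention classifier
===================================================
Genes                                           200
Classes                                           3
Layers                                            1
Heads per layer                                   2
Readout activation                             none
Parameters                                     2205
Epochs (batch size)                         50 (16)
Best epoch                                       26
Validation accuracy                          0.9667
---------------------------------------------------
Test accuracy                                0.9444
Test MCC                                     0.9168
Test macro AUC                               0.9934
===================================================
```

The model separates the three classes on held-out samples (94% accuracy;
MCC and macro one-vs-rest AUC confirm it is not driven by class
imbalance). Interpretation then recovers the planted structure:

```python
net = results.extract_network(0, n_hubs=20)   # class-0 Key->Query network
hubs = {gene for gene, degree in net.hubs}
print(len(net.edges), len(hubs & set(truth["markers"][0])))
# 199 9
```

With the default 99.5th-percentile attribution threshold the class-0
network keeps 199 edges, and 9 of its top-20 hub genes are planted
class-0 markers (hypergeometric p ≈ 1e-5 against a 200-gene universe) —
the attention the model learned points back at the genes that define the
class. `results.entropy_profile()`, `results.prune_scan()` and
`results.probe_scan()` expose the complementary diagnostics, and
`results.save("ckpt")` writes a checkpoint that reloads bit-identically.

A command-line interface mirrors the library for shell pipelines:

```bash
tgem simulate --seed 0 --outdir data/
tgem train data/expression.tsv data/labels.tsv --seed 0 --outdir run/
tgem interpret run/checkpoint data/expression.tsv data/labels.tsv --outdir run/
tgem network run/checkpoint data/expression.tsv data/labels.tsv \
     --class class0 --gmt data/genesets.gmt --outdir run/
```

Expression is accepted as TSV/CSV (samples × genes, first column sample
ID) or an MTX triplet; genesets as GMT; networks export as SIF/GraphML
for Cytoscape. Every run writes a manifest with config, seed and input
digests.

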