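# omic-integrate

Orthogonal multimodality integration and clustering for CITE-seq data.

CITE-seq measures, for every cell, both the transcriptome (RNA UMI counts)
and a panel of surface proteins quantified by antibody-derived tags (ADTs).
The two modalities are partly redundant — much of a protein's abundance is
predictable from RNA — and naively concatenating them double-counts the
shared signal while burying the protein-specific part. This package is for
analysts who want to combine both modalities for cell clustering *and* to
quantify, protein by protein, what the ADT panel adds beyond the
transcriptome.

## The model

With `X` the scaled RNA matrix (n cells × p genes) and `Y` the scaled ADT
matrix (n × q proteins), fit the multivariate linear regression

```
Y = X B + U,          B̂ = (XᵀX)⁻¹ XᵀY,        Σ̂ = Yᵀ(I − P_X)Y / n,
```

where `P_X` projects onto the column space of `X` (a minimum-norm SVD solve
handles rank deficiency). The decomposition

```
Ŷ = X B̂   (RNA-explained ADT),        Û = Y − Ŷ   (orthogonal residual)
```

splits every protein's expression into the part RNA explains and the part it
cannot: `Û` lies in the orthogonal complement of the RNA space, so `XᵀÛ = 0`
exactly. Clustering runs on the concatenation `[X | Û]` — a shared-nearest-
neighbour graph with Louvain community detection — which keeps both
modalities with no redundancy, at O(np²) cost. Per protein,
`r²_k = 1 − ‖û_k‖²/‖y_k‖²` reports how much of its variance RNA captures;
proteins with low `r²` carry the most RNA-orthogonal information.

Three extensions round out the analysis:

* **Cluster interpretation** — per cluster j, a logistic regression on ADTs
  and/or Wilcoxon-selected marker genes, with class-balancing weights
  `w_i = 0.5 n [z_i/π + (1−z_i)/(1−π)]` (each class contributes total weight
  n²/2, so rare clusters are not swamped), evaluated by rank-based AUC over
  repeated stratified 70/30 splits.
* **Batch correction** — with one-hot batch design `Z`, ANOVA models
  `X = ZΓ_RNAᵀ + X₀` and `Y = ZΓ_ADTᵀ + X₀B + U` remove per-batch additive
  shifts by within-batch centring before the same orthogonal integration.
* **Synthetic data** — a generator that plants cluster signal *inside the
  residual channel* (orthogonal to RNA by construction), so the value of
  integration is testable end to end without any external dataset.

## Worked example

```python
import numpy as np
from omic import *
from omic.preprocess import *

# paired RNA/ADT counts with 3 planted cell populations
spec = SimulationSpec(n_cells=1000, n_genes=200, n_adts=10, n_clusters=3,
                      counts_mode=True, seed=0)
bundle = simulate(spec)

rna_norm = lognormalize_rna(bundle.rna)              # log1p library-size norm
hvg = select_hvg(rna_norm, bundle.rna, n_top=150)    # mean-variance trend HVGs
X = scale_features(rna_norm.subset_features(hvg))    # z-scored genes
Y = scale_features(clr_transform(bundle.adt))        # CLR + z-scored proteins

model = fit_projection(X, Y)                         # Y = X B + U
result = residualize(X, Y, model)
print(explained_variance_report(result).head(4))

data = integrate(X, result)                          # [X | standardised U]
graph = knn_graph(data, k=20, n_pcs=30)
clusters = louvain_cluster(graph, resolution=0.8, seed=0)
print("clusters:", clusters.labels.max() + 1)
print("ARI vs planted labels:", ari(clusters.labels, bundle.true_labels))
```

Output:

```
adt_id       r2
 adt_2 0.218099
 adt_7 0.248119
 adt_5 0.270148
 adt_6 0.291841
clusters: 3
ARI vs planted labels: 1.0
```

The `r2` column is the fraction of each protein's variance the RNA regression
explains; `adt_2` at 0.22 is the protein carrying the most RNA-orthogonal
information, hence the most to gain from integration. The clustering on
`[X | Û]` recovers the three planted populations exactly (Adjusted Rand
Index 1.0 against the simulation's true labels).

The same pipeline is available from the shell:

```bash
omic simulate --cells 1000 --genes 200 --adts 10 --clusters 3 --out sim/
omic run --rna sim/rna --adt sim/adt --n-top 150 --out results/
```

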