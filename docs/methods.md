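# Methods

## Model and assumptions

The core model is a multivariate linear regression of scaled ADT expression
on scaled RNA expression, `Y = XB + U`, with the residual rows assumed
uncorrelated with `X` and i.i.d. `N_q(0, Σ)`. Both matrices are per-feature
z-scored (mean 0, SD 1 with the n−1 denominator), so the model carries no
intercept; the fit asserts near-zero column means and warns otherwise rather
than failing, so the estimator can also be applied to centred latent matrices
in simulations. The least-squares solution is obtained from an SVD-based
rank-revealing solve (`numpy.linalg.lstsq`), which returns the minimum-norm
coefficients when scaled genes are collinear; the effective rank is recorded
and a warning emitted when it is below p. The residual covariance uses the
maximum-likelihood 1/n denominator by default; `sigma_denominator="n-rank"`
selects the unbiased variant.

The decomposition is exact by construction: `Ŷ + Û = Y` to round-off and
`XᵀÛ = 0` to the accuracy of the least-squares solve (asserted at
`1e-8·n` in tests). Per-protein explained variance is
`r² = 1 − ‖û‖²/‖y‖²` on the zero-mean columns, clipped to [0, 1] for
reporting with the raw value retained for diagnostics.

### Residual re-standardisation, not a log transform

Downstream clustering consumes `[X | Û]`. The residual columns are re-scaled
to unit SD (their means are already ~0) so that a protein's residual variance
does not depend on how well RNA predicted it. Residuals are signed, so no log
transform can apply to them; re-standardisation is the whole of the
second-stage normalisation here, as a deliberate design choice. A flag
disables it. Residual columns that are numerically zero (proteins fully
explained by RNA) are kept as zero columns rather than having round-off noise
inflated to unit variance.

## Preprocessing

* RNA: library-size normalisation to `scale_factor` (default 1e4) followed by
  `log1p`. Cells with zero total count are an error naming the cell.
* ADT: centred log-ratio with a +1 pseudocount, centring each protein across
  cells by default (the "margin 2" convention for antibody panels); a
  within-cell margin and an alternative zero-handling dialect
  (`positive_geomean`) are available. Pseudocount CLR is the default because
  its contract is simple and exactly testable; the dialect switch exists for
  pipelines that form the geometric mean over positive entries only.
* Scaling: per-feature z-score, n−1 SD everywhere, constant columns mapped to
  zeros. Clipping of extreme z-scores (common choice 10) is available but off
  by default, because clipping breaks the exact orthogonality `XᵀÛ = 0`.
* HVG selection: a loess-style local-linear fit (statsmodels `lowess`,
  default span 0.3, fitted on features with positive variance) of
  log10(variance) on log10(mean) of raw counts predicts each gene's expected
  SD; counts standardised by that prediction are clipped at √n and genes
  ranked by the variance of the clipped values. Ties break by feature order,
  so selection is deterministic. The trend is locally linear rather than
  locally quadratic; with realistically many genes the difference is
  negligible, and the smoothing window is widened automatically when very few
  features are supplied. Default `n_top` is 2000 (field convention; no value
  is canonical).

## Clustering

Cells form a shared-nearest-neighbour graph: exact Euclidean k-NN (default
k = 20), edge weights the Jaccard overlap of the two neighbourhoods (each
including the cell itself), pruned below 1/15. Neighbours are found in PCA
space (30 components) when the integrated matrix has more than 50 columns,
on raw columns otherwise — a scalability choice that leaves small problems
untouched. Louvain modularity optimisation (python-igraph, seeded through
Python's `random` module) yields the partition at resolution 0.8 by default;
Leiden-style alternatives are out of scope. Cluster ids are relabelled
contiguously from zero in order of first appearance.

The Adjusted Rand Index is computed from the contingency table in exact
integer arithmetic; the 0/0 edge cases (both partitions all-singletons or
both a single cluster) return 1.0, which are the only ways the denominator
can vanish. `resolution_scan` picks the grid resolution maximising ARI
against reference labels (ties to the smallest resolution) and returns the
full table; it is only offered when trustworthy reference labels exist,
because tuning resolution against the labels one later evaluates against is
circular — the default unsupervised path uses the fixed resolution and logs
that fact. UMAP is wrapped purely for visualisation, seeded, with random
initialisation below 10 points where spectral initialisation is undefined.

## Per-cluster classification

For cluster j, marker genes are the ones with two-sided Mann–Whitney
p ≤ α (default 0.01) between the cluster and the rest — scipy's
implementation, which uses the exact distribution for small tie-free groups
and the tie- and continuity-corrected normal approximation otherwise. The
design stacks the full ADT panel before the selected genes (`integrated`),
or uses either block alone; no intercept by default (the scaled features are
centred), with an option to add one.

The weighted logistic loss uses the class-balancing weights
`w_i = 0.5n[z_i/π + (1−z_i)/(1−π)]` exactly; each class's total weight is
n²/2 as an algebraic identity, tested as such. The minimiser is
Newton/IRLS with a small ridge (default 1e-4) that keeps separable designs
finite; non-convergence warns and returns the best iterate. At π = 0.5 the
weights are constant and the fit coincides with plain logistic regression,
which is cross-checked against scikit-learn in the tests. Hard
classification thresholds the linear predictor at zero; evaluation uses the
rank-based AUC of the continuous scores (ties contribute ½), the standard
choice when the downstream question is ranking quality.

Repeated evaluation draws stratified 70/30 train/test splits (default 100
repeats). Marker selection runs inside the training portion of each split by
default, so the test cells never influence the gene set; a
`select_on_all` switch reproduces the simpler select-once protocol for
comparability. When no gene clears α in a split (possible when a cluster has
no transcriptomic signature at all), the single smallest-p gene is used so
the RNA-only design is never empty; the reported AUC then honestly hovers at
chance. Coefficients for reporting come from a final fit on all cells.

## Batch correction

Batches enter as a full one-hot design `Z` (no reference level, so `ZᵀZ` is
the diagonal of batch sizes and the per-batch means are directly
identifiable). `Γ̂_RNA = (ZᵀZ)⁻¹ZᵀX` is the matrix of per-batch feature
means and `X̂₀ = (I − P_Z)X` the within-batch-centred RNA. The joint
regression of `Y` on `[Z | X̂₀]` decouples exactly because `ZᵀX̂₀ = 0`:
`Γ̂_ADT` is the per-batch ADT mean and `B̂` the minimum-norm solve of the
within-batch-centred `Y` on `X̂₀`. The decoupled route is implemented and
its equality with a direct joint solve is asserted in tests. With one batch
the whole path reduces exactly to the single-batch pipeline (also asserted).
Preprocessing (normalise/scale) precedes correction; residual
re-standardisation follows it. Only additive per-batch shifts are modelled —
batch-specific coefficient matrices or nonlinear corrections are out of
scope. HVG selection pools batches.

## Synthetic data

The generator draws cluster assignments (uniform by default;
`cluster_weights` gives uneven population sizes), builds latent RNA as
cluster mean shifts (scale `rna_effect`, in SD units of the latent noise)
plus Gaussian noise, and a sparse coefficient matrix (`b_density` nonzero
fraction, entries scaled so each protein's RNA-driven variance is O(1)).
The residual channel's cluster shifts (scale `adt_residual_effect`) plus
noise are explicitly projected onto the orthogonal complement of the latent
RNA columns, so `XᵀU = 0` holds by construction and any structure placed
there is provably invisible to RNA-only analysis — the property that makes
the integration-value experiments meaningful. With `n_marker_adts` set, the
cluster shifts follow a canonical-marker pattern instead (protein m elevated
by the full effect in cluster m mod k and silent elsewhere), mimicking a
population distinguished by a single surface marker; the effect used in the
marker scenarios is 3 SD units, the strength of an essentially binary
canonical marker. Optional per-batch additive shifts
(`batch_effect_sd`) apply to both modalities.

`counts_mode` maps latent values through an exponential link into
negative-binomial sampling (variance μ + φμ², default dispersion φ = 0.5 —
moderate overdispersion; baseline means 0.5 per gene and 20 per protein,
reflecting the much deeper ADT coverage), producing UMI-like integers that
exercise the preprocessing transforms. The generator does not model dropout
beyond NB sampling, doublets, or ambient contamination, so passing tests
demonstrate correctness of the method's mathematics and its behaviour under
its own model — not robustness to every artefact of real droplet data.

## Verification problem sizes

The test-suite experiments use moderate simulated sizes chosen to make their
effects unambiguous: the integration-value experiment runs at n = 2000 cells,
300 genes, 15 proteins, 4 clusters over 10 seeds; batch rescue at n = 1000
with two 70/30-sized populations and batch shifts of 3 SD; parameter
recovery at n = 5000 with no cluster structure (cluster mean offsets are
absorbed into batch means and would confound the comparison, so the recovery
check isolates the batch estimator); classifier attribution at n = 600 with
20 split repeats. The acceptance script re-runs the same experiments from
scratch with the caller's seed.

## Known limitations

* The projection is strictly linear; protein abundance with a nonlinear
  RNA relationship contributes to the residual channel by construction.
* Louvain at a fixed resolution on very low-dimensional data can split
  well-separated groups; the PCA default and k = 20 reflect common practice,
  not an optimum for every geometry.
* Resolution tuning against reference labels is circular when those labels
  are later used for evaluation; the package exposes it for comparability
  but never applies it silently.
* The weighted logistic coefficients are reported under the small ridge
  penalty; with separable clusters their magnitudes depend on it even though
  signs and rankings are stable.
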