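"""Per-cluster interpretation: marker selection, class-balanced logistic
regression, and repeated-split AUC evaluation.

For each cluster j define z_i = 1 if cell i belongs to the cluster.  Genes
differentially expressed in the cluster (two-sided Wilcoxon rank-sum,
p <= alpha) join the ADT panel in a logistic model

    P(z_i = 1 | x_i) = 1 / (1 + exp(-x_i' beta)),

fitted by minimising the class-balanced weighted negative log-likelihood with
weights

    w_i = 0.5 n [ z_i / pi + (1 - z_i) / (1 - pi) ],    pi = mean(z),

so each class contributes a total weight of 0.5 n^2 regardless of imbalance —
a rare cluster is not swamped by the background.  Prediction thresholds the
linear predictor at zero.  Classifier value is summarised by the rank-based
AUC of the linear predictor over repeated stratified 70/30 train/test splits;
comparing the AUC of RNA-only, ADT-only and integrated predictor sets
quantifies what each modality adds for that cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._types import ExpressionMatrix

__all__ = [
    "ClusterClassifier",
    "wilcoxon_select",
    "build_design",
    "fit_weighted_logistic",
    "classify",
    "auc",
    "repeated_split_evaluation",
]

PREDICTOR_MODES = ("rna_only", "adt_only", "integrated")


@dataclass
class ClusterClassifier:
    cluster_id: int
    selected_genes: list
    predictor_mode: str
    beta: np.ndarray
    pi: float
    alpha: float
    converged: bool = True


@dataclass
class SplitEvaluation:
    """AUC distributions over repeated splits plus final-fit coefficients."""

    cluster_id: int
    aucs: dict[str, np.ndarray]  # mode -> (n_repeats,)
    coefficients: dict[str, pd.Series]  # mode -> named coefficient vector
    selected_genes: dict[str, list] = field(default_factory=dict)

    def mean_auc(self, mode: str) -> float:
        return float(np.mean(self.aucs[mode]))


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=float)


def _feature_ids(m, prefix: str, width: int) -> pd.Index:
    if isinstance(m, ExpressionMatrix):
        return m.feature_ids
    return pd.Index([f"{prefix}{i}" for i in range(width)])


def wilcoxon_select(
    X_norm,
    labels,
    cluster_j: int,
    alpha: float = 0.01,
    return_pvalues: bool = False,
):
    """Genes differing between cluster j and the rest (two-sided rank-sum test).

    Uses the Mann-Whitney U test per gene (exact for small tie-free groups,
    tie- and continuity-corrected normal approximation otherwise); returns the
    ids with p <= alpha ordered by ascending p.
    """
    Xv = _values(X_norm)
    labels = np.asarray(labels)
    in_mask = labels == cluster_j
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError(
            f"cluster {cluster_j} needs >= 2 cells inside and outside "
            f"(got {n_in} / {n_out})"
        )
    res = stats.mannwhitneyu(Xv[in_mask], Xv[~in_mask], axis=0, method="auto")
    pvals = np.atleast_1d(res.pvalue)
    ids = _feature_ids(X_norm, "gene_", Xv.shape[1])
    order = np.argsort(pvals, kind="stable")
    keep = order[pvals[order] <= alpha]
    selected = ids[keep].tolist()
    if return_pvalues:
        return selected, pd.Series(pvals, index=ids)
    return selected


def build_design(
    Y_norm,
    X_norm,
    selected_genes,
    predictor_mode: str = "integrated",
    intercept: bool = False,
) -> tuple[np.ndarray, pd.Index]:
    """Assemble the per-cluster design matrix.

    ``integrated`` stacks the full ADT panel (q columns) before the selected
    genes (p_j columns); ``rna_only`` uses the selected genes; ``adt_only``
    the ADT panel.  No intercept column unless requested.
    """
    if predictor_mode not in PREDICTOR_MODES:
        raise ValueError(f"predictor_mode must be one of {PREDICTOR_MODES}")
    Yv = _values(Y_norm)
    Xv = _values(X_norm)
    if Yv.shape[0] != Xv.shape[0]:
        raise ValueError("ADT and RNA matrices disagree on the number of cells")
    adt_ids = _feature_ids(Y_norm, "adt_", Yv.shape[1])
    gene_ids = _feature_ids(X_norm, "gene_", Xv.shape[1])

    blocks, names = [], []
    if predictor_mode in ("adt_only", "integrated"):
        blocks.append(Yv)
        names.extend(adt_ids.tolist())
    if predictor_mode in ("rna_only", "integrated"):
        if len(selected_genes) == 0:
            if predictor_mode == "rna_only":
                raise ValueError(
                    "no genes selected: the RNA-only design is empty "
                    "(relax alpha or check the cluster)"
                )
        else:
            gi = gene_ids.get_indexer(pd.Index(selected_genes))
            if (gi < 0).any():
                raise KeyError("selected genes missing from the RNA matrix")
            blocks.append(Xv[:, gi])
            names.extend(list(selected_genes))
    design = np.hstack(blocks) if blocks else np.empty((Yv.shape[0], 0))
    if intercept:
        design = np.hstack([design, np.ones((design.shape[0], 1))])
        names.append("(intercept)")
    return design, pd.Index(names)


def class_balance_weights(z: np.ndarray) -> np.ndarray:
    """w_i = 0.5 n [z_i/pi + (1-z_i)/(1-pi)]; each class sums to 0.5 n^2."""
    z = np.asarray(z, dtype=float)
    n = z.size
    pi = z.mean()
    if not 0.0 < pi < 1.0:
        raise ValueError("z must contain both classes")
    return 0.5 * n * (z / pi + (1.0 - z) / (1.0 - pi))


def fit_weighted_logistic(
    design: np.ndarray,
    z,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-4,
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS minimiser of the class-balanced weighted logistic loss.

    Minimises sum_i w_i [-z_i log p_i - (1-z_i) log(1-p_i)] + ridge ||beta||^2/2.
    The small default ridge keeps separable designs finite.  Returns
    ``(beta, converged)``; non-convergence warns and returns the best iterate.
    """
    X = np.asarray(design, dtype=float)
    z = np.asarray(z, dtype=float)
    w = class_balance_weights(z)
    n, d = X.shape
    beta = np.zeros(d)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        grad = X.T @ (w * (z - p)) - ridge * beta
        s = np.maximum(w * p * (1.0 - p), 1e-12)
        H = (X.T * s) @ X + ridge * np.eye(d)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol * max(1.0, np.max(np.abs(beta))):
            converged = True
            break
    if not converged:
        warnings.warn("weighted logistic fit did not converge; returning last iterate",
                      stacklevel=2)
    return beta, converged


def classify(design: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Predict 1 when the linear predictor is strictly positive, else 0."""
    design = np.asarray(design, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if design.shape[1] != beta.size:
        raise ValueError(f"design has {design.shape[1]} columns, beta has {beta.size}")
    return (design @ beta > 0).astype(int)


def auc(scores, truth) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth differ in length")
    pos = truth == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _stratified_split(z: np.ndarray, train_frac: float, rng: np.random.Generator):
    train_idx = []
    test_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(z == cls)
        if idx.size < 2:
            raise ValueError("cluster too small for a stratified split")
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both sides non-empty per class
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def repeated_split_evaluation(
    Y_norm,
    X_norm,
    labels,
    cluster_j: int,
    modes=PREDICTOR_MODES,
    train_frac: float = 0.7,
    n_repeats: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
    ridge: float = 1e-4,
    select_on_all: bool = False,
) -> SplitEvaluation:
    """Repeated stratified train/test evaluation of the cluster-j classifiers.

    Each repeat draws a stratified ``train_frac`` split, selects marker genes
    on the training cells only (``select_on_all=True`` reproduces the simpler
    select-once-on-everything protocol), fits the weighted logistic model per
    predictor mode on the training cells and scores the AUC of the linear
    predictor on the held-out cells.  If no gene clears ``alpha`` in a split,
    the single smallest-p gene is used so the RNA design is never empty.
    Coefficients for reporting come from a final fit on all cells.
    """
    labels = np.asarray(labels)
    z = (labels == cluster_j).astype(int)
    if z.sum() < 2 or (1 - z).sum() < 2:
        raise ValueError(f"cluster {cluster_j} too small to evaluate")
    rng = np.random.default_rng(seed)

    genes_all = None
    if select_on_all:
        genes_all = _select_with_fallback(X_norm, labels, cluster_j, alpha)

    aucs: dict[str, list] = {m: [] for m in modes}
    for _ in range(n_repeats):
        tr, te = _stratified_split(z, train_frac, rng)
        if genes_all is not None:
            genes = genes_all
        else:
            genes = _select_with_fallback(
                _subset_rows(X_norm, tr), labels[tr], cluster_j, alpha
            )
        for mode in modes:
            design, _ = build_design(Y_norm, X_norm, genes, mode)
            beta, _ = fit_weighted_logistic(design[tr], z[tr], ridge=ridge)
            aucs[mode].append(auc(design[te] @ beta, z[te]))

    final_genes = genes_all if genes_all is not None else _select_with_fallback(
        X_norm, labels, cluster_j, alpha
    )
    coefficients = {}
    for mode in modes:
        design, names = build_design(Y_norm, X_norm, final_genes, mode)
        beta, _ = fit_weighted_logistic(design, z, ridge=ridge)
        coefficients[mode] = pd.Series(beta, index=names)

    return SplitEvaluation(
        cluster_id=cluster_j,
        aucs={m: np.asarray(v) for m, v in aucs.items()},
        coefficients=coefficients,
        selected_genes={"final": final_genes},
    )


def _select_with_fallback(X_norm, labels, cluster_j, alpha):
    selected, pvals = wilcoxon_select(X_norm, labels, cluster_j, alpha, return_pvalues=True)
    if not selected:
        selected = [pvals.idxmin()]
    return selected


def _subset_rows(m, idx):
    if isinstance(m, ExpressionMatrix):
        return ExpressionMatrix(
            values=m.values[idx],
            obs_ids=m.obs_ids[idx],
            feature_ids=m.feature_ids,
            state=m.state,
            modality=m.modality,
        )
    return np.asarray(m)[idx]
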