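"""Multi-batch integration: ANOVA batch-effect removal before projection.

With B batches encoded in a one-hot n x B design Z, the expression matrices
decompose into additive per-batch shifts and batch-free main effects:

    X = Z Gamma_RNA' + X0,      Y = Z Gamma_ADT' + Y0 = Z Gamma_ADT' + X0 B + U.

Gamma_RNA is estimated by regressing X on Z — i.e. per-batch feature means —
and the corrected RNA is the within-batch-centred X0_hat = (I - P_Z) X.
Y is then regressed jointly on [Z | X0_hat]; because Z' X0_hat = 0 the joint
least-squares estimates decouple exactly into Gamma_ADT_hat = (Z'Z)^-1 Z'Y and
B_hat = least squares of the within-batch-centred Y on X0_hat, which is the
route implemented here.  Clustering then uses [X0_hat | U_hat], identical to
the single-batch path, which the B = 1 case reduces to exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import ExpressionMatrix
from .integrate import IntegratedData, ProjectionResult, integrate

__all__ = [
    "BatchDesign",
    "BatchModel",
    "build_batch_design",
    "correct_rna",
    "fit_batch_projection",
    "batch_integrate",
]


@dataclass
class BatchDesign:
    Z: np.ndarray  # (n, B) one-hot
    batch_ids: pd.Index  # length B, first-appearance order

    @property
    def n_batches(self) -> int:
        return self.Z.shape[1]

    @property
    def sizes(self) -> np.ndarray:
        return self.Z.sum(axis=0).astype(int)


@dataclass
class BatchModel:
    design: BatchDesign
    Gamma_rna: np.ndarray  # (B, p) per-batch RNA shifts
    Gamma_adt: np.ndarray  # (B, q) per-batch ADT shifts
    X0_hat: np.ndarray  # (n, p) corrected RNA
    Y0_hat: np.ndarray  # (n, q) corrected-ADT fit X0_hat @ B_hat
    B_hat: np.ndarray  # (p, q)
    U_hat: np.ndarray  # (n, q) residuals
    rank: int
    feature_ids_rna: pd.Index | None = None
    feature_ids_adt: pd.Index | None = None
    obs_ids: pd.Index | None = None


def build_batch_design(batch_labels) -> BatchDesign:
    """One-hot encode batch labels; batch order is first appearance."""
    labels = pd.Series(batch_labels)
    if labels.isna().any():
        bad = labels.index[labels.isna()].tolist()
        raise ValueError(f"missing batch labels at positions {bad[:5]}")
    if labels.empty:
        raise ValueError("no batch labels given")
    batch_ids = labels.drop_duplicates().reset_index(drop=True)
    codes = labels.map({b: i for i, b in batch_ids.items()}).to_numpy()
    Z = np.zeros((labels.size, batch_ids.size))
    Z[np.arange(labels.size), codes] = 1.0
    return BatchDesign(Z=Z, batch_ids=pd.Index(batch_ids))


def _values(m) -> np.ndarray:
    return m.values.astype(float) if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=float)


def correct_rna(X, design: BatchDesign) -> tuple[np.ndarray, np.ndarray]:
    """Estimate per-batch RNA shifts and return the within-batch-centred RNA.

    Gamma_rna_hat = (Z'Z)^-1 Z'X (per-batch feature means) and
    X0_hat = [I - Z (Z'Z)^-1 Z'] X.
    """
    Xv = _values(X)
    Z = design.Z
    if Xv.shape[0] != Z.shape[0]:
        raise ValueError("X and batch design disagree on the number of cells")
    sizes = Z.sum(axis=0)
    Gamma = (Z.T @ Xv) / sizes[:, None]
    X0 = Xv - Z @ Gamma
    return Gamma, X0


def fit_batch_projection(Y, design: BatchDesign, X0_hat: np.ndarray, X=None) -> BatchModel:
    """Joint regression of Y on [Z | X0_hat], solved by orthogonal decoupling.

    Z' X0_hat = 0 by construction, so the joint least-squares problem splits:
    Gamma_adt_hat is the per-batch ADT mean and B_hat the minimum-norm solve of
    the within-batch-centred Y on X0_hat.  Residuals follow as
    U_hat = Y - Z Gamma_adt_hat' - X0_hat B_hat.
    """
    Yv = _values(Y)
    Z = design.Z
    if Yv.shape[0] != Z.shape[0] or X0_hat.shape[0] != Z.shape[0]:
        raise ValueError("Y, X0_hat and the batch design disagree on observations")
    if np.max(np.abs(Z.T @ X0_hat)) > 1e-6 * max(1.0, np.abs(X0_hat).max()) * Z.shape[0]:
        raise ValueError("X0_hat is not within-batch centred for this design")

    sizes = Z.sum(axis=0)
    Gamma_adt = (Z.T @ Yv) / sizes[:, None]
    Yc = Yv - Z @ Gamma_adt
    B_hat, _, rank, _ = np.linalg.lstsq(X0_hat, Yc, rcond=None)
    Y0_hat = X0_hat @ B_hat
    U_hat = Yv - Z @ Gamma_adt - Y0_hat

    Gamma_rna = None
    if X is not None:
        Gamma_rna, _ = correct_rna(X, design)
    return BatchModel(
        design=design,
        Gamma_rna=Gamma_rna if Gamma_rna is not None else np.zeros((design.n_batches, X0_hat.shape[1])),
        Gamma_adt=Gamma_adt,
        X0_hat=X0_hat,
        Y0_hat=Y0_hat,
        B_hat=B_hat,
        U_hat=U_hat,
        rank=int(rank),
        feature_ids_rna=getattr(X, "feature_ids", None) if X is not None else None,
        feature_ids_adt=getattr(Y, "feature_ids", None),
        obs_ids=getattr(Y, "obs_ids", None),
    )


def batch_integrate(model: BatchModel, restandardize_residuals: bool = True) -> IntegratedData:
    """Concatenate corrected RNA with (re-standardised) residuals for clustering."""
    q = model.U_hat.shape[1]
    adt_ids = (
        model.feature_ids_adt
        if model.feature_ids_adt is not None
        else pd.Index([f"adt_{i}" for i in range(q)])
    )
    result = ProjectionResult(
        Y_hat=model.Y0_hat,
        U_hat=model.U_hat,
        r2_per_adt=np.zeros(q),
        r2_raw=np.zeros(q),
        feature_ids_adt=pd.Index(adt_ids),
    )
    data = integrate(model.X0_hat, result, restandardize_residuals=restandardize_residuals)
    if model.obs_ids is not None:
        data.obs_ids = pd.Index(model.obs_ids)
    if model.feature_ids_rna is not None:
        data.feature_ids = pd.Index(model.feature_ids_rna).append(
            pd.Index([f"residual_{a}" for a in adt_ids])
        )
    return data
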