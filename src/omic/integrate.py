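"""Orthogonal integration of ADT onto RNA.

The core model is a multivariate linear regression of the scaled ADT matrix Y
(n x q) on the scaled RNA matrix X (n x p),

    Y = X B + U,        u_i ~ N_q(0, Sigma) i.i.d., uncorrelated with X,

whose least-squares fit splits every protein's expression into a part the
transcriptome linearly explains (Y_hat = X B_hat) and an orthogonal residual
(U_hat = Y - Y_hat) carrying only information that RNA cannot provide.
Clustering then runs on the column-concatenation [X | U_hat], which keeps both
modalities while removing their redundancy, at O(n p^2) cost.

Because X and Y are column-standardised (mean zero), the model carries no
intercept.  B_hat is the minimum-norm least-squares solution, so rank-deficient
X (collinear scaled genes) is handled; the effective rank is recorded and a
warning emitted when it falls below p.  Sigma_hat uses the maximum-likelihood
1/n denominator by default, with 1/(n - rank) available for the unbiased
variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import ExpressionMatrix, Modality, State

__all__ = [
    "ProjectionModel",
    "ProjectionResult",
    "IntegratedData",
    "fit_projection",
    "residualize",
    "integrate",
    "explained_variance_report",
]

_MEAN_TOL = 0.1  # columns should be centred; louder deviations get a warning


@dataclass
class ProjectionModel:
    """Fitted ADT-on-RNA regression: coefficients and residual covariance."""

    B_hat: np.ndarray  # (p, q)
    Sigma_hat: np.ndarray  # (q, q), symmetric PSD
    rank: int  # effective rank of X used in the solve
    feature_ids_rna: pd.Index
    feature_ids_adt: pd.Index
    sigma_denominator: str = "n"


@dataclass
class ProjectionResult:
    """Decomposition Y = Y_hat + U_hat plus per-protein explained variance."""

    Y_hat: np.ndarray  # (n, q) RNA-explained part
    U_hat: np.ndarray  # (n, q) orthogonal residual
    r2_per_adt: np.ndarray  # (q,) clipped to [0, 1]
    r2_raw: np.ndarray  # (q,) unclipped, for diagnostics
    feature_ids_adt: pd.Index


@dataclass
class IntegratedData:
    """[X | standardised residuals], ready for graph clustering."""

    values: np.ndarray  # (n, p + q)
    block_labels: np.ndarray  # per-column: "rna" or "adt_residual"
    obs_ids: pd.Index
    feature_ids: pd.Index

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]


def _as_scaled_array(m, modality: Modality | None) -> np.ndarray:
    if isinstance(m, ExpressionMatrix):
        if m.state is not State.SCALED:
            raise ValueError(f"expected scaled input, got state {m.state.value}")
        if modality is not None and m.modality is not modality:
            raise ValueError(f"expected {modality.value} input, got {m.modality.value}")
        return np.asarray(m.values, dtype=float)
    return np.asarray(m, dtype=float)


def fit_projection(
    X: ExpressionMatrix | np.ndarray,
    Y: ExpressionMatrix | np.ndarray,
    sigma_denominator: str = "n",
) -> ProjectionModel:
    """Fit the multivariate regression of scaled ADT on scaled RNA.

    B_hat minimises ||Y - X B||_F; with full-rank X this equals
    (X'X)^-1 X'Y, otherwise the minimum-norm solution from an SVD-based
    rank-revealing solve.  Sigma_hat = Y'(I - P_X)Y / n with P_X the projection
    onto col(X) (``sigma_denominator="n-rank"`` selects the unbiased variant).
    """
    Xv = _as_scaled_array(X, Modality.RNA)
    Yv = _as_scaled_array(Y, Modality.ADT)
    n, p = Xv.shape
    if Yv.shape[0] != n:
        raise ValueError(f"observation mismatch: X has {n} rows, Y has {Yv.shape[0]}")
    if n < 2:
        raise ValueError("need at least 2 observations to fit the projection")
    if sigma_denominator not in ("n", "n-rank"):
        raise ValueError("sigma_denominator must be 'n' or 'n-rank'")

    col_means = np.abs(Xv.mean(axis=0)).max(initial=0.0)
    if col_means > _MEAN_TOL:
        warnings.warn(
            f"X columns are not centred (max |mean| = {col_means:.3g}); "
            "the model has no intercept",
            stacklevel=2,
        )

    B_hat, _, rank, _ = np.linalg.lstsq(Xv, Yv, rcond=None)
    if rank < p:
        warnings.warn(f"X is rank deficient: effective rank {rank} < p = {p}", stacklevel=2)

    resid = Yv - Xv @ B_hat
    denom = n if sigma_denominator == "n" else max(n - rank, 1)
    Sigma_hat = (resid.T @ resid) / denom
    Sigma_hat = 0.5 * (Sigma_hat + Sigma_hat.T)  # enforce exact symmetry

    rna_ids = X.feature_ids if isinstance(X, ExpressionMatrix) else pd.RangeIndex(p)
    adt_ids = Y.feature_ids if isinstance(Y, ExpressionMatrix) else pd.RangeIndex(Yv.shape[1])
    return ProjectionModel(
        B_hat=B_hat,
        Sigma_hat=Sigma_hat,
        rank=int(rank),
        feature_ids_rna=pd.Index(rna_ids),
        feature_ids_adt=pd.Index(adt_ids),
        sigma_denominator=sigma_denominator,
    )


def residualize(
    X: ExpressionMatrix | np.ndarray,
    Y: ExpressionMatrix | np.ndarray,
    model: ProjectionModel,
) -> ProjectionResult:
    """Split Y into the RNA-explained part and the orthogonal residual.

    ``r2_per_adt[k] = 1 - ||u_k||^2 / ||y_k||^2`` on the zero-mean scaled
    columns: the fraction of protein k's variance the RNA regression captures.
    """
    Xv = _as_scaled_array(X, Modality.RNA)
    Yv = _as_scaled_array(Y, Modality.ADT)
    if isinstance(X, ExpressionMatrix) and not X.feature_ids.equals(model.feature_ids_rna):
        raise ValueError("RNA features differ from those the model was fitted on")
    if isinstance(Y, ExpressionMatrix) and not Y.feature_ids.equals(model.feature_ids_adt):
        raise ValueError("ADT features differ from those the model was fitted on")
    if Xv.shape[1] != model.B_hat.shape[0]:
        raise ValueError(
            f"X has {Xv.shape[1]} features but the model expects {model.B_hat.shape[0]}"
        )
    if Yv.shape[1] != model.B_hat.shape[1]:
        raise ValueError(
            f"Y has {Yv.shape[1]} features but the model expects {model.B_hat.shape[1]}"
        )

    Y_hat = Xv @ model.B_hat
    U_hat = Yv - Y_hat
    ss_tot = (Yv**2).sum(axis=0)
    ss_res = (U_hat**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_raw = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)
    return ProjectionResult(
        Y_hat=Y_hat,
        U_hat=U_hat,
        r2_per_adt=np.clip(r2_raw, 0.0, 1.0),
        r2_raw=r2_raw,
        feature_ids_adt=model.feature_ids_adt,
    )


def integrate(
    X: ExpressionMatrix | np.ndarray,
    result: ProjectionResult,
    restandardize_residuals: bool = True,
) -> IntegratedData:
    """Column-concatenate X with the ADT residuals.

    With ``restandardize_residuals`` (default) each residual column is rescaled
    to unit n-1 SD; residual means are already ~0 by construction.  Residuals
    are signed, so no log transform is applied.  Constant residual columns are
    kept as zeros.
    """
    Xv = _as_scaled_array(X, Modality.RNA)
    U = result.U_hat
    if U.shape[0] != Xv.shape[0]:
        raise ValueError("X and residuals have different numbers of observations")
    if restandardize_residuals and U.shape[0] > 1:
        sd = U.std(axis=0, ddof=1)
        # residual columns that are numerically zero (protein fully explained
        # by RNA) stay zero instead of having round-off noise blown up to SD 1
        yscale = max(np.abs(result.Y_hat).max(), np.abs(U).max(), 1e-300)
        tiny = sd <= 1e-10 * yscale
        U = np.where(tiny, 0.0, U / np.where(tiny, 1.0, sd))
    values = np.hstack([Xv, U])
    p, q = Xv.shape[1], U.shape[1]
    block_labels = np.array(["rna"] * p + ["adt_residual"] * q)
    if isinstance(X, ExpressionMatrix):
        obs_ids = X.obs_ids
        rna_ids = X.feature_ids
    else:
        obs_ids = pd.RangeIndex(Xv.shape[0])
        rna_ids = pd.Index([f"rna_{i}" for i in range(p)])
    adt_ids = pd.Index([f"residual_{a}" for a in result.feature_ids_adt])
    return IntegratedData(
        values=values,
        block_labels=block_labels,
        obs_ids=pd.Index(obs_ids),
        feature_ids=pd.Index(rna_ids).append(adt_ids),
    )


def explained_variance_report(result: ProjectionResult) -> pd.DataFrame:
    """Per-protein explained variance, sorted ascending.

    The proteins at the top of the table are those whose expression RNA
    explains worst — the ones carrying the most RNA-orthogonal information
    and therefore the most to gain from integration.
    """
    df = pd.DataFrame({"adt_id": result.feature_ids_adt, "r2": result.r2_per_adt})
    return df.sort_values("r2", kind="stable").reset_index(drop=True)
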