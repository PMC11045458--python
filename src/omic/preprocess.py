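"""Normalisation, scaling and highly-variable-gene selection.

Raw UMI counts enter here and leave as the two scaled matrices the orthogonal
integration model consumes: X (cells x genes, z-scored log-normalised RNA) and
Y (cells x proteins, z-scored CLR-transformed ADT).

Conventions
-----------
* RNA: per-cell library-size normalisation to ``scale_factor`` followed by
  ``log1p`` — entry (c, g) becomes ``ln(1 + count * scale_factor / total_c)``.
* ADT: centred log-ratio with a +1 pseudocount.  The default margin centres
  each protein across cells (the "margin 2" convention for antibody panels);
  the alternative centres within each cell across proteins.
* Scaling: per-feature z-score with the n-1 sample standard deviation;
  constant features map to all-zero columns rather than NaN.
* HVG ranking follows the variance-stabilising recipe: a loess-style trend of
  log10(variance) on log10(mean) of raw counts predicts each gene's expected
  standard deviation; counts standardised by that prediction are clipped at
  sqrt(n) and genes are ranked by the variance of the clipped values.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._types import ExpressionMatrix, Modality, State

__all__ = [
    "CLRMargin",
    "lognormalize_rna",
    "clr_transform",
    "scale_features",
    "select_hvg",
]


class CLRMargin(str, Enum):
    """Which margin the CLR centres over."""

    FEATURE_ACROSS_CELLS = "feature_across_cells"  # per-protein, across cells
    WITHIN_CELL = "within_cell"  # per-cell, across proteins


def _require(m: ExpressionMatrix, state: State, modality: Modality | None = None) -> None:
    if m.state is not state:
        raise ValueError(f"expected a {state.value} matrix, got {m.state.value}")
    if modality is not None and m.modality is not modality:
        raise ValueError(f"expected {modality.value} modality, got {m.modality.value}")


def lognormalize_rna(counts: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalise and log-transform raw RNA counts.

    Entry (c, g) becomes ``ln(1 + counts[c, g] * scale_factor / total_counts[c])``.

    Raises
    ------
    ValueError
        If any cell has zero total count (names the offending cell).
    """
    _require(counts, State.RAW, Modality.RNA)
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = counts.values.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.obs_ids[np.flatnonzero(totals <= 0)].tolist()
        raise ValueError(f"cells with zero total count: {bad[:5]}")
    out = np.log1p(counts.values * (scale_factor / totals[:, None]))
    return counts.copy_with(out, State.NORMALIZED)


def clr_transform(
    counts: ExpressionMatrix,
    margin: CLRMargin | str = CLRMargin.FEATURE_ACROSS_CELLS,
    dialect: str = "pseudocount",
) -> ExpressionMatrix:
    """Centred log-ratio transform of raw ADT counts.

    Default dialect: ``ln(x + 1)`` centred by the arithmetic mean of
    ``ln(x + 1)`` over the chosen margin.  The ``positive_geomean`` dialect
    instead divides by ``exp(mean of log1p over positive entries)`` before the
    log, matching pipelines that ignore zeros when forming the geometric mean.
    """
    _require(counts, State.RAW, Modality.ADT)
    margin = CLRMargin(margin)
    axis = 0 if margin is CLRMargin.FEATURE_ACROSS_CELLS else 1
    logx = np.log1p(counts.values.astype(float))
    if dialect == "pseudocount":
        out = logx - logx.mean(axis=axis, keepdims=True)
    elif dialect == "positive_geomean":
        pos = counts.values > 0
        npos = pos.sum(axis=axis, keepdims=True)
        with np.errstate(invalid="ignore"):
            mean_pos = np.where(npos > 0, (logx * pos).sum(axis=axis, keepdims=True) / npos, 0.0)
        out = np.log1p(counts.values / np.exp(mean_pos))
    else:
        raise ValueError(f"unknown clr dialect {dialect!r}")
    return counts.copy_with(out, State.NORMALIZED)


def scale_features(m: ExpressionMatrix, clip: float | None = None) -> ExpressionMatrix:
    """Z-score each feature column (n-1 SD); constant columns become zeros.

    ``clip`` caps absolute z-scores (common choice 10); default is no clipping,
    which keeps the downstream residual orthogonality exact.
    """
    _require(m, State.NORMALIZED)
    vals = m.values.astype(float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if m.n_obs > 1 else np.zeros(m.n_features)
    out = np.where(sd > 0, (vals - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if clip is not None:
        out = np.clip(out, -clip, clip)
    return m.copy_with(out, State.SCALED)


def select_hvg(
    normalized_rna: ExpressionMatrix,
    raw_rna: ExpressionMatrix,
    n_top: int = 2000,
    span: float = 0.3,
) -> list:
    """Rank genes by standardised variance and return the top ``n_top`` ids.

    Fits a loess-style local-linear regression of log10(variance) on
    log10(mean) over genes with positive raw-count variance, standardises each
    gene's counts by the trend-predicted SD with clipping at sqrt(n), and ranks
    by the variance of the clipped standardised counts (descending, ties broken
    by feature order).  Deterministic given inputs and span.
    """
    _require(normalized_rna, State.NORMALIZED, Modality.RNA)
    _require(raw_rna, State.RAW, Modality.RNA)
    if not normalized_rna.feature_ids.equals(raw_rna.feature_ids):
        raise ValueError("normalized and raw matrices must share feature_ids")
    if n_top <= 0:
        raise ValueError("n_top must be positive")

    counts = raw_rna.values.astype(float)
    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    eligible = np.flatnonzero(var > 0)
    if n_top > eligible.size:
        raise ValueError(
            f"n_top={n_top} exceeds the {eligible.size} features with positive variance"
        )

    log_mean = np.log10(mean[eligible])
    log_var = np.log10(var[eligible])
    # widen the smoothing window so it always covers at least a few features
    frac = max(span, min(1.0, 4.0 / eligible.size))
    with np.errstate(invalid="ignore", divide="ignore"):
        fitted_log_var = lowess(log_var, log_mean, frac=frac, xvals=log_mean)
    # degenerate windows (e.g. duplicated log-means) fall back to the raw trend
    bad = ~np.isfinite(fitted_log_var)
    fitted_log_var[bad] = log_var[bad]
    expected_sd = np.sqrt(10.0 ** fitted_log_var)

    clip_val = np.sqrt(n)
    z = (counts[:, eligible] - mean[eligible]) / expected_sd
    z = np.clip(z, -clip_val, clip_val)
    std_variance = z.var(axis=0, ddof=1)

    # stable argsort on the negated variance keeps ties in feature order
    order = np.argsort(-std_variance, kind="stable")[:n_top]
    return raw_rna.feature_ids[eligible[order]].tolist()
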