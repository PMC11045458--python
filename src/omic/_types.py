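"""Core data containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a lightweight wrapper around a
dense ``(n_obs, n_features)`` float array carrying observation/feature identifiers,
the modality (RNA or ADT) and a processing-state tag.  The state tag lets each
stage enforce its contract (e.g. log-normalisation only accepts raw counts,
scaling only accepts normalised data) without guessing from the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = ["Modality", "State", "ExpressionMatrix"]


class Modality(str, Enum):
    RNA = "RNA"
    ADT = "ADT"


class State(str, Enum):
    RAW = "raw"
    NORMALIZED = "normalized"
    SCALED = "scaled"


@dataclass
class ExpressionMatrix:
    """Observations x features expression matrix with identifiers and a state tag.

    Parameters
    ----------
    values
        Dense numeric array of shape ``(n_obs, n_features)``; no missing entries.
    obs_ids
        Unique observation (cell / spot) identifiers, length ``n_obs``.
    feature_ids
        Unique feature (gene / protein) identifiers, length ``n_features``.
    state
        Processing state: ``raw`` (non-negative integer counts), ``normalized``
        (log / CLR space) or ``scaled`` (per-feature z-scores).
    modality
        ``RNA`` or ``ADT``.
    """

    values: np.ndarray
    obs_ids: pd.Index
    feature_ids: pd.Index
    state: State
    modality: Modality
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        self.obs_ids = pd.Index(self.obs_ids)
        self.feature_ids = pd.Index(self.feature_ids)
        self.state = State(self.state)
        self.modality = Modality(self.modality)
        n, m = self.values.shape
        if len(self.obs_ids) != n:
            raise ValueError(f"{len(self.obs_ids)} obs_ids for {n} rows")
        if len(self.feature_ids) != m:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {m} columns")
        if not self.obs_ids.is_unique:
            raise ValueError("obs_ids are not unique")
        if not self.feature_ids.is_unique:
            raise ValueError("feature_ids are not unique")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")
        if self.state is State.RAW:
            # non-integer "counts" are tolerated: ADT panels sometimes arrive
            # background-subtracted, and the CLR only needs non-negativity
            if (self.values < 0).any():
                raise ValueError("raw counts must be non-negative")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: np.ndarray, state: State | str | None = None) -> "ExpressionMatrix":
        """Return a new matrix sharing identifiers but with new values/state."""
        return ExpressionMatrix(
            values=values,
            obs_ids=self.obs_ids,
            feature_ids=self.feature_ids,
            state=State(state) if state is not None else self.state,
            modality=self.modality,
            meta=dict(self.meta),
        )

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        idx = self.feature_ids.get_indexer(pd.Index(feature_ids))
        if (idx < 0).any():
            missing = pd.Index(feature_ids)[idx < 0].tolist()
            raise KeyError(f"features not present: {missing[:5]}")
        return ExpressionMatrix(
            values=self.values[:, idx],
            obs_ids=self.obs_ids,
            feature_ids=pd.Index(feature_ids),
            state=self.state,
            modality=self.modality,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.feature_ids)
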