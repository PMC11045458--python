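"""Readers and writers for the supported on-disk formats.

Three input formats are supported, all with cells as rows after loading:

* ``mtx_dir`` — a 10x-style directory with ``matrix.mtx`` plus ``features.tsv``
  (or ``genes.tsv``) and ``barcodes.tsv`` sidecars; the matrix is stored
  features x cells and transposed on read.
* ``csv`` / ``tsv`` — dense, header row = feature ids, index column = cell ids.
* ``h5`` — an .h5ad container with RNA as the main matrix and ADT as a named
  ``obsm`` entry, so the file opens unchanged in scanpy or Seurat converters.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from ._types import ExpressionMatrix, Modality, State

__all__ = ["read_matrix", "write_matrix_csv", "write_container", "read_container", "ADT_KEY"]

ADT_KEY = "ADT"


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "mtx_dir"
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    if suffix in (".h5", ".h5ad"):
        return "h5"
    raise ValueError(f"cannot infer format of {path}")


def read_matrix(
    path,
    format: str | None = None,
    modality: Modality | str = Modality.RNA,
    state: State | str = State.RAW,
    expected_features=None,
) -> ExpressionMatrix:
    """Load an expression matrix with observation/feature identifiers.

    ``expected_features``: optional iterable of known feature ids; when a CSV
    arrives transposed (features as rows), overlap with the row index triggers
    an automatic transpose with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    modality = Modality(modality)
    state = State(state)

    if fmt == "mtx_dir":
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"missing matrix.mtx in {path}")
        feat_file = next((path / n for n in ("features.tsv", "genes.tsv") if (path / n).exists()), None)
        bc_file = path / "barcodes.tsv"
        if feat_file is None:
            raise FileNotFoundError(f"missing features.tsv/genes.tsv in {path}")
        if not bc_file.exists():
            raise FileNotFoundError(f"missing barcodes.tsv in {path}")
        m = spio.mmread(mtx)
        features = pd.read_csv(feat_file, sep="\t", header=None)[0]
        barcodes = pd.read_csv(bc_file, sep="\t", header=None)[0]
        if m.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"matrix.mtx is {m.shape} but sidecars give "
                f"{len(features)} features x {len(barcodes)} barcodes"
            )
        values = np.asarray(m.T.todense() if sparse.issparse(m) else m.T)
        return ExpressionMatrix(values, pd.Index(barcodes), pd.Index(features), state, modality)

    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if expected_features is not None:
            expected = pd.Index(expected_features)
            row_hits = expected.isin(df.index).mean()
            col_hits = expected.isin(df.columns).mean()
            if row_hits > col_hits and row_hits > 0.5:
                warnings.warn(
                    f"{path.name}: feature ids found on the row axis; transposing "
                    "to cells x features",
                    stacklevel=2,
                )
                df = df.T
        return ExpressionMatrix(
            df.to_numpy(dtype=float), pd.Index(df.index), pd.Index(df.columns), state, modality
        )

    if fmt == "h5":
        rna, adt_m = read_container(path)
        return rna if modality is Modality.RNA else adt_m

    raise ValueError(f"unknown format {format!r}")


def write_matrix_csv(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path)


def write_container(
    path,
    rna: ExpressionMatrix,
    adt: ExpressionMatrix,
    obs: pd.DataFrame | None = None,
    uns: dict | None = None,
) -> None:
    """Write paired matrices to an .h5ad container (RNA = X, ADT in obsm)."""
    if not rna.obs_ids.equals(adt.obs_ids):
        raise ValueError("RNA and ADT matrices disagree on observations")
    obs_index = rna.obs_ids.astype(str).rename(None)
    adata = ad.AnnData(
        X=np.asarray(rna.values, dtype=float),
        obs=(obs.copy() if obs is not None else pd.DataFrame(index=obs_index)),
        var=pd.DataFrame(index=rna.feature_ids.astype(str).rename(None)),
    )
    adata.obs_names = obs_index
    adata.obsm[ADT_KEY] = adt.to_frame().set_axis(adt.obs_ids.astype(str), axis=0)
    adata.uns["omic"] = {
        "rna_state": rna.state.value,
        "adt_state": adt.state.value,
        **(uns or {}),
    }
    adata.write_h5ad(Path(path))


def read_container(path) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Read the paired container back into (rna, adt) matrices."""
    adata = ad.read_h5ad(Path(path))
    meta = dict(adata.uns.get("omic", {}))
    rna_state = State(meta.get("rna_state", "raw"))
    adt_state = State(meta.get("adt_state", "raw"))
    X = adata.X
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)
    rna = ExpressionMatrix(
        X, pd.Index(adata.obs_names), pd.Index(adata.var_names), rna_state, Modality.RNA
    )
    if ADT_KEY not in adata.obsm:
        raise KeyError(f"container {path} has no {ADT_KEY!r} obsm entry")
    adt_df = adata.obsm[ADT_KEY]
    if not isinstance(adt_df, pd.DataFrame):
        adt_df = pd.DataFrame(
            np.asarray(adt_df),
            index=adata.obs_names,
            columns=[f"adt_{i}" for i in range(np.asarray(adt_df).shape[1])],
        )
    adt = ExpressionMatrix(
        adt_df.to_numpy(dtype=float),
        pd.Index(adata.obs_names),
        pd.Index(adt_df.columns),
        adt_state,
        Modality.ADT,
    )
    return rna, adt


def write_mtx_dir(m: ExpressionMatrix, path) -> None:
    """Write a matrix as a 10x-style MTX directory (features x cells)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(m.values.T))
    pd.Series(m.feature_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.obs_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
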