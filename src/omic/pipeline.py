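"""End-to-end orchestration: preprocess -> (batch-correct) -> integrate ->
cluster -> (interpret), with every artifact and parameter written to disk.

All randomness flows from a single top-level seed, split deterministically per
stage, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._types import ExpressionMatrix, Modality, State
from . import preprocess as pp
from . import cluster as cl
from . import interpret as ip
from . import batch as bt
from . import io as oio
from .integrate import explained_variance_report, fit_projection, residualize
from .integrate import integrate as integrate_residuals

log = logging.getLogger("omic")

__all__ = ["RunConfig", "run_pipeline"]

_STAGE_SEED_OFFSETS = {"cluster": 1, "umap": 2, "interpret": 3}


@dataclass
class RunConfig:
    """All parameters of a full run; defaults match the stage modules."""

    rna_path: str = ""
    adt_path: str = ""
    rna_format: str | None = None
    adt_format: str | None = None
    batch_csv: str | None = None  # CSV with obs_id,batch columns
    labels_csv: str | None = None  # reference labels: obs_id,label
    out_dir: str = "omic_out"

    # preprocess
    n_top: int = 2000
    scale_factor: float = 1e4
    clr_margin: str = "feature_across_cells"
    clr_dialect: str = "pseudocount"
    clip: float | None = None
    span: float = 0.3
    # integrate
    restandardize_residuals: bool = True
    sigma_denominator: str = "n"
    # cluster
    k: int = 20
    resolution: float = 0.8
    n_pcs: int | None = None
    run_umap: bool = False
    # interpret
    interpret_clusters: bool = False
    alpha: float = 0.01
    train_frac: float = 0.7
    n_repeats: int = 100
    ridge: float = 1e-4

    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _stage_seed(config: RunConfig, stage: str) -> int:
    return (config.seed * 1000 + _STAGE_SEED_OFFSETS.get(stage, 0)) % (2**31 - 1)


def run_pipeline(
    config: RunConfig,
    rna: ExpressionMatrix | None = None,
    adt: ExpressionMatrix | None = None,
) -> dict:
    """Execute the full pipeline and write artifacts under ``config.out_dir``.

    Matrices may be passed in memory (e.g. straight from the simulator);
    otherwise they are read from the configured paths.  Returns a result
    bundle with the key in-memory objects plus the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": [],
    }
    stage = "load"
    try:
        if rna is None:
            if not config.rna_path:
                raise ValueError("no RNA input given")
            rna = oio.read_matrix(config.rna_path, config.rna_format, Modality.RNA)
        if adt is None:
            if not config.adt_path:
                raise ValueError(
                    "no ADT input given: the method requires both modalities"
                )
            adt = oio.read_matrix(config.adt_path, config.adt_format, Modality.ADT)

        stage = "preprocess"
        if rna.state is State.RAW:
            rna_norm = pp.lognormalize_rna(rna, config.scale_factor)
            n_top = min(config.n_top, rna.n_features)
            hvg = pp.select_hvg(rna_norm, rna, n_top=n_top, span=config.span)
            rna_norm = rna_norm.subset_features(hvg)
        else:
            rna_norm = rna
        if adt.state is State.RAW:
            adt_norm = pp.clr_transform(adt, config.clr_margin, config.clr_dialect)
        else:
            adt_norm = adt
        X = pp.scale_features(rna_norm, clip=config.clip) if rna_norm.state is not State.SCALED else rna_norm
        Y = pp.scale_features(adt_norm, clip=config.clip) if adt_norm.state is not State.SCALED else adt_norm
        manifest["stages"].append("preprocess")

        batch_labels = None
        if config.batch_csv:
            bdf = pd.read_csv(config.batch_csv, index_col=0)
            batch_labels = bdf.iloc[:, 0].reindex(X.obs_ids).to_numpy()

        stage = "integrate"
        if batch_labels is not None:
            design = bt.build_batch_design(batch_labels)
            _, X0 = bt.correct_rna(X, design)
            bmodel = bt.fit_batch_projection(Y, design, X0, X=X)
            data = bt.batch_integrate(bmodel, config.restandardize_residuals)
            model = None
            r2_table = None
            log.info("batch model: %d batches, effective rank %d", design.n_batches, bmodel.rank)
        else:
            model = fit_projection(X, Y, config.sigma_denominator)
            result = residualize(X, Y, model)
            data = integrate_residuals(X, result, config.restandardize_residuals)
            r2_table = explained_variance_report(result)
            r2_table.to_csv(out / "explained_variance.csv", index=False)
            manifest["outputs"].append("explained_variance.csv")
            pd.DataFrame(
                model.B_hat, index=model.feature_ids_rna, columns=model.feature_ids_adt
            ).to_csv(out / "B_hat.csv")
            manifest["outputs"].append("B_hat.csv")
            log.info(
                "integrate: n=%d p=%d q=%d effective rank=%d",
                X.n_obs, X.n_features, Y.n_features, model.rank,
            )
        manifest["stages"].append("integrate")

        stage = "cluster"
        n_pcs = config.n_pcs
        if n_pcs is None and data.values.shape[1] > 50:
            n_pcs = min(30, data.n_obs - 1)
        graph = cl.knn_graph(data, k=config.k, n_pcs=n_pcs)
        cseed = _stage_seed(config, "cluster")
        ref_labels = None
        if config.labels_csv:
            ldf = pd.read_csv(config.labels_csv, index_col=0)
            ref_labels = ldf.iloc[:, 0].reindex(data.obs_ids).to_numpy()
            grid = [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.6, 2.0]
            best_res, clus, scan_table = cl.resolution_scan(
                data, ref_labels, grid, k=config.k, seed=cseed, n_pcs=n_pcs
            )
            scan_table.to_csv(out / "resolution_scan.csv", index=False)
            manifest["outputs"].append("resolution_scan.csv")
            log.info("resolution scan selected %.2f", best_res)
        else:
            log.info("no reference labels: clustering at fixed resolution %.2f",
                     config.resolution)
            clus = cl.louvain_cluster(graph, config.resolution, seed=cseed)
        clus.k_neighbors = config.k
        labels_df = pd.DataFrame({"obs_id": data.obs_ids, "label": clus.labels})
        labels_df.to_csv(out / "cluster_labels.csv", index=False)
        manifest["outputs"].append("cluster_labels.csv")
        manifest["stages"].append("cluster")

        if config.run_umap:
            stage = "umap"
            coords = cl.umap_embed(data, seed=_stage_seed(config, "umap"))
            pd.DataFrame(coords, index=data.obs_ids, columns=["umap1", "umap2"]).to_csv(
                out / "umap.csv"
            )
            manifest["outputs"].append("umap.csv")
            manifest["stages"].append("umap")

        evaluations = {}
        if config.interpret_clusters:
            stage = "interpret"
            iseed = _stage_seed(config, "interpret")
            rows = []
            for j in np.unique(clus.labels):
                n_j = int((clus.labels == j).sum())
                if n_j < 10 or n_j > clus.labels.size - 10:
                    continue
                ev = ip.repeated_split_evaluation(
                    Y, X, clus.labels, int(j),
                    train_frac=config.train_frac,
                    n_repeats=config.n_repeats,
                    seed=iseed + int(j),
                    alpha=config.alpha,
                    ridge=config.ridge,
                )
                evaluations[int(j)] = ev
                for mode, vals in ev.aucs.items():
                    rows.append({"cluster": int(j), "mode": mode,
                                 "mean_auc": float(np.mean(vals)),
                                 "sd_auc": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0})
                coef = pd.concat(ev.coefficients, names=["mode", "feature"]).rename("estimate")
                coef.to_frame().assign(sign=np.sign(coef)).to_csv(
                    out / f"coefficients_cluster{j}.csv"
                )
                manifest["outputs"].append(f"coefficients_cluster{j}.csv")
            pd.DataFrame(rows).to_csv(out / "auc_summary.csv", index=False)
            manifest["outputs"].append("auc_summary.csv")
            manifest["stages"].append("interpret")

        manifest["seed_per_stage"] = {s: _stage_seed(config, s) for s in _STAGE_SEED_OFFSETS}
        oio.write_json(manifest, out / "manifest.json")
        return {
            "X": X,
            "Y": Y,
            "model": model,
            "integrated": data,
            "clusters": clus,
            "r2_table": r2_table,
            "evaluations": evaluations,
            "manifest": manifest,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
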