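"""End-to-end workflow: QC -> normalize -> HVG -> impute -> cluster -> evaluate.

The clustering stage is delegated to the standard toolchain (PCA
neighborhood graph + Leiden community detection via scanpy/leidenalg)
and is never part of the imputation method itself. Stage order is fixed;
imputation always runs on the log-normalized, gene-selected matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .impute import impute as _impute_op
from . import metrics as _metrics
from . import preprocessing as _pre
from .types import DatasetBundle, ImputationConfig, QCConfig, SpotGeneMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClusterConfig", "RunConfig", "cluster_leiden", "run_pipeline",
           "PipelineResult", "sweep_hyperparameters"]


@dataclass
class ClusterConfig:
    method: str = "leiden"
    resolution: float = 1.0
    n_neighbors: int = 15
    n_pcs: int = 30
    seed: int = 0


@dataclass
class RunConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    hvg_mode: str = "all"
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    bundle: DatasetBundle
    cluster_labels: np.ndarray
    metrics: Optional[dict]
    report: object  # ImputationReport
    qc_report: object


def cluster_leiden(matrix: SpotGeneMatrix, cfg: ClusterConfig | None = None) -> np.ndarray:
    """Leiden clustering on a PCA neighborhood graph of the expression matrix."""
    import scanpy as sc
    import anndata as ad

    cfg = cfg or ClusterConfig()
    if cfg.method != "leiden":
        raise ValueError(f"unsupported clustering method {cfg.method!r}")
    adata = ad.AnnData(X=np.asarray(matrix.values, dtype=np.float32))
    n_pcs = min(cfg.n_pcs, matrix.n_genes - 1, matrix.n_spots - 1)
    sc.pp.pca(adata, n_comps=n_pcs, random_state=cfg.seed)
    sc.pp.neighbors(adata, n_neighbors=cfg.n_neighbors, random_state=cfg.seed)
    sc.tl.leiden(
        adata,
        resolution=cfg.resolution,
        random_state=cfg.seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    return adata.obs["leiden"].to_numpy().astype(str)


def run_pipeline(bundle: DatasetBundle, cfg: RunConfig | None = None) -> PipelineResult:
    """Execute the full workflow on a raw-count bundle.

    Stages run in the fixed order QC -> normalize -> HVG -> impute ->
    cluster -> evaluate; metrics against ``bundle.true_labels`` are
    computed when labels are present.
    """
    cfg = cfg or RunConfig()
    if not bundle.has_coords:
        raise ValueError(
            "pipeline requires spatial coordinates; this bundle has none"
        )

    matrix, coords, labels, qc_report = _pre.qc_filter(
        bundle.matrix, bundle.coords, bundle.true_labels, cfg.qc
    )
    matrix = _pre.normalize_log1p(matrix)
    matrix = _pre.select_hvg(matrix, cfg.hvg_mode)
    imputed, report, decisions = _impute_op(matrix, coords, cfg.imputation)

    cluster_labels = cluster_leiden(imputed, cfg.cluster)

    scores = None
    if labels is not None:
        scores = _metrics.metric_set(labels, cluster_labels)
        logger.info("clustering agreement: %s", scores)

    out = DatasetBundle(
        matrix=imputed,
        coords=coords,
        true_labels=labels,
        layers={"decisions": decisions.astype(float)},
        provenance=list(bundle.provenance),
    )
    out.log("run_pipeline", config=cfg.to_dict())
    return PipelineResult(
        bundle=out,
        cluster_labels=cluster_labels,
        metrics=scores,
        report=report,
        qc_report=qc_report,
    )


def sweep_hyperparameters(
    matrix: SpotGeneMatrix,
    coords,
    k_values=(3, 5, 7, 9, 11),
    delta_values=(0.04, 0.1, 0.2, 0.3, 0.4),
) -> list[dict]:
    """Grid-sweep (k, delta) and collect the imputation reports.

    Useful for sensitivity analysis: the returned rows hold the decision
    counts and sparsity accounting for every combination.
    """
    rows = []
    for k in k_values:
        for delta in delta_values:
            _, report, _ = _impute_op(
                matrix, coords, ImputationConfig(k=k, delta=delta)
            )
            rows.append({"k": k, "delta": delta, **report.to_dict()})
    return rows
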